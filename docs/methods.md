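# Methods

## Model

A tissue of fixed size `N` contains normal cells (Type0) and
premalignant cells carrying one cancer-related mutation (Type1).
Homeostasis is modeled as a Moran process: turnover events occur at
rate `N/δ` (one whole-tissue turnover per `δ` days); at each event one
of the `N` cells dies uniformly at random and a replacement divides,
chosen with probability proportional to its selection weight — `r0`
per Type0 cell, `r1` per Type1 cell, total `F = r0(N−i) + r1·i` at
Type1 count `i`. The dividing-cell pool includes the dying cell, so
the weights use `N−i` and `i`, not `N−i−1`. A dividing Type0's
daughter is Type1 with probability `μ1`; a dividing Type1's daughter
is Type2 (malignant) with probability `μ2`.

A Type2 daughter cannot remain in the homeostatic tissue: it is
emitted as a tumor *founder*, and an additional mutation-free division
(the redraw, Type0 with probability `c0 = r0(N−i)/F`, Type1 with
`c1 = r1·i/F`) fills the vacancy within the same event. The joint
law of one turnover event over (Δi ∈ {−1,0,+1}) × (founder yes/no)
is computed in closed form; its Δi-marginals are

    P(i→i+1) = [r0(N−i)μ1 + r1·i(1−μ2+μ2·c1)]/F · (N−i)/N
    P(i→i−1) = [r0(N−i)(1−μ1) + r1·i·μ2·c0]/F · i/N

and the total founder-emission probability per event is `r1·i·μ2/F`.

Founders seed a pooled tumor population `x2` that evolves as a linear
birth–death process: per-cell birth rate `r2`, death rate `d2`
(supercritical, `r2 > d2`; a single founder survives stochastic
extinction with probability `1 − d2/r2`). Founders emitted while an
earlier lineage is still growing add one cell to the pool, so a
detected tumor may descend from several initiations. When `x2` first
reaches `switch_multiplier·N` (default `2N`) the growth is treated as
deterministic exponential, and the remaining time to the detection
size `M_detect` (default 1e9 cells ≈ 1 cm³) is

    Δts = ln(M_detect / x2) / (r2 − d2).

One widely circulated typeset form of this expression multiplies by
`(r2 − d2)` instead of dividing; only the division is dimensionally a
time, and the package uses it. Tissue turnover continues during the
deterministic window; founder emissions inside it are ignored — they
would be removed at the imminent resection, which discards every
Type2 cell while preserving the Type1 count. The time from surgery to
the next detection is the recurrence time. Exactly one surgery and
one recurrence are simulated per patient.

`d2` is a required model rate that the source model description never
assigns; the package default is `d2 = 1/δ` (death at the tissue
turnover rate), and every experiment here states the `d2` it uses
(all acceptance settings use `d2 = 1.0`).

## Event engine

The three event classes — turnover at rate `N/δ`, Type2 birth at
`r2·x2`, Type2 death at `d2·x2` — are independent Poisson streams
while `(i, x2)` is unchanged. The engine therefore thins the turnover
stream analytically: the silent outcome (no Type1 change, no founder)
is dropped, state-changing turnover events arrive at rate
`(N/δ)·(1 − p_silent)`, and each jump advances the clock by an
exponential with the combined thinned rate. Poisson thinning is exact,
so the sequence of state changes and their times have exactly the
distribution of the naive per-event simulation; the unit tests check
the underlying kernel against brute-force enumeration of the full
death × division × mutation × redraw tree for `N ≤ 12` at 1e-12, and
the engine against the classical Moran fixation formulas
(`1/N` neutrally, `(1−r0/r1)/(1−(r0/r1)^N)` under selection). The
loop is compiled with numba; typical cohorts simulate at millions of
state-changing events per second, far above the naive-event-rate
equivalent.

Reproducibility: per-patient seeds are spawned from a master seed with
`numpy.random.SeedSequence` (counter-based, order-independent), and
each patient's trajectory is a pure function of its seed and the
parameters.

Degenerate inputs are handled without error: a tissue with `i = 0`,
`μ1 = 0` and no tumor has total event rate 0 and censors at the
horizon; all horizon crossings (`t_max`, default 1e5 days) yield
censored observations.

## Branching-process validation samplers

Two independent samplers exist solely to validate the simulator's
approximations:

* a per-event birth–death simulator (extinction fractions, sizes at a
  fixed time);
* the exact transition law of the linear birth–death process over a
  step `dt` — each cell leaves 0 descendants with probability
  `α = d2(e^{g·dt}−1)/(r2·e^{g·dt}−d2)` (with `g = r2−d2`), otherwise
  a geometric number with parameter `β = (r2/d2)α` — sampled as a
  binomial number of surviving lineages plus a negative-binomial
  offspring count. Chaining these steps is distributionally exact at
  the grid times, which makes a *fully stochastic* passage-time
  experiment from `2N` to 1e9 cells feasible; the recorded passage
  time is the first grid point past the true crossing, a bias below
  `dt = 0.02` day on a ~65-day passage. The acceptance check confirms
  the mean stochastic passage time is within 5% of `Δts`, justifying
  the deterministic switch.

## Survival layer

Kaplan–Meier estimation and the two-sample log-rank test are delegated
to lifelines (standard product-limit estimator; chi-square log-rank
with the hypergeometric tie variance) behind this package's interface;
both are verified against hand-computed micro-examples. The fitting
objective uses five *recurrence-fraction* time points: among the `K`
event times sorted ascending, the point at fraction `q ∈ {0.2, 0.4,
0.6, 0.8, 1.0}` is the order statistic `t(⌈qK⌉)`. The ceiling rule
keeps the 100% point exactly the maximum event time; interpolating
alternatives were rejected for that reason. Fractions are taken over
event patients only — censored patients never reach "recurred", and
including them would leave the 100% point undefined. The discrepancy
between simulated and clinical point sets is the sum of squared
log-residuals, base 10 by default (the base is a knob; it rescales
but never reorders objectives).

## Fitting

`fit_nelder_mead` estimates `θ = (r1, r2, log10 μ)` with `μ1 = μ2 =
10^{log10 μ}` (a single shared mutation probability; sweeps may still
vary `μ1`, `μ2` independently). Fixed during fitting: `N = 1000`,
`δ = 1`, `r0 = 1`, `d2`, `M_detect`, and a fitting horizon of
`t_max = 20,000` days — far beyond any observed disease-free interval,
chosen so that objective evaluations at degenerate parameter values
terminate. The stochastic objective is made deterministic by common
random numbers: every evaluation simulates `runs_per_eval` patients
from the same master seed, so Nelder–Mead sees a fixed surface.
Box constraints (`r1 ∈ [0.5, 1.5]`, `r2 ∈ (d2+0.01, 3]`,
`log10 μ ∈ [−6, −2]`, covering all published per-cancer estimates)
are enforced by a penalty sentinel (1e6 plus the squared violation);
evaluations with no observed recurrence return the same sentinel
rather than raising. Three restarts from jittered starts (default
start `r1 = 1`, `r2 = 1.4`, `log10 μ = −3.5`; 60 evaluations each)
are run and the best objective wins. The reported log-rank p compares
a freshly seeded cohort at the estimate with the clinical sample,
censored rows included on both sides.

The recovery harness shows `log10 μ` and `r2` are well identified
(±0.5 and ±0.2 at 300 runs/evaluation) while `r1` is weakly
identified — many fitness values produce similar recurrence-time
curves, consistent with the flat direction reported for such fits.

## Synthetic cohorts

`gen_synthetic_cohort` emulates a pan-cancer clinical
disease-free-interval table: simulated recurrence times become DFIs
with event = 1; optional independent exponential right-censoring is
calibrated numerically (Brent root-finding on the expected censored
fraction) so that the realized censored fraction matches the request
in expectation. What the generator does **not** emulate: patient
heterogeneity in model parameters, adjuvant-therapy effects,
informative censoring, multi-stage mutational routes, and measurement
granularity of clinical follow-up. Tests that pass on these cohorts
therefore validate the machinery (estimator correctness, recovery of
generating parameters), not the model's adequacy for any real
clinical series.

## Problem sizes and numerical choices

Replicate counts in the validation suite — 200 runs per classification
or sweep point, 100 sets × 100 runs for the random sweep, 5,000
fixation replicates, 10,000 branching founders, 300 runs per objective
evaluation — were chosen to give 3-standard-error or bootstrap-95%
resolution on each tested quantity at desk scale. Bootstrap intervals
use 2,000 percentile resamples of the median. Monotonicity checks
require adjacent medians non-increasing within bootstrap uncertainty
and the extreme grid points' intervals disjoint. Probability
comparisons in kernel tests use absolute tolerance 1e-12; all
closed-form Monte-Carlo checks use 3 standard errors.

## Known limitations

* A single intermediate (Type1) stage; real carcinogenesis may need
  more, which would change the survival-curve shape (notably the long
  tail).
* No spatial structure; the field is well mixed.
* The pooled tumor `x2` does not track lineages, so per-lineage
  extinction after pooling is approximated by the pooled birth–death
  law (matching the source model's bookkeeping).
* `r1` is weakly identifiable from recurrence times alone.
* Founder emissions during the deterministic growth window are
  discarded; for parameter sets where detection is slow relative to
  founding this slightly undercounts multi-initiation overlap, but
  those founders would be resected with the pool anyway.
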