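"""Exact per-event probability kernel of the homeostatic tissue.

One turnover event: a cell dies uniformly at random, a replacement is
chosen to divide with probability proportional to its selection weight
(r0 for Type0, r1 for Type1; the pool includes the dying cell), and the
daughter may carry one further mutation.  A Type1 daughter that mutates
to Type2 cannot stay in the tissue: it is emitted as a tumor *founder*
and an additional, mutation-free division (the redraw) fills the slot.

The kernel is the joint distribution over (change in Type1 count) x
(founder emitted or not); marginalizing over founder emission gives the
standard three transition probabilities of the embedded Moran chain.
"""

from __future__ import annotations

import dataclasses

from .params import ModelParams
from .state import TissueState


@dataclasses.dataclass(frozen=True)
class SelectionWeights:
    """Division-selection bookkeeping at Type1 count i.

    F = r0 (N - i) + r1 i is the total selection weight; c0 and c1 are
    the probabilities that the redraw division picks a Type0 / Type1
    cell (no mutation occurs in the redraw).
    """

    F: float
    c0: float
    c1: float


@dataclasses.dataclass(frozen=True)
class TurnoverKernel:
    """Joint six-outcome distribution of one turnover event."""

    p_up_nofounder: float
    p_up_founder: float
    p_stay_nofounder: float
    p_stay_founder: float
    p_down_nofounder: float
    p_down_founder: float

    @property
    def p_up(self) -> float:
        return self.p_up_nofounder + self.p_up_founder

    @property
    def p_down(self) -> float:
        return self.p_down_nofounder + self.p_down_founder

    @property
    def p_stay(self) -> float:
        return self.p_stay_nofounder + self.p_stay_founder

    @property
    def p_founder(self) -> float:
        return self.p_up_founder + self.p_stay_founder + self.p_down_founder

    @property
    def p_change(self) -> float:
        """Probability the event alters the state (i moves or a founder
        is emitted) — the complement of the silent outcome."""
        return 1.0 - self.p_stay_nofounder

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (
            self.p_up_nofounder,
            self.p_up_founder,
            self.p_stay_nofounder,
            self.p_stay_founder,
            self.p_down_nofounder,
            self.p_down_founder,
        )


def _check_i(i: int, N: int) -> None:
    if not 0 <= i <= N:
        raise ValueError(f"Type1 count i must lie in [0, {N}], got {i}")


def selection_weights(params: ModelParams, i: int) -> SelectionWeights:
    """Total selection weight F and redraw probabilities c0, c1 at i."""
    _check_i(i, params.N)
    F = params.r0 * (params.N - i) + params.r1 * i
    c1 = params.r1 * i / F
    return SelectionWeights(F=F, c0=1.0 - c1, c1=c1)


def turnover_kernel(params: ModelParams, i: int) -> TurnoverKernel:
    """The six-outcome joint distribution of one turnover event at i."""
    _check_i(i, params.N)
    N, r0, r1 = params.N, params.r0, params.r1
    mu1, mu2 = params.mu1, params.mu2
    w = selection_weights(params, i)
    F, c0, c1 = w.F, w.c0, w.c1
    p_die0 = (N - i) / N
    p_die1 = i / N
    founder = r1 * i * mu2 / F  # P(first-round division is Type1 and mutates)

    up_nf = p_die0 * (r1 * i * (1.0 - mu2) + r0 * (N - i) * mu1) / F
    up_f = p_die0 * founder * c1
    down_nf = p_die1 * (r0 * (N - i) * (1.0 - mu1)) / F
    down_f = p_die1 * founder * c0
    stay_f = p_die0 * founder * c0 + p_die1 * founder * c1
    stay_nf = 1.0 - (up_nf + up_f + down_nf + down_f + stay_f)
    return TurnoverKernel(
        p_up_nofounder=up_nf,
        p_up_founder=up_f,
        p_stay_nofounder=stay_nf,
        p_stay_founder=stay_f,
        p_down_nofounder=down_nf,
        p_down_founder=down_f,
    )


def transition_probabilities(params: ModelParams, i: int) -> tuple[float, float, float]:
    """(p_up, p_down, p_stay) of the Type1 count in one turnover event.

    Closed form (marginal of the six-outcome kernel over founder
    emission)::

        p_up   = [r0 (N-i) mu1 + r1 i (1 - mu2 + mu2 c1)] / F * (N-i)/N
        p_down = [r0 (N-i) (1 - mu1) + r1 i mu2 c0] / F * i/N
        p_stay = 1 - p_up - p_down
    """
    _check_i(i, params.N)
    N, r0, r1 = params.N, params.r0, params.r1
    mu1, mu2 = params.mu1, params.mu2
    w = selection_weights(params, i)
    p_up = (r0 * (N - i) * mu1 + r1 * i * (1.0 - mu2 + mu2 * w.c1)) / w.F * (N - i) / N
    p_down = (r0 * (N - i) * (1.0 - mu1) + r1 * i * mu2 * w.c0) / w.F * i / N
    return p_up, p_down, 1.0 - p_up - p_down


def event_rates(
    params: ModelParams, state: TissueState
) -> tuple[float, float, float, float]:
    """Rates of the three competing event classes and the mean wait.

    Returns ``(rate_turnover, rate_type2_death, rate_type2_birth,
    mean_wait)`` with ``rate_turnover = N / delta`` and mean waiting
    time ``1 / (N/delta + d2 x2 + r2 x2)``.
    """
    rate_turnover = params.turnover_rate
    rate_death = params.d2 * state.x2
    rate_birth = params.r2 * state.x2
    total = rate_turnover + rate_death + rate_birth
    return rate_turnover, rate_death, rate_birth, 1.0 / total
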