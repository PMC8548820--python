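"""Parameter estimation and parameter-sweep experiments.

The fitting layer estimates theta = (r1, r2, log10_mu) — premalignant
fitness, cancer growth rate and a shared per-division mutation
probability mu1 = mu2 = 10**log10_mu — by minimizing the log-SSR
between simulated and clinical recurrence-fraction quantile points with
Nelder-Mead.  The stochastic objective is made deterministic by common
random numbers: every evaluation reuses the same master seed, so the
optimizer sees a fixed response surface.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ModelParams
from .simulator import simulate_cohort
from .survival import QuantilePoints, event_quantiles, log_ssr, logrank_test

__all__ = [
    "FitConfig",
    "FitResult",
    "objective",
    "fit_nelder_mead",
    "sweep",
    "random_parameter_sets",
    "PENALTY",
]

# Sentinel objective for infeasible / fully-censored evaluations; any
# feasible evaluation is orders of magnitude below it, and the added
# squared bound violation gives Nelder-Mead a slope back into the box.
PENALTY = 1.0e6


@dataclasses.dataclass
class FitConfig:
    """Configuration of one fitting run.

    ``fixed`` holds the parameters not estimated (N, delta, r0, d2,
    M_detect, t_max); the default horizon of 20,000 days comfortably
    exceeds any observed disease-free interval while keeping
    degenerate-parameter evaluations bounded.
    """

    runs_per_eval: int = 300
    master_seed: int = 0
    restarts: int = 3
    max_evals_per_restart: int = 60
    x0: tuple[float, float, float] = (1.0, 1.4, -3.5)
    bounds: Mapping[str, tuple[float, float]] | None = None
    fixed: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {
            "N": 1000,
            "delta": 1.0,
            "r0": 1.0,
            "d2": 1.0,
            "M_detect": 1e9,
            "t_max": 2e4,
        }
    )

    def __post_init__(self) -> None:
        if self.runs_per_eval < 10:
            raise ValueError("runs_per_eval must be >= 10")
        d2 = self.fixed.get("d2", 1.0 / self.fixed.get("delta", 1.0))
        if self.bounds is None:
            self.bounds = {
                "r1": (0.5, 1.5),
                "r2": (d2 + 0.01, 3.0),
                "log10_mu": (-6.0, -2.0),
            }
        if self.bounds["r2"][0] <= d2:
            raise ValueError("lower bound on r2 must exceed d2")

    def params_at(self, theta: Sequence[float]) -> ModelParams:
        r1, r2, log10_mu = theta
        mu = 10.0 ** log10_mu
        return ModelParams(r1=float(r1), r2=float(r2), mu1=mu, mu2=mu, **self.fixed)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        d["fixed"] = dict(self.fixed)
        d["x0"] = list(self.x0)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FitConfig":
        d = dict(d)
        if "bounds" in d and d["bounds"] is not None:
            d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        if "x0" in d:
            d["x0"] = tuple(d["x0"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Best estimate over restarts, with goodness-of-fit attachments."""

    r1_hat: float
    r2_hat: float
    log10_mu_hat: float
    objective: float
    logrank_p: float
    logrank_statistic: float
    n_evaluations: int
    seed: int
    converged: bool

    @property
    def theta(self) -> tuple[float, float, float]:
        return (self.r1_hat, self.r2_hat, self.log10_mu_hat)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _bound_violation(theta: Sequence[float], bounds: Mapping[str, tuple[float, float]]) -> float:
    v = 0.0
    for x, key in zip(theta, ("r1", "r2", "log10_mu")):
        lo, hi = bounds[key]
        if x < lo:
            v += (lo - x) ** 2
        elif x > hi:
            v += (x - hi) ** 2
    return v


def objective(
    theta: Sequence[float], clin_q: QuantilePoints, cfg: FitConfig
) -> float:
    """log-SSR between simulated and clinical quantile points at theta.

    Deterministic in (theta, cfg): the cohort is simulated with
    cfg.master_seed every call (common random numbers).  Out-of-bounds
    theta and evaluations with no observed recurrence return the
    PENALTY sentinel (plus the squared violation), never raise.
    """
    viol = _bound_violation(theta, cfg.bounds)
    if viol > 0:
        return PENALTY + viol
    cohort = simulate_cohort(cfg.params_at(theta), cfg.runs_per_eval, cfg.master_seed)
    ev = cohort.recurrence_events
    if len(ev) == 0:
        return PENALTY
    sim_q = event_quantiles(ev["t_recurrence"].to_numpy())
    return log_ssr(sim_q, clin_q)


def _clinical_arrays(clinical: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if {"dfi_days", "dfi_event"} <= set(clinical.columns):
        return (
            clinical["dfi_days"].to_numpy(dtype=float),
            clinical["dfi_event"].to_numpy(dtype=int),
        )
    if {"t_recurrence", "recurrence_censored"} <= set(clinical.columns):
        df = clinical
        if "detection_censored" in df.columns:
            df = df[df["detection_censored"] == 0]
        return (
            df["t_recurrence"].to_numpy(dtype=float),
            (1 - df["recurrence_censored"]).to_numpy(dtype=int),
        )
    raise ValueError(
        "clinical table needs (dfi_days, dfi_event) or "
        "(t_recurrence, recurrence_censored) columns"
    )


def fit_nelder_mead(clinical: pd.DataFrame, cfg: FitConfig) -> FitResult:
    """Estimate (r1, r2, log10_mu) against a clinical cohort.

    Quantile points are extracted from event rows only; Nelder-Mead is
    restarted cfg.restarts times from jittered starts and the best
    objective wins (ties to the cheaper run).  The returned log-rank p
    compares a freshly seeded cohort at the estimate with the clinical
    sample (censored rows included on both sides).
    """
    times, events = _clinical_arrays(clinical)
    if events.sum() < 5:
        raise ValueError("clinical cohort must contain at least 5 events")
    clin_q = event_quantiles(times[events == 1])

    rng = np.random.default_rng(cfg.master_seed)
    best: optimize.OptimizeResult | None = None
    total_evals = 0
    converged = False
    for k in range(cfg.restarts):
        x0 = np.asarray(cfg.x0, dtype=float)
        if k > 0:
            x0 = x0 + rng.normal(0.0, [0.05, 0.1, 0.3])
        res = optimize.minimize(
            objective,
            x0,
            args=(clin_q, cfg),
            method="Nelder-Mead",
            options={
                "maxfev": cfg.max_evals_per_restart,
                "xatol": 1e-3,
                "fatol": 1e-4,
            },
        )
        total_evals += res.nfev
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = tuple(float(x) for x in best.x)
    # goodness of fit on an independent stream
    check_seed = int(np.random.SeedSequence([cfg.master_seed, 0x5EED]).generate_state(1)[0] % 2**31)
    check = simulate_cohort(cfg.params_at(theta_hat), cfg.runs_per_eval, check_seed)
    sim_t = check.table["t_recurrence"].to_numpy(dtype=float)
    sim_e = 1 - np.maximum(
        check.table["recurrence_censored"].to_numpy(),
        check.table["detection_censored"].to_numpy(),
    )
    stat, p = logrank_test(sim_t, sim_e, times, events)
    return FitResult(
        r1_hat=theta_hat[0],
        r2_hat=theta_hat[1],
        log10_mu_hat=theta_hat[2],
        objective=float(best.fun),
        logrank_p=p,
        logrank_statistic=stat,
        n_evaluations=total_evals,
        seed=cfg.master_seed,
        converged=converged,
    )


# ----------------------------------------------------------------------
# sweeps

PROP_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def random_parameter_sets(
    ranges: Mapping[str, tuple[float, float]],
    n_sets: int,
    master_seed: int,
) -> pd.DataFrame:
    """Draw parameter sets: uniform for fitness values (r1, r2),
    log-uniform for mutation probabilities (mu1, mu2)."""
    rng = np.random.default_rng(master_seed)
    cols: dict[str, np.ndarray] = {}
    for name, (lo, hi) in ranges.items():
        if name.startswith("mu"):
            cols[name] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n_sets)
        else:
            cols[name] = rng.uniform(lo, hi, n_sets)
    return pd.DataFrame(cols)


def _prop_bin(p: float) -> str:
    for lo, hi in zip(PROP_BINS[:-1], PROP_BINS[1:]):
        if p <= hi:
            return f"{lo:.1f}-{hi:.1f}"
    return "0.8-1.0"


def sweep(
    param_sets: pd.DataFrame,
    runs_per_set: int,
    master_seed: int,
    fixed: Mapping[str, Any] | None = None,
) -> pd.DataFrame:
    """Simulate a cohort for each parameter set and summarize.

    ``param_sets`` holds one row per set with any subset of ModelParams
    fields (e.g. from :func:`random_parameter_sets`); the rest come
    from ``fixed`` / defaults.  Each row of the output carries the
    recurrence-time summaries, the mean Type1 proportion at first
    surgery, its 0.2-wide bin, and the small/intermediate/large class
    shares.
    """
    if runs_per_set < 10:
        raise ValueError("runs_per_set must be >= 10")
    fixed = dict(fixed or {})
    seeds = np.random.SeedSequence(master_seed).spawn(len(param_sets))
    rows = []
    for k, (_, ps) in enumerate(param_sets.iterrows()):
        kw = dict(fixed)
        kw.update({name: val for name, val in ps.items()})
        if "N" in kw:
            kw["N"] = int(kw["N"])
        params = ModelParams(**kw)
        seed = int(seeds[k].generate_state(1)[0] % 2**31)
        cohort = simulate_cohort(params, runs_per_set, seed)
        tab = cohort.table
        detected = tab[tab.detection_censored == 0]
        ev = cohort.recurrence_events
        props = detected["i_at_first_surgery"].to_numpy() / params.N
        classes = detected["class_at_surgery"]
        n_det = max(len(detected), 1)
        rec = ev["t_recurrence"].to_numpy()
        row = {name: val for name, val in ps.items()}
        mean_prop = float(props.mean()) if len(props) else np.nan
        row.update(
            {
                "seed": seed,
                "n_runs": runs_per_set,
                "n_detected": len(detected),
                "n_recurrence_events": len(ev),
                "median_recurrence": float(np.median(rec)) if len(rec) else np.nan,
                "mean_recurrence": float(rec.mean()) if len(rec) else np.nan,
                "sd_recurrence": float(rec.std(ddof=1)) if len(rec) > 1 else np.nan,
                "mean_type1_prop": mean_prop,
                "prop_bin": _prop_bin(mean_prop) if len(props) else "",
                "share_small": float((classes == "small").sum() / n_det),
                "share_intermediate": float((classes == "intermediate").sum() / n_det),
                "share_large": float((classes == "large").sum() / n_det),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
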