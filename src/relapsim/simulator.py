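"""Patient-level simulation: initiation, resection, recurrence.

One simulated patient starts from an all-Type0 tissue, accumulates
Type1 cells by Moran turnover with mutation, and emits Type2 founders.
The pooled Type2 population grows stochastically (birth rate r2, death
rate d2) until it first reaches ``switch_multiplier * N`` cells, after
which growth to the detection size M_detect is deterministic
exponential while the tissue keeps turning over.  At detection all
Type2 cells are resected (Type1 count preserved) and the process
repeats; the time from surgery to the second detection is the
recurrence time.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from .moran import event_rates, turnover_kernel
from .params import ModelParams, classify_tissue
from .state import TissueState

__all__ = [
    "DetectionResult",
    "PatientResult",
    "CohortTable",
    "advance_event",
    "run_tissue_for",
    "simulate_until_detection",
    "apply_surgery",
    "simulate_patient",
    "simulate_cohort",
    "read_cohort",
]

_SEED_MOD = 2**31  # numba's np.random.seed wants a small positive int


def _engine_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, _SEED_MOD))


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-patient engine seeds from a master seed (counter-based, so a
    cohort's content is independent of evaluation order)."""
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [int(c.generate_state(1)[0]) % _SEED_MOD for c in ss.spawn(n)],
        dtype=np.int64,
    )


# ----------------------------------------------------------------------
# results


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    """Outcome of one detection leg."""

    t_detect: float
    i_at_detect: int
    t_founding: float | None
    censored: bool


@dataclasses.dataclass(frozen=True)
class PatientResult:
    """One simulated patient: first detection, surgery, recurrence."""

    t_first_detection: float
    i_at_first_surgery: int
    class_at_surgery: str
    t_recurrence: float
    recurrence_censored: bool
    detection_censored: bool
    seed: int


_COHORT_COLUMNS = [
    "run_id",
    "seed",
    "t_first_detection",
    "i_at_first_surgery",
    "class_at_surgery",
    "t_recurrence",
    "recurrence_censored",
    "detection_censored",
]


@dataclasses.dataclass
class CohortTable:
    """A reproducible batch of simulated patients."""

    params: ModelParams
    master_seed: int
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def recurrence_events(self) -> pd.DataFrame:
        """Rows whose recurrence was observed (neither leg censored)."""
        t = self.table
        return t[(t.recurrence_censored == 0) & (t.detection_censored == 0)]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV written by :meth:`CohortTable.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COHORT_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


# ----------------------------------------------------------------------
# single-event and windowed tissue dynamics (exact, rng-driven)


def advance_event(
    state: TissueState, params: ModelParams, rng: np.random.Generator
) -> TissueState:
    """Advance the full stochastic process by exactly one Gillespie event.

    The waiting time is exponential with the total rate of the three
    event classes; the event class is chosen proportionally to its
    rate; turnover outcomes are drawn from the six-outcome kernel
    (including the silent outcome).  Intended for inspection and unit
    testing — cohort simulation uses the compiled engine, which samples
    the identical distribution but skips silent outcomes analytically.
    """
    rate_turn, rate_death, rate_birth, _ = event_rates(params, state)
    total = rate_turn + rate_death + rate_birth
    new = state.copy()
    new.t = state.t + rng.exponential(1.0 / total)
    u = rng.random() * total
    if u < rate_birth:
        new.x2 += 1
        return new
    if u < rate_birth + rate_death:
        new.x2 -= 1
        return new
    k = turnover_kernel(params, state.i)
    up_nf, up_f, st_nf, st_f, dn_nf, dn_f = k.as_tuple()
    v = rng.random()
    if v < up_nf:
        new.i += 1
    elif v < up_nf + up_f:
        new.i += 1
        _emit_founder(new)
    elif v < up_nf + up_f + st_f:
        _emit_founder(new)
    elif v < up_nf + up_f + st_f + dn_nf:
        new.i -= 1
    elif v < up_nf + up_f + st_f + dn_nf + dn_f:
        new.i -= 1
        _emit_founder(new)
    # else: silent outcome, state unchanged apart from time
    return new


def _emit_founder(state: TissueState) -> None:
    if state.x2 == 0:
        state.t_last_founding = state.t
    state.x2 += 1


def run_tissue_for(
    params: ModelParams,
    state: TissueState,
    duration: float,
    rng: np.random.Generator,
) -> TissueState:
    """Simulate only tissue turnover for exactly `duration` days.

    Used inside the deterministic tumor-growth window: Type2
    birth/death is handled in closed form outside, and founder
    emissions during the window are ignored (they would be removed at
    the imminent resection).  Type1-count moves follow the marginal
    (p_up, p_down) of the kernel.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    new = state.copy()
    if duration == 0:
        return new
    new.i = int(
        _engine._tissue_advance_seeded(
            _engine_seed(rng),
            params.N,
            params.delta,
            params.r0,
            params.r1,
            params.mu1,
            params.mu2,
            state.i,
            float(duration),
        )
    )
    new.t = state.t + duration
    return new


# ----------------------------------------------------------------------
# detection legs and the full patient protocol


def _leg_args(params: ModelParams) -> tuple:
    return (
        params.N,
        params.delta,
        params.r0,
        params.r1,
        params.r2,
        params.d2,
        params.mu1,
        params.mu2,
        params.M_detect,
        params.switch_size,
        params.t_max,
    )


def simulate_until_detection(
    params: ModelParams, state: TissueState, rng: np.random.Generator
) -> tuple[DetectionResult, TissueState]:
    """Run the hybrid process from `state` until the tumor reaches
    M_detect (or the horizon t_max passes).

    Stochastic below ``switch_multiplier*N`` Type2 cells, deterministic
    above; the tissue keeps turning over during the deterministic
    window.  Censoring at t_max is a normal outcome, not an error.
    """
    if state.x2 >= params.M_detect:
        raise ValueError("state already at or beyond detection size")
    status, t_detect, i_at, t_found, i_final, t_final = _engine._run_leg_seeded(
        _engine_seed(rng), *_leg_args(params), state.i, state.x2, state.t
    )
    founding = None if t_found < 0 else float(t_found)
    new = TissueState(i=int(i_final), x2=0, t=float(t_final), t_last_founding=founding)
    if status == _engine.DETECTED:
        new.x2 = int(params.M_detect)
    result = DetectionResult(
        t_detect=float(t_detect),
        i_at_detect=int(i_at),
        t_founding=founding,
        censored=(status == _engine.CENSORED),
    )
    return result, new


def apply_surgery(state: TissueState) -> TissueState:
    """Resect: remove every Type2 cell, preserving the Type1 count and
    the clock.  Idempotent."""
    new = state.copy()
    new.x2 = 0
    new.t_last_founding = None
    return new


def simulate_patient(params: ModelParams, seed: int) -> PatientResult:
    """Simulate one patient deterministically from (params, seed)."""
    out = _engine._simulate_patient(int(seed) % _SEED_MOD, *_leg_args(params))
    t_det1, i_det1, tf1, det_cens, t_rec, rec_cens = out
    return PatientResult(
        t_first_detection=float(t_det1),
        i_at_first_surgery=int(i_det1),
        class_at_surgery=classify_tissue(int(i_det1), params.N),
        t_recurrence=float(t_rec),
        recurrence_censored=bool(rec_cens),
        detection_censored=bool(det_cens),
        seed=int(seed) % _SEED_MOD,
    )


def simulate_cohort(params: ModelParams, n: int, master_seed: int) -> CohortTable:
    """Simulate n independent patients; bit-for-bit reproducible from
    (params, n, master_seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = derive_seeds(master_seed, n)
    args = _leg_args(params)
    rows = np.empty((n, 6), dtype=np.float64)
    for k in range(n):
        rows[k] = _engine._simulate_patient(int(seeds[k]), *args)
    df = pd.DataFrame(
        {
            "run_id": np.arange(n),
            "seed": seeds,
            "t_first_detection": rows[:, 0],
            "i_at_first_surgery": rows[:, 1].astype(np.int64),
            "class_at_surgery": [
                classify_tissue(int(i), params.N) for i in rows[:, 1]
            ],
            "t_recurrence": rows[:, 4],
            "recurrence_censored": rows[:, 5].astype(np.int64),
            "detection_censored": rows[:, 3].astype(np.int64),
        },
        columns=_COHORT_COLUMNS,
    )
    return CohortTable(params=params, master_seed=int(master_seed), table=df)
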