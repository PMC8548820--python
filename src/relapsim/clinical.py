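"""Clinical disease-free-interval tables and the synthetic cohort
generator.

The clinical layout mirrors pan-cancer clinical-resource exports: one
row per patient with a cancer-type code, a binary disease-free-interval
(DFI) event indicator and the DFI in days.  ``read_clinical`` maps
either the resource's column spellings or a plain one onto the
canonical columns; ``gen_synthetic_cohort`` produces the same layout
from the simulator at known parameters, with optional independent
exponential right-censoring, and stands in for the external download
in every test and example.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ModelParams
from .simulator import simulate_cohort

__all__ = ["DIALECTS", "read_clinical", "write_clinical", "gen_synthetic_cohort"]

log = logging.getLogger(__name__)

CANONICAL = ["patient_id", "cancer_type", "dfi_event", "dfi_days"]

# column-name mappings, canonical -> file spelling
DIALECTS: dict[str, Mapping[str, str]] = {
    "tcga": {
        "patient_id": "bcr_patient_barcode",
        "cancer_type": "type",
        "dfi_event": "DFI",
        "dfi_days": "DFI.time",
    },
    "plain": {
        "patient_id": "patient_id",
        "cancer_type": "cancer_type",
        "dfi_event": "dfi_event",
        "dfi_days": "dfi_days",
    },
}


def read_clinical(path: str | Path, dialect: str = "plain") -> pd.DataFrame:
    """Read a clinical DFI table into canonical columns.

    Rows with missing/NA indicator or time, or nonpositive times, are
    dropped with a logged count.  Raises on unmappable columns, naming
    the missing field.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; know {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise ValueError(
            f"clinical table at {path} lacks required column(s) {missing} "
            f"for dialect {dialect!r}"
        )
    out = pd.DataFrame({canon: df[src] for canon, src in mapping.items()})
    n0 = len(out)
    out["dfi_event"] = pd.to_numeric(out["dfi_event"], errors="coerce")
    out["dfi_days"] = pd.to_numeric(out["dfi_days"], errors="coerce")
    out = out.dropna(subset=["dfi_event", "dfi_days"])
    n_na = n0 - len(out)
    bad = out["dfi_days"] <= 0
    n_bad = int(bad.sum())
    out = out[~bad]
    if n_na or n_bad:
        log.info(
            "read_clinical: dropped %d rows with missing indicator/time and "
            "%d rows with nonpositive time (%d kept)", n_na, n_bad, len(out)
        )
    out["dfi_event"] = out["dfi_event"].astype(int)
    out["dfi_days"] = out["dfi_days"].astype(float)
    if not out["dfi_event"].isin((0, 1)).all():
        raise ValueError("dfi_event column must be binary 0/1")
    return out.reset_index(drop=True)


def write_clinical(df: pd.DataFrame, path: str | Path, dialect: str = "plain") -> None:
    """Write canonical clinical records under a dialect's spellings."""
    mapping = DIALECTS[dialect]
    renamed = df[CANONICAL].rename(columns=mapping)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    renamed.to_csv(path, sep=sep, index=False)


def _censor_rate_for(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate lambda with expected censored
    fraction `target` over the given event times: solves
    mean(1 - exp(-lambda t)) = target."""
    def f(lam: float) -> float:
        return float(np.mean(-np.expm1(-lam * times))) - target

    lo, hi = 1e-12, 1.0 / max(times.min(), 1e-9)
    while f(hi) < 0:
        hi *= 4.0
        if hi > 1e12:  # pragma: no cover - pathological
            break
    return float(optimize.brentq(f, lo, hi))


def gen_synthetic_cohort(
    params: ModelParams,
    n: int,
    censor_rate: float,
    master_seed: int,
    cancer_type: str = "SYN",
) -> pd.DataFrame:
    """Synthetic clinical cohort: simulated recurrence times as DFIs.

    Each patient's DFI is the simulated recurrence time (event = 1)
    unless an independent exponential censoring time falls first, in
    which case the row carries the censoring time with event = 0.  The
    censoring rate is calibrated numerically so the expected censored
    fraction equals ``censor_rate``.  Simulator-censored runs (horizon
    reached) are reported as censored at their observation span.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    cohort = simulate_cohort(params, n, master_seed)
    tab = cohort.table
    times = tab["t_recurrence"].to_numpy(dtype=float)
    events = (
        1
        - np.maximum(
            tab["recurrence_censored"].to_numpy(), tab["detection_censored"].to_numpy()
        )
    ).astype(int)

    if censor_rate > 0.0 and events.sum() > 0:
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0xC3]))
        lam = _censor_rate_for(times[events == 1], censor_rate)
        c = rng.exponential(1.0 / lam, size=n)
        newly = (c < times) & (events == 1)
        times = np.where(newly, c, times)
        events = np.where(newly, 0, events)

    return pd.DataFrame(
        {
            "patient_id": [f"{cancer_type}-{master_seed}-{k:05d}" for k in range(n)],
            "cancer_type": cancer_type,
            "dfi_event": events,
            "dfi_days": times,
        }
    )
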