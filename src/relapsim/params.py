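"""Model parameterization.

The model couples a constant-size Moran process (normal Type0 cells and
premalignant Type1 cells, total N) to a supercritical branching process
of malignant Type2 cells.  All rates are per day; all times are days.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import yaml


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the tissue/tumor model.

    Parameters
    ----------
    N : int
        Number of cells in the homeostatic tissue (Type0 + Type1).
    delta : float
        Average turnover time of the whole tissue, days.  Turnover
        events (one cell dies, one divides) occur at rate ``N / delta``.
    r0, r1 : float
        Selection weights of Type0 / Type1 cells when a dividing cell is
        chosen (dimensionless; only their ratio matters).
    r2 : float
        Birth rate of a Type2 (cancer) cell, per cell per day.
    d2 : float or None
        Death rate of a Type2 cell, per cell per day.  ``None`` resolves
        to ``1/delta`` (death at the tissue turnover rate) — a package
        convention, always overridable.
    mu1 : float
        Probability that a dividing Type0 cell's daughter is Type1.
    mu2 : float
        Probability that a dividing Type1 cell's daughter is Type2.
    M_detect : float
        Tumor size (cells) at which detection/resection occurs.
    switch_multiplier : float
        Tumor growth is simulated stochastically below
        ``switch_multiplier * N`` cells and deterministically above.
    t_max : float
        Censoring horizon, days.  Trajectories exceeding it are reported
        censored, never raised as errors.
    """

    N: int
    delta: float = 1.0
    r0: float = 1.0
    r1: float = 1.0
    r2: float = 1.2
    d2: float | None = None
    mu1: float = 1e-3
    mu2: float = 1e-3
    M_detect: float = 1e9
    switch_multiplier: float = 2.0
    t_max: float = 1e5

    def __post_init__(self) -> None:
        if self.d2 is None:
            object.__setattr__(self, "d2", 1.0 / self.delta)
        if not (isinstance(self.N, (int,)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not (self.r0 > 0 and self.r1 > 0):
            raise ValueError("r0 and r1 must be positive")
        if not (self.r2 > self.d2 >= 0):
            raise ValueError(
                f"need supercritical tumor growth r2 > d2 >= 0, got r2={self.r2}, d2={self.d2}"
            )
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.M_detect > self.switch_multiplier * self.N:
            raise ValueError("M_detect must exceed switch_multiplier * N")
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")

    # -- convenience -------------------------------------------------
    @property
    def switch_size(self) -> int:
        """Tumor size at which growth becomes deterministic (default 2N)."""
        return int(round(self.switch_multiplier * self.N))

    @property
    def turnover_rate(self) -> float:
        """Rate of tissue turnover events, per day (= N / delta)."""
        return self.N / self.delta

    def replace(self, **kwargs: Any) -> "ModelParams":
        d = dataclasses.asdict(self)
        d.update(kwargs)
        return ModelParams(**d)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown parameter fields: {sorted(extra)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write as flat YAML or JSON mapping (by file extension)."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def classify_tissue(i: int, N: int) -> str:
    """Classify Type1 abundance: small (i <= 0.1N), large (i > 0.9N),
    else intermediate.  Boundaries use exact integer arithmetic."""
    if not 0 <= i <= N:
        raise ValueError(f"i must lie in [0, {N}], got {i}")
    if 10 * i <= N:
        return "small"
    if 10 * i > 9 * N:
        return "large"
    return "intermediate"


def deterministic_growth_time(params: ModelParams, x_start: float) -> float:
    """Time for the tumor to grow from ``x_start`` to detection size.

    Net exponential growth at rate r2 - d2:
    ``ln(M_detect / x_start) / (r2 - d2)``.
    """
    if x_start <= 0:
        raise ValueError("x_start must be positive")
    if x_start > params.M_detect:
        raise ValueError("x_start exceeds detection size")
    if params.r2 <= params.d2:
        raise ValueError("requires supercritical growth r2 > d2")
    return math.log(params.M_detect / x_start) / (params.r2 - params.d2)
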