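"""Mutable tissue/tumor state carried through a simulation."""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass
class TissueState:
    """Current state of one patient's tissue and tumor.

    Attributes
    ----------
    i : int
        Number of premalignant Type1 cells (0..N).
    x2 : int
        Number of malignant Type2 cells (>= 0).
    t : float
        Elapsed time, days.
    t_last_founding : float or None
        Time of the most recent 0 -> positive transition of x2 (i.e.
        when the currently growing tumor lineage was founded), or None
        if no tumor exists / after resection.
    """

    i: int = 0
    x2: int = 0
    t: float = 0.0
    t_last_founding: float | None = None

    def copy(self) -> "TissueState":
        return dataclasses.replace(self)
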