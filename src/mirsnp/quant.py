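"""Small wet-lab arithmetic layer: comparative-Ct fold change, caliper
tumour volume, and wound-closure percentage.

These are deterministic, unit-consistent pure functions over hand-entered
measurements; no image processing or efficiency-corrected quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CtMeasurement",
    "TumourMeasurement",
    "WoundMeasurement",
    "ddct_fold_change",
    "tumour_volume",
    "wound_closure_pct",
]


@dataclass(frozen=True)
class CtMeasurement:
    """qPCR threshold cycles for the comparative-Ct method.

    ``reference`` names the normalizer transcript (U6 for miRNA assays;
    GAPDH or Actin for mRNA) and is metadata only.
    """

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float
    reference: str = ""

    def __post_init__(self):
        vals = (
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all Ct values must be finite")


@dataclass(frozen=True)
class TumourMeasurement:
    """Caliper width and length in mm (length >= width by convention)."""

    width: float
    length: float

    def __post_init__(self):
        if self.width < 0 or self.length < 0:
            raise ValueError("tumour dimensions must be non-negative")


@dataclass(frozen=True)
class WoundMeasurement:
    """Remaining open wound width at time 0 and at time t (same units)."""

    open_width_t0: float
    open_width_t: float

    def __post_init__(self):
        if self.open_width_t0 <= 0:
            raise ValueError("baseline open width must be positive")
        if self.open_width_t < 0:
            raise ValueError("open width must be non-negative")


def ddct_fold_change(m: CtMeasurement) -> float:
    """Relative expression by the comparative threshold-cycle method.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator); returns 2**(-ddCt).
    Amplification efficiency is fixed at 2 (ideal doubling per cycle).
    """
    ddct = (m.ct_target_sample - m.ct_reference_sample) - (
        m.ct_target_calibrator - m.ct_reference_calibrator
    )
    return 2.0 ** (-ddct)


def tumour_volume(m: TumourMeasurement) -> float:
    """Volume in mm^3 from caliper measurements: width * length^2 / 2."""
    return m.width * m.length**2 / 2.0


def wound_closure_pct(m: WoundMeasurement, area: bool = False) -> float:
    """Percentage of wound closure relative to time 0.

    Measured on the remaining open width: 100 * (w0 - wt) / w0.  With
    ``area=True`` the widths are treated as the linear scale of an open
    area, giving 100 * (1 - (wt/w0)^2).  Values below 0 (the gap widened)
    are returned as-is.
    """
    if area:
        return 100.0 * (1.0 - (m.open_width_t / m.open_width_t0) ** 2)
    return 100.0 * (m.open_width_t0 - m.open_width_t) / m.open_width_t0
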