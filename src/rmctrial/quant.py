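"""Preclinical quantification formulas.

Corrected total cell fluorescence (CTCF) for imaging, caliper tumor
volume, body-weight change, tumor growth inhibition (TGI) for mouse
efficacy studies, and the ddCt fold change for qRT-PCR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "FluorescenceMeasurement",
    "TumorGrowthRecord",
    "ctcf",
    "body_weight_change",
    "tumor_growth_inhibition",
    "tumor_volume",
    "ddct_fold_change",
]

MIN_BACKGROUND_READINGS = 5


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """One cell's fluorescence readout with background context.

    ``background_means`` must carry at least five readings, matching the
    acquisition protocol of sampling five or more background areas per
    image.
    """

    integrated_density: float
    cell_area: float  # pixel^2
    background_means: Sequence[float]

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell area must be positive")
        if len(self.background_means) < MIN_BACKGROUND_READINGS:
            raise ValueError(
                f"need >= {MIN_BACKGROUND_READINGS} background readings, "
                f"got {len(self.background_means)}"
            )


@dataclass(frozen=True)
class TumorGrowthRecord:
    """Start/end tumor volume (mm^3) and body weight (g) for one arm."""

    arm: str  # "treatment" | "vehicle"
    v_start: float
    v_end: float
    bw_0: float | None = None
    bw_i: float | None = None

    def __post_init__(self) -> None:
        if self.v_start <= 0 or self.v_end <= 0:
            raise ValueError("volumes must be positive")


def ctcf(m: FluorescenceMeasurement) -> float:
    """CTCF = integrated density - cell area x mean background fluorescence.

    Negative values (background over-subtraction) are returned as-is;
    callers may flag them.
    """
    bg = sum(m.background_means) / len(m.background_means)
    return m.integrated_density - m.cell_area * bg


def body_weight_change(bw_0: float, bw_i: float) -> float:
    """Signed body-weight change percent: (BWi - BW0)/BW0 x 100."""
    if bw_0 <= 0:
        raise ValueError("baseline body weight must be positive")
    return (bw_i - bw_0) / bw_0 * 100.0


def tumor_growth_inhibition(
    trx: TumorGrowthRecord, veh: TumorGrowthRecord
) -> float:
    """TGI% = 100 - (dV_treatment / dV_vehicle x 100).

    Exceeds 100% for regressing tumors.  Undefined (error) when the
    vehicle arm shows no net growth.
    """
    dv_veh = veh.v_end - veh.v_start
    if dv_veh == 0:
        raise ZeroDivisionError("vehicle arm shows zero net growth")
    dv_trx = trx.v_end - trx.v_start
    return 100.0 - (dv_trx / dv_veh) * 100.0


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume, length x width^2 / 2 (mm^3)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    return length_mm * width_mm**2 / 2.0


def ddct_fold_change(
    ct_target_trx: float,
    ct_ref_trx: float,
    ct_target_ctl: float,
    ct_ref_ctl: float,
) -> float:
    """Relative expression 2^-ddCt from qRT-PCR cycle thresholds."""
    ddct = (ct_target_trx - ct_ref_trx) - (ct_target_ctl - ct_ref_ctl)
    return 2.0 ** (-ddct)
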