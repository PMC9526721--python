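"""Closed-form preclinical quantification metrics.

Walking-track sciatic function index (SFI), total regenerating axon counts
from optical-section sampling, pupillary light reflex constriction, qPCR
2^-ddCt fold change, and paired percent recovery.  These are scalar formulas
on measured quantities; units are explicit where mixing mm and um is a real
hazard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import UnitMismatchError

logger = logging.getLogger(__name__)


@dataclass
class FootprintMeasurements:
    """Hindlimb footprint distances, experimental (E) vs naive (N) side.

    PL: print length, heel to third toe.  TS: toe spread, first to fifth
    toe.  ITS: intermediary toe spread, second to fourth toe.  Any common
    length unit; only within-ratio consistency matters.
    """

    EPL: float
    NPL: float
    ETS: float
    NTS: float
    EITS: float
    NITS: float

    def __post_init__(self) -> None:
        for name in ("EPL", "NPL", "ETS", "NTS", "EITS", "NITS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def sciatic_function_index(m: FootprintMeasurements) -> float:
    """SFI = -38.3*(EPL-NPL)/NPL + 109.5*(ETS-NTS)/NTS + 13.3*(EITS-NITS)/NITS - 8.8

    Values near 0 indicate normal gait; near -100, severe motor impairment.
    """
    return (
        -38.3 * (m.EPL - m.NPL) / m.NPL
        + 109.5 * (m.ETS - m.NTS) / m.NTS
        + 13.3 * (m.EITS - m.NITS) / m.NITS
        - 8.8
    )


@dataclass
class AxonCountInputs:
    """Inputs for the optical-section axon count estimate.

    r is the optic-nerve cross-sectional radius, axons_per_width the average
    axon count per unit nerve width at the distance of interest, and t the
    optical section thickness (default 0.010 mm = 10 um).  All three carry a
    unit tag and must agree.
    """

    r: float
    axons_per_width: float
    t: float = 0.010
    r_unit: str = "mm"
    width_unit: str = "mm"
    t_unit: str = "mm"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.axons_per_width < 0:
            raise ValueError("axons_per_width must be >= 0")
        units = {self.r_unit, self.width_unit, self.t_unit}
        if len(units) != 1:
            raise UnitMismatchError(f"inconsistent units: {sorted(units)}")

    @classmethod
    def from_diameter(cls, diameter: float, axons_per_width: float, t: float = 0.010,
                      unit: str = "mm") -> "AxonCountInputs":
        """Convenience for protocols that measure the nerve's full width."""
        return cls(diameter / 2.0, axons_per_width, t,
                   r_unit=unit, width_unit=unit, t_unit=unit)


def total_regenerating_axons(x: AxonCountInputs) -> float:
    """Sum(a_d) = pi * r^2 * [axons per width] / t, unrounded."""
    return math.pi * x.r ** 2 * x.axons_per_width / x.t


def pupil_constriction_percent(baseline_area: float, stimulated_area: float) -> float:
    """Percent reduction in pupil area after a light stimulus.

    100 * (baseline - stimulated) / baseline.  Dilation (stimulated >
    baseline) returns a negative value with a logged warning.
    """
    if baseline_area <= 0:
        raise ValueError("baseline area must be > 0")
    if stimulated_area > baseline_area:
        logger.warning("stimulated pupil larger than baseline: reporting dilation")
    return 100.0 * (baseline_area - stimulated_area) / baseline_area


def pupil_constriction_percent_from_diameter(baseline_d: float, stimulated_d: float) -> float:
    """Diameter convenience wrapper: areas scale as diameter squared."""
    return pupil_constriction_percent(baseline_d ** 2, stimulated_d ** 2)


@dataclass
class QpcrInputs:
    """Cycle thresholds for target and reference genes in test and control."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_reference_test",
                     "ct_target_control", "ct_reference_control"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")


def ddct_fold_change(q: QpcrInputs) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_test -
    dCt_control; fold change = 2^-ddCt.
    """
    dct_test = q.ct_target_test - q.ct_reference_test
    dct_control = q.ct_target_control - q.ct_reference_control
    return 2.0 ** (-(dct_test - dct_control))


def paired_percent_recovery(measure_injured: float, measure_reference: float) -> float:
    """100 * injured / same-animal reference (e.g. CMAP vs own baseline)."""
    if measure_reference <= 0:
        raise ValueError("reference measure must be > 0")
    return 100.0 * measure_injured / measure_reference
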