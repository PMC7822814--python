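"""PO2 <-> T1 calibration for perfluoro-15-crown-5-ether (PFCE).

The longitudinal relaxation rate R1 = 1/T1 of PFCE increases linearly with
the partial pressure of dissolved oxygen, so an in vitro calibration maps a
fitted T1 directly to PO2:

    PO2 [mmHg] = a / T1 [s] - b

i.e. PO2 is affine in R1 with slope ``a`` (mmHg s) and intercept ``-b``
(mmHg).  The constants used here (a = 470.81, b = 200.14) come from an
in vitro calibration at 7 T and are treated as fixed inputs; no temperature
or field-strength correction is applied.

Out-of-range results (PO2 < 0 or > 760 mmHg) are physically impossible but
can arise from noise propagation through the T1 fit; conversion never clips
them — quality-control flagging is the caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OxygenCalibration", "DEFAULT_CALIBRATION", "t1_to_po2", "po2_to_t1"]


@dataclass(frozen=True)
class OxygenCalibration:
    """Affine PO2/R1 calibration: PO2 = slope / T1 - intercept.

    Attributes
    ----------
    slope : float
        Calibration slope in mmHg * s (PO2 per unit R1).
    intercept : float
        Calibration intercept in mmHg; PO2 = 0 at T1 = slope / intercept.
    """

    slope: float = 470.81
    intercept: float = 200.14

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.intercept <= 0:
            raise ValueError("calibration slope and intercept must be positive")

    @property
    def t1_at_zero_po2(self) -> float:
        """T1 (s) at which the calibrated PO2 crosses zero."""
        return self.slope / self.intercept


DEFAULT_CALIBRATION = OxygenCalibration()


def t1_to_po2(t1_s, calibration: OxygenCalibration = DEFAULT_CALIBRATION):
    """Convert T1 (s) to PO2 (mmHg) via the PFCE calibration.

    Accepts scalars or arrays.  T1 must be strictly positive; values are not
    clipped to the physiological range.
    """
    t1 = np.asarray(t1_s, dtype=float)
    if np.any(t1 <= 0) or not np.all(np.isfinite(t1)):
        raise ValueError("T1 must be finite and > 0")
    po2 = calibration.slope / t1 - calibration.intercept
    return float(po2) if np.isscalar(t1_s) else po2


def po2_to_t1(po2_mmhg, calibration: OxygenCalibration = DEFAULT_CALIBRATION):
    """Invert the calibration: T1 (s) = slope / (PO2 + intercept).

    Defined for PO2 > -intercept (the calibration's vertical asymptote);
    exact algebraic inverse of :func:`t1_to_po2`.
    """
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 <= -calibration.intercept) or not np.all(np.isfinite(po2)):
        raise ValueError(
            f"PO2 must be finite and > {-calibration.intercept:.2f} mmHg"
        )
    t1 = calibration.slope / (po2 + calibration.intercept)
    return float(t1) if np.isscalar(po2_mmhg) else t1
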