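"""Fucoidanase activity from PARAFAC dose scores, and HP-SEC MW calibration.

The FTIR dose-series assay defines one fucoidanase unit (U_f) as the amount
of enzyme that increases the one-component PARAFAC score by 0.01.  An
ordinary least-squares line is fitted through the (enzyme concentration,
dose score) points,

    score = a * conc + b,

the unit concentration ``c_unit`` solves the line at the 0.01 threshold
using |a| (the PARAFAC sign indeterminacy makes the sign of the printed
slope an orientation artifact), and the specific activity follows as

    U_f / uM = 1 / (k_scale * c_unit),

where ``k_scale`` (default 100) is the unit-scaling convention that links
the threshold concentration to the per-micromolar unit count.

The module also houses the size-exclusion calibration: a least-squares
polynomial mapping retention time to log10 molecular weight through
pullulan standards, with an extrapolation flag outside the standard range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "ActivityResult",
    "HpsecCalibration",
    "MwEstimate",
    "NoActivityError",
    "fit_score_calibration",
    "unit_concentration",
    "specific_activity",
    "compute_activity",
    "hpsec_calibrate",
    "estimate_mw",
]


class NoActivityError(ValueError):
    """Raised when the calibration cannot yield a positive unit concentration."""


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line through (dose, score) points: score = slope_a * dose + intercept_b."""

    slope_a: float
    intercept_b: float
    r_squared: float
    n_points: int
    points: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class ActivityResult:
    unit_threshold: float
    c_unit: float  # uM of enzyme that raises the score by the threshold
    k_scale: float
    specific_activity: float  # U_f per uM enzyme


def fit_score_calibration(doses, scores) -> CalibrationFit:
    """Ordinary least-squares calibration line through (dose, score) pairs."""
    doses = np.asarray(doses, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if doses.shape != scores.shape or doses.ndim != 1:
        raise ValueError("doses and scores must be 1-D and of equal length")
    if doses.size < 2:
        raise ValueError("at least two calibration points are required")
    if np.ptp(doses) == 0:
        raise ValueError("singular fit: all doses are equal")
    res = stats.linregress(doses, scores)
    fitted = res.intercept + res.slope * doses
    ss_res = float(np.sum((scores - fitted) ** 2))
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=r2,
        n_points=int(doses.size),
        points=tuple(zip(doses.tolist(), scores.tolist())),
    )


def unit_concentration(fit: CalibrationFit, unit_threshold: float = 0.01) -> float:
    """Enzyme concentration (uM) at which the calibration line reaches the
    unit threshold; uses |slope| so the result is orientation-free."""
    if fit.slope_a == 0:
        raise NoActivityError("zero calibration slope: no activity detected")
    c = (unit_threshold - fit.intercept_b) / abs(fit.slope_a)
    if c <= 0:
        raise NoActivityError(
            "activity too high to calibrate at this threshold "
            f"(c_unit = {c:.6g} uM <= 0)"
        )
    return c


def specific_activity(c_unit: float, k_scale: float = 100.0) -> float:
    """Specific activity in U_f/uM from the unit concentration."""
    if not c_unit > 0:
        raise NoActivityError(f"c_unit must be > 0, got {c_unit}")
    if not k_scale > 0:
        raise ValueError("k_scale must be > 0")
    return 1.0 / (k_scale * c_unit)


def compute_activity(
    fit: CalibrationFit,
    unit_threshold: float = 0.01,
    k_scale: float = 100.0,
) -> ActivityResult:
    c = unit_concentration(fit, unit_threshold)
    return ActivityResult(
        unit_threshold=unit_threshold,
        c_unit=c,
        k_scale=k_scale,
        specific_activity=specific_activity(c, k_scale),
    )


# ---------------------------------------------------------------------------
# HP-SEC molecular-weight calibration


@dataclass(frozen=True)
class HpsecCalibration:
    """Polynomial log10(MW/Da) = p(retention time / min), fitted to standards."""

    coefficients: tuple[float, ...]  # ascending powers
    degree: int
    standards: tuple[tuple[float, float], ...]  # (rt min, MW Da)
    rt_min: float
    rt_max: float
    monotone_decreasing: bool

    def log10_mw(self, rt: float) -> float:
        return float(np.polynomial.polynomial.polyval(rt, self.coefficients))


@dataclass(frozen=True)
class MwEstimate:
    mw_da: float
    log10_mw: float
    rt: float
    extrapolated: bool


def hpsec_calibrate(standards, degree: int = 3) -> HpsecCalibration:
    """Fit the log10-MW vs retention-time polynomial to external standards.

    Warns (without failing) when the fitted curve is not monotone-decreasing
    over the standard range, since later-eluting species should be smaller.
    """
    pts = [(float(rt), float(mw)) for rt, mw in standards]
    if any(mw <= 0 for _, mw in pts):
        raise ValueError("standard molecular weights must be > 0")
    if len(pts) <= degree:
        raise ValueError(
            f"need more than degree={degree} standards, got {len(pts)}"
        )
    rts = np.array([rt for rt, _ in pts])
    logmw = np.log10([mw for _, mw in pts])
    series = np.polynomial.Polynomial.fit(rts, logmw, deg=degree).convert()
    coeffs = tuple(float(c) for c in series.coef)
    grid = np.linspace(rts.min(), rts.max(), 512)
    deriv = series.deriv()(grid)
    monotone = bool(np.all(deriv <= 0))
    if not monotone:
        warnings.warn(
            "HP-SEC calibration is not monotone-decreasing over the standard "
            "range; molecular-weight estimates may be ambiguous",
            stacklevel=2,
        )
    return HpsecCalibration(
        coefficients=coeffs,
        degree=degree,
        standards=tuple(pts),
        rt_min=float(rts.min()),
        rt_max=float(rts.max()),
        monotone_decreasing=monotone,
    )


def estimate_mw(cal: HpsecCalibration, rt: float) -> MwEstimate:
    """Molecular weight (Da) at a retention time, flagging extrapolation."""
    log10_mw = cal.log10_mw(rt)
    return MwEstimate(
        mw_da=float(10.0**log10_mw),
        log10_mw=log10_mw,
        rt=float(rt),
        extrapolated=not (cal.rt_min <= rt <= cal.rt_max),
    )
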