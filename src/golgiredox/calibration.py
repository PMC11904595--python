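"""TRaQ-G calibration: fit the ratio-vs-[GSH] curve and invert it per cell.

The chemigenetic sensor pairs a GSH-reactive dye (TRaQ-G) with the
GSH-insensitive fluorescent protein mGold; the mGold/TRaQ-G ratio rises
with [GSH] and saturates.  An in-vitro dilution series at the Golgi pH
provides the calibration, modelled as a one-site saturating hyperbola

    ratio(c) = r0 + (r_max - r0) * c / (k_half + c)

with a shape-preserving monotone interpolant (PCHIP) as fallback when the
parametric fit fails to converge or to be monotone.  Per-cell ratios are
mapped through the inverse to absolute GSH concentrations with bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import interpolate, optimize

from .exceptions import InsufficientDataError, InvalidCalibrationError
from .imaging import CellRatioRecord
from .nernst import propagate_uncertainty

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CellGshEstimate",
    "GshQuantSummary",
    "fit_calibration",
    "invert_calibration",
    "quantify_cells",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration well: [GSH] vs. mean mGold/TRaQ-G ratio over FOVs."""

    gsh: float
    ratio_mean: float
    ratio_sd: float = 0.0
    n_fov: int = 1

    def __post_init__(self) -> None:
        if self.gsh < 0:
            raise ValueError("gsh must be nonnegative (molar)")
        if not self.ratio_mean > 0:
            raise ValueError("ratio_mean must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted, strictly monotone ratio([GSH]) relation.

    ``params`` is (r0, r_max, k_half) for the saturating model; for the
    interpolant fallback they are derived views (endpoint ratios and the
    concentration at the midpoint ratio).  ``valid_range`` is the fitted
    concentration interval; inversion outside it is extrapolation.
    """

    model: Literal["saturating", "monotone-interpolant"]
    r0: float
    r_max: float
    k_half: float
    fit_quality: float
    valid_range: Tuple[float, float]
    ratio_range: Tuple[float, float]
    _interpolant: Optional[object] = None

    def __post_init__(self) -> None:
        if self.r_max == self.r0:
            raise InvalidCalibrationError("flat calibration: r_max == r0")

    def predict(self, gsh: "float | np.ndarray") -> "float | np.ndarray":
        """Forward model: ratio expected at concentration ``gsh`` (molar)."""
        c = np.asarray(gsh, dtype=float)
        if self.model == "saturating":
            out = self.r0 + (self.r_max - self.r0) * c / (self.k_half + c)
        else:
            out = self._interpolant(np.clip(c, *self.valid_range))
        return float(out) if np.isscalar(gsh) else out


@dataclass(frozen=True)
class CellGshEstimate:
    """Per-cell absolute GSH estimate with bounds."""

    cell_id: int
    gsh: float
    gsh_lower: float
    gsh_upper: float
    extrapolated_flag: bool

    def __post_init__(self) -> None:
        if not (0 <= self.gsh_lower <= self.gsh <= self.gsh_upper):
            raise ValueError("bounds must satisfy lower <= gsh <= upper")


@dataclass(frozen=True)
class GshQuantSummary:
    """Cohort summary: median [GSH] over cells with a bootstrap interval."""

    cells: Tuple[CellGshEstimate, ...]
    gsh_median: float
    gsh_lower: float
    gsh_upper: float
    n_extrapolated: int


def _fit_saturating(
    conc: np.ndarray, ratios: np.ndarray
) -> Tuple[float, float, float]:
    r0_guess = float(ratios[np.argmin(conc)])
    rmax_guess = float(ratios[np.argmax(conc)])
    k_guess = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1e-3

    def model(c, r0, rmax, khalf):
        return r0 + (rmax - r0) * c / (khalf + c)

    popt, _ = optimize.curve_fit(
        model,
        conc,
        ratios,
        p0=[r0_guess, rmax_guess, k_guess],
        bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return tuple(float(v) for v in popt)  # type: ignore[return-value]


def fit_calibration(
    points: Sequence[CalibrationPoint],
    model: Literal["saturating", "interpolant"] = "saturating",
) -> CalibrationCurve:
    """Fit the calibration relation to ≥ 4 distinct concentrations.

    In ``saturating`` mode a least-squares hyperbola fit is attempted and a
    monotone interpolant is used as fallback if the fit fails to converge or
    the fitted curve is not strictly increasing.  In ``interpolant`` mode
    the ratio means must themselves be strictly monotone in concentration;
    offending points are reported otherwise.  ``fit_quality`` is
    1 − SS_res/SS_tot of the fitted curve on the calibration points.
    """
    pts = sorted(points, key=lambda p: p.gsh)
    conc = np.array([p.gsh for p in pts])
    ratios = np.array([p.ratio_mean for p in pts])
    if np.unique(conc).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {np.unique(conc).size}"
        )

    def quality(pred: np.ndarray) -> float:
        ss_tot = float(np.sum((ratios - ratios.mean()) ** 2))
        ss_res = float(np.sum((ratios - pred) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    if model == "saturating":
        try:
            r0, r_max, k_half = _fit_saturating(conc, ratios)
        except (RuntimeError, ValueError):
            r0 = r_max = k_half = None  # type: ignore[assignment]
        if r0 is not None and r_max > r0 and k_half > 0:
            curve = CalibrationCurve(
                model="saturating",
                r0=r0,
                r_max=r_max,
                k_half=k_half,
                fit_quality=quality(
                    r0 + (r_max - r0) * conc / (k_half + conc)
                ),
                valid_range=(float(conc.min()), float(conc.max())),
                ratio_range=(float(ratios.min()), float(ratios.max())),
            )
            return curve
        # fall through to the monotone interpolant

    diffs = np.diff(ratios)
    if np.any(diffs <= 0):
        bad = [
            f"[GSH]={pts[i + 1].gsh:g} M (ratio {pts[i + 1].ratio_mean:g} "
            f"after {pts[i].ratio_mean:g})"
            for i in np.flatnonzero(diffs <= 0)
        ]
        raise InvalidCalibrationError(
            "calibration ratios are not strictly increasing at: "
            + "; ".join(bad)
        )
    pchip = interpolate.PchipInterpolator(conc, ratios)
    mid_ratio = 0.5 * (ratios[0] + ratios[-1])
    k_half = float(
        optimize.brentq(
            lambda c: pchip(c) - mid_ratio, conc.min(), conc.max()
        )
    )
    return CalibrationCurve(
        model="monotone-interpolant",
        r0=float(ratios[0]),
        r_max=float(ratios[-1]),
        k_half=k_half,
        fit_quality=1.0,
        valid_range=(float(conc.min()), float(conc.max())),
        ratio_range=(float(ratios.min()), float(ratios.max())),
        _interpolant=pchip,
    )


def invert_calibration(
    curve: CalibrationCurve, ratio: float
) -> Tuple[float, bool]:
    """Map a measured ratio back to [GSH] (molar); flag extrapolation.

    For the saturating model the closed-form inverse
    c = k_half·(ratio − r0)/(r_max − ratio) is used; ratios below r0 floor
    at 0 and ratios at or above r_max return the upper end of the valid
    range, both flagged.  Ratios outside the fitted ratio range are
    inverted by extension and flagged extrapolated.
    """
    lo, hi = curve.ratio_range
    extrapolated = not (lo <= ratio <= hi)
    if curve.model == "saturating":
        if ratio >= curve.r_max:
            return curve.valid_range[1], True
        if ratio <= curve.r0:
            return 0.0, True
        c = curve.k_half * (ratio - curve.r0) / (curve.r_max - ratio)
        return max(c, 0.0), extrapolated
    # monotone interpolant: bracketed root inside the fitted range, clamped
    # endpoints outside it
    if ratio <= curve.predict(curve.valid_range[0]):
        return (0.0, True) if ratio < lo else (curve.valid_range[0], False)
    if ratio >= curve.predict(curve.valid_range[1]):
        return curve.valid_range[1], True
    c = float(
        optimize.brentq(
            lambda x: curve.predict(x) - ratio, *curve.valid_range
        )
    )
    return c, extrapolated


def quantify_cells(
    records: Sequence[CellRatioRecord],
    curve: CalibrationCurve,
    n_boot: int = 2000,
    seed: int = 0,
) -> GshQuantSummary:
    """Per-cell absolute [GSH] estimates and a cohort median with interval.

    The cohort interval is a percentile bootstrap of the median per-cell
    ratio mapped through the calibration inverse.  Per-cell bounds shift
    each cell's ratio by the bootstrap deltas of the cohort median before
    inversion, so they inherit both the calibration shape and the measured
    dispersion.
    """
    if not records:
        raise InsufficientDataError("no cell records to quantify")
    ratios = np.array([r.ratio for r in records])
    if ratios.size >= 3:
        med, r_lo, r_hi = propagate_uncertainty(
            ratios, n_boot=n_boot, seed=seed, statistic="median"
        )
    else:
        med = float(np.median(ratios))
        r_lo = r_hi = med
    d_lo, d_hi = med - r_lo, r_hi - med
    cells: List[CellGshEstimate] = []
    for rec in records:
        gsh, flag = invert_calibration(curve, rec.ratio)
        lower, _ = invert_calibration(curve, rec.ratio - d_lo)
        upper, _ = invert_calibration(curve, rec.ratio + d_hi)
        cells.append(
            CellGshEstimate(
                cell_id=rec.cell_id,
                gsh=gsh,
                gsh_lower=min(lower, gsh),
                gsh_upper=max(upper, gsh),
                extrapolated_flag=flag,
            )
        )
    gsh_median, _ = invert_calibration(curve, med)
    gsh_lower, _ = invert_calibration(curve, r_lo)
    gsh_upper, _ = invert_calibration(curve, r_hi)
    return GshQuantSummary(
        cells=tuple(cells),
        gsh_median=gsh_median,
        gsh_lower=min(gsh_lower, gsh_median),
        gsh_upper=max(gsh_upper, gsh_median),
        n_extrapolated=sum(c.extrapolated_flag for c in cells),
    )
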