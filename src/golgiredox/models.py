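"""Model/Results API over the three quantification arms.

Each arm is exposed as a model object built from data whose ``fit()``
returns a results object carrying estimates, uncertainties, diagnostics and
a ``summary()`` table:

* :class:`RoGfpRedoxModel` — per-cell 405/445 ratios under basal, reduced
  (DTT) and oxidized (H₂O₂) conditions → degree of sensor oxidation,
  E_GSH with a bootstrap interval, and Q = [GSH]²/[GSSG];
* :class:`GrxPrmModel` — light/heavy XIC traces of the glutaredoxin-probe
  peptide → [probe-SH]:[probe-SSG], fraction oxidized and R_GS;
* :class:`TraqGshModel` — calibration points plus per-cell mGold/TRaQ-G
  ratios → absolute [GSH] per cell and cohort median with interval.

Joint results combine into absolute pool concentrations via
:func:`combine_pool`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nernst
from .calibration import (
    CalibrationCurve,
    CalibrationPoint,
    GshQuantSummary,
    fit_calibration,
    quantify_cells,
)
from .exceptions import InsufficientDataError
from .imaging import CellRatioRecord, compare_conditions
from .nernst import (
    GRX_GOLGI,
    ROGFP1_IE,
    GlutathionePool,
    GrxEquilibrium,
    OxDValue,
    RatioCalibration,
    RedoxConstants,
    SensorSpec,
)
from .prm import LabelRatioResult, XICTrace, glutathionylation_ratio

__all__ = [
    "RoGfpRedoxModel",
    "RoGfpRedoxResults",
    "GrxPrmModel",
    "GrxPrmResults",
    "TraqGshModel",
    "TraqGshResults",
    "combine_pool",
]


def _records_frame(records: Sequence[CellRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "condition": [r.condition for r in records],
            "replicate_id": [r.replicate_id for r in records],
            "ratio": [r.ratio for r in records],
            "mean_num": [r.mean_num for r in records],
            "mean_den": [r.mean_den for r in records],
            "golgi_area": [r.golgi_area for r in records],
        }
    )


class RoGfpRedoxModel:
    """Golgi E_GSH from per-cell ratiometric roGFP measurements.

    Parameters
    ----------
    data : pandas.DataFrame
        Per-cell table with at least ``condition`` and ``ratio`` columns;
        a ``mean_den`` column enables estimating the I(445)min/max span
        from the oxidized/reduced denominator intensities.
    basal, reduced, oxidized : str
        Condition labels of the basal, fully reduced (DTT) and fully
        oxidized (H₂O₂) treatments.
    sensor : SensorSpec
        roGFP variant; defaults to roGFP1-iE with its working-pH midpoint.
    ph : float
        Organelle pH used for the midpoint correction (Golgi: 6.2).
    span_445 : float, optional
        I(445)min/I(445)max.  When omitted it is estimated as the ratio of
        median denominator intensities of oxidized vs. reduced cells.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        basal: str = "basal",
        reduced: str = "DTT",
        oxidized: str = "H2O2",
        sensor: SensorSpec = ROGFP1_IE,
        constants: RedoxConstants = RedoxConstants(),
        ph: float = 6.2,
        span_445: Optional[float] = None,
    ) -> None:
        required = {"condition", "ratio"}
        if not required.issubset(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        self.data = data.reset_index(drop=True)
        self.basal, self.reduced, self.oxidized = basal, reduced, oxidized
        self.sensor, self.constants, self.ph = sensor, constants, ph
        self.span_445 = span_445
        for cond in (basal, reduced, oxidized):
            if (data["condition"] == cond).sum() < 3:
                raise InsufficientDataError(
                    f"need >= 3 cells in condition {cond!r}"
                )

    @classmethod
    def from_records(
        cls, records: Sequence[CellRatioRecord], **kwargs
    ) -> "RoGfpRedoxModel":
        return cls(_records_frame(records), **kwargs)

    def fit(self, n_boot: int = 2000, seed: int = 0) -> "RoGfpRedoxResults":
        df = self.data
        sel = {
            cond: df.loc[df["condition"] == cond]
            for cond in (self.basal, self.reduced, self.oxidized)
        }
        r_red = float(sel[self.reduced]["ratio"].median())
        r_ox = float(sel[self.oxidized]["ratio"].median())
        r_basal = float(sel[self.basal]["ratio"].median())
        if self.span_445 is not None:
            span = self.span_445
        elif "mean_den" in df.columns:
            span = float(
                sel[self.oxidized]["mean_den"].median()
                / sel[self.reduced]["mean_den"].median()
            )
            span = float(np.clip(span, 1e-3, 1.0))
        else:
            span = 1.0
        e0 = nernst.midpoint_at_ph(self.sensor, self.ph, self.constants)

        basal_ratios = sel[self.basal]["ratio"].to_numpy()
        per_cell = []
        n_clamped = 0
        for r in basal_ratios:
            oxd_i = nernst.oxd_from_ratios(
                RatioCalibration(
                    r_basal=float(r), r_red=r_red, r_ox=r_ox, span_445=span
                )
            )
            n_clamped += oxd_i.clamped_flag
            per_cell.append(
                nernst.e_gsh_from_oxd(oxd_i, e0, self.constants)
            )
        per_cell_e = np.asarray(per_cell)
        e_gsh, e_lo, e_hi = nernst.propagate_uncertainty(
            per_cell_e, n_boot=n_boot, seed=seed, statistic="median"
        )
        cal = RatioCalibration(
            r_basal=r_basal, r_red=r_red, r_ox=r_ox, span_445=span
        )
        oxd = nernst.oxd_from_ratios(cal)
        tests = {
            f"{self.basal} vs {other}": compare_conditions(
                basal_ratios, sel[other]["ratio"].to_numpy()
            )
            for other in (self.oxidized, self.reduced)
        }
        return RoGfpRedoxResults(
            model=self,
            calibration=cal,
            e0=e0,
            oxd=oxd,
            e_gsh=e_gsh,
            e_gsh_interval=(e_lo, e_hi),
            q=nernst.q_from_e_gsh(e_gsh, e0, self.constants),
            per_cell_e=per_cell_e,
            n_clamped=int(n_clamped),
            condition_tests=tests,
        )


@dataclass(frozen=True)
class RoGfpRedoxResults:
    """Fitted E_GSH, its interval, the OxD diagnostics and Q."""

    model: RoGfpRedoxModel
    calibration: RatioCalibration
    e0: float
    oxd: OxDValue
    e_gsh: float
    e_gsh_interval: Tuple[float, float]
    q: float
    per_cell_e: np.ndarray
    n_clamped: int
    condition_tests: Dict[str, Tuple[float, float]]

    def pool(self, r_gs: float) -> GlutathionePool:
        """Absolute pool from this fit's Q and an external R_GS."""
        return nernst.pool_from_q_and_rgs(self.q, r_gs)

    def summary(self) -> str:
        cal = self.calibration
        lines = [
            "roGFP redox state (ratiometric, per-cell)",
            "=" * 45,
            f"sensor                {self.model.sensor.name} (E0' = {self.e0:.1f} mV at pH {self.model.ph})",
            f"cells (basal)         {self.per_cell_e.size}  [clamped OxD: {self.n_clamped}]",
            f"R_red / R / R_ox      {cal.r_red:.4f} / {cal.r_basal:.4f} / {cal.r_ox:.4f}",
            f"I(445)min/max span    {cal.span_445:.4f}",
            f"OxD (basal)           {self.oxd.oxd:.4f}",
            f"E_GSH                 {self.e_gsh:.1f} mV  "
            f"[{self.e_gsh_interval[0]:.1f}, {self.e_gsh_interval[1]:.1f}]",
            f"Q = [GSH]^2/[GSSG]    {self.q * 1e3:.1f} mM",
        ]
        for name, (u, p) in self.condition_tests.items():
            lines.append(f"Mann-Whitney {name:<18} U = {u:.1f}, p = {p:.3g}")
        return "\n".join(lines)


class GrxPrmModel:
    """R_GS from light/heavy XIC traces of the glutaredoxin-probe peptide."""

    def __init__(
        self,
        light: XICTrace,
        heavy: XICTrace,
        grx: GrxEquilibrium = GRX_GOLGI,
        rt_window: Optional[Tuple[float, float]] = None,
        unmodified: Optional[XICTrace] = None,
    ) -> None:
        self.light, self.heavy = light, heavy
        self.grx, self.rt_window = grx, rt_window
        self.unmodified = unmodified

    def fit(self) -> "GrxPrmResults":
        ratio = glutathionylation_ratio(
            self.light,
            self.heavy,
            grx=self.grx,
            rt_window=self.rt_window,
            unmodified=self.unmodified,
        )
        return GrxPrmResults(model=self, label_ratio=ratio)


@dataclass(frozen=True)
class GrxPrmResults:
    """Integrated areas, the light:heavy ratio and the derived R_GS."""

    model: GrxPrmModel
    label_ratio: LabelRatioResult

    @property
    def r_gs(self) -> float:
        return self.label_ratio.r_gs

    @property
    def sh_to_ssg(self) -> float:
        return self.label_ratio.sh_to_ssg

    def summary(self) -> str:
        lr = self.label_ratio
        return "\n".join(
            [
                "Glutaredoxin-probe PRM quantification (y14++ XIC)",
                "=" * 49,
                f"area (light, probe-SH)    {lr.area_light:.4g}",
                f"area (heavy, probe-SSG)   {lr.area_heavy:.4g}",
                f"[SH]:[SSG]                {lr.sh_to_ssg:.4f}",
                f"fraction oxidized         {lr.fraction_oxidized:.4f}",
                f"K_ox                      {self.model.grx.k_ox:.0f}",
                f"R_GS = [GSH]/[GSSG]       {lr.r_gs:.1f}",
                f"unmodified peptide        "
                f"{'detected' if lr.unmodified_detected else 'below LOD / not monitored'}",
            ]
        )


class TraqGshModel:
    """Absolute [GSH] from TRaQ-G ratios via a fitted calibration curve."""

    def __init__(
        self,
        calibration_points: Sequence[CalibrationPoint],
        cell_records: Sequence[CellRatioRecord],
        model: str = "saturating",
    ) -> None:
        self.calibration_points = list(calibration_points)
        self.cell_records = list(cell_records)
        self.calibration_model = model

    def fit(self, n_boot: int = 2000, seed: int = 0) -> "TraqGshResults":
        curve = fit_calibration(
            self.calibration_points, model=self.calibration_model  # type: ignore[arg-type]
        )
        quant = quantify_cells(
            self.cell_records, curve, n_boot=n_boot, seed=seed
        )
        return TraqGshResults(model=self, curve=curve, quant=quant)


@dataclass(frozen=True)
class TraqGshResults:
    """Fitted calibration curve plus per-cell and cohort [GSH] estimates."""

    model: TraqGshModel
    curve: CalibrationCurve
    quant: GshQuantSummary

    @property
    def gsh_median(self) -> float:
        return self.quant.gsh_median

    def summary(self) -> str:
        c, q = self.curve, self.quant
        return "\n".join(
            [
                "TRaQ-G absolute GSH quantification",
                "=" * 40,
                f"calibration model      {c.model}",
                f"r0 / r_max / k_half    {c.r0:.3f} / {c.r_max:.3f} / "
                f"{c.k_half * 1e3:.3f} mM",
                f"fit quality (R^2)      {c.fit_quality:.4f}",
                f"cells                  {len(q.cells)}  "
                f"[extrapolated: {q.n_extrapolated}]",
                f"[GSH] median           {q.gsh_median * 1e3:.2f} mM  "
                f"[{q.gsh_lower * 1e3:.2f}, {q.gsh_upper * 1e3:.2f}]",
            ]
        )


def combine_pool(
    rogfp: RoGfpRedoxResults, prm: GrxPrmResults
) -> GlutathionePool:
    """Absolute Golgi pool from the roGFP potential and the probe's R_GS."""
    return rogfp.pool(prm.r_gs)
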