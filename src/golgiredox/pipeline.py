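"""End-to-end orchestration of the three quantification arms.

``run_pipeline`` executes the requested arms from a
:class:`PipelineConfig` and assembles a summary table in the shape of the
reference results table (one row per quantity: E_GSH, Q, R_GS, [GS],
[GSH], each with its method tag and interval).  When no input files are
configured, each arm simulates its own inputs from the configured ground
truth and analyses them with the full pipeline — the standard self-check
mode.

Every numeric in the summary is traceable through the structured log
(cells found, cells excluded and why, clamp events, areas integrated).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io, nernst
from .calibration import CalibrationPoint
from .exceptions import ConfigError
from .imaging import (
    CellRatioRecord,
    ExclusionRecord,
    FieldOfView,
    correct_background,
    per_cell_ratio_table,
    segment_cells,
    segment_golgi,
)
from .models import (
    GrxPrmModel,
    GrxPrmResults,
    RoGfpRedoxModel,
    RoGfpRedoxResults,
    TraqGshModel,
    TraqGshResults,
    combine_pool,
)
from .nernst import (
    GrxEquilibrium,
    RedoxConstants,
    SensorSpec,
    oxd_from_e_gsh,
    ratio_from_oxd,
)
from .prm import build_target_list
from .synth import (
    ImagingScenario,
    XicScenario,
    simulate_calibration_plate,
    simulate_fov,
    simulate_xic_pair,
)
from .calibration import fit_calibration

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "make_table1_report",
    "SIM_ANCHORS",
]

_MODES = ("rogfp", "traqg", "prm", "all", "simulate")

#: Dynamic-range anchors of the simulated ratiometric sensor:
#: (R_red, R_ox, I(445)min/I(445)max).
SIM_ANCHORS = (0.2, 2.0, 0.5)

#: Ground-truth calibration of the simulated TRaQ-G sensor:
#: (r0, r_max, k_half in molar).
SIM_TRAQG_CURVE = (1.0, 5.0, 2.0e-3)

#: Calibration-plate GSH concentrations (molar), including a
#: blank-adjacent low point.
SIM_PLATE_CONCS = (0.25e-3, 0.5e-3, 1.0e-3, 2.0e-3, 4.0e-3, 8.0e-3)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (see ``load``/``from_dict``)."""

    mode: str = "all"
    out_dir: Optional[str] = None
    seed: int = 0
    # assay conditions
    ph: float = 6.2
    temperature_K: float = 310.15
    sensor_name: str = "roGFP1-iE"
    midpoint_ph7_mV: float = -236.0
    midpoint_override_mV: Optional[float] = -190.0
    k_ox: float = 234.0
    n_boot: int = 2000
    calibration_model: str = "saturating"
    # segmentation / integration parameters
    block: int = 600
    threshold_k: float = 2.0
    spot_radius: int = 5
    min_cell_area: int = 200
    min_golgi_area: int = 10
    den_floor: Optional[float] = None
    rt_window_min: Optional[float] = None
    rt_window_max: Optional[float] = None
    baseline: str = "median"
    # optional input files (when absent, arms simulate their inputs)
    rogfp_manifest: Optional[str] = None
    traqg_manifest: Optional[str] = None
    calibration_csv: Optional[str] = None
    xic_csv: Optional[str] = None
    # simulation ground truth / sizes
    sim_true_e_gsh_mV: float = -157.0
    sim_true_gsh_M: float = 2.7e-3
    sim_true_sh_to_ssg: float = 0.06
    sim_n_cells: int = 60
    sim_replicates: int = 3
    sim_block: int = 64
    sim_dispersion: float = 0.10
    sim_traqg_dispersion: float = 0.20
    sim_traqg_cells_per_fov: int = 50
    sim_traqg_fovs: int = 3
    sim_xic_snr: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not 4.0 <= self.ph <= 9.0:
            raise ConfigError(f"pH {self.ph} outside [4, 9]")
        for name in ("rogfp_manifest", "traqg_manifest", "calibration_csv", "xic_csv"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_dict(cls, values: Dict[str, object]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)  # type: ignore[arg-type]

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        return cls.from_dict(io.load_flat_config(path))

    @property
    def constants(self) -> RedoxConstants:
        return RedoxConstants(temperature=self.temperature_K)

    @property
    def sensor(self) -> SensorSpec:
        return SensorSpec(
            self.sensor_name, self.midpoint_ph7_mV, self.midpoint_override_mV
        )

    @property
    def grx(self) -> GrxEquilibrium:
        return GrxEquilibrium(k_ox=self.k_ox)

    @property
    def rt_window(self) -> Optional[Tuple[float, float]]:
        if self.rt_window_min is None or self.rt_window_max is None:
            return None
        return (self.rt_window_min, self.rt_window_max)


@dataclass
class PipelineResult:
    """Summary table plus per-arm results and the structured log."""

    summary: pd.DataFrame
    rogfp: Optional[RoGfpRedoxResults] = None
    traqg: Optional[TraqGshResults] = None
    prm: Optional[GrxPrmResults] = None
    log: List[str] = field(default_factory=list)


def _analyze_fovs(
    fovs: Sequence[FieldOfView],
    block: int,
    threshold_k: float,
    spot_radius: int,
    min_cell_area: int,
    min_golgi_area: int,
    den_floor: Optional[float],
    log: List[str],
) -> Tuple[List[CellRatioRecord], List[ExclusionRecord]]:
    """Run the imaging pipeline on each field and pool per-cell records."""
    records: List[CellRatioRecord] = []
    exclusions: List[ExclusionRecord] = []
    for fov in fovs:
        num = correct_background(fov.numerator, block=block)
        den = correct_background(fov.denominator, block=block)
        corrected = FieldOfView(
            channels=(num, den),
            channel_labels=fov.channel_labels,
            condition=fov.condition,
            replicate_id=fov.replicate_id,
        )
        cells = segment_cells(
            den, k=threshold_k, min_cell_area=min_cell_area
        )
        seg = segment_golgi(
            den,
            cells,
            spot_scale=spot_radius,
            k=threshold_k,
            min_golgi_area=min_golgi_area,
        )
        recs, excl = per_cell_ratio_table(corrected, seg, den_floor=den_floor)
        log.append(
            f"[{fov.condition}/{fov.replicate_id}] cells={int(cells.max())} "
            f"golgi_groups={len(seg.golgi_to_cell)} records={len(recs)} "
            f"excluded={len(excl)}"
        )
        records.extend(recs)
        exclusions.extend(excl)
    return records, exclusions


def _simulate_rogfp_fovs(
    config: PipelineConfig,
) -> List[FieldOfView]:
    """Simulated basal/oxidized/reduced fields at the configured truth."""
    consts = config.constants
    e0 = nernst.midpoint_at_ph(config.sensor, config.ph, consts)
    r_red, r_ox, span = SIM_ANCHORS
    oxd_basal = oxd_from_e_gsh(config.sim_true_e_gsh_mV, e0, consts).oxd
    cond_oxd = {"basal": oxd_basal, "H2O2": 1.0, "DTT": 0.0}
    ratios = {
        c: ratio_from_oxd(x, r_red, r_ox, span) for c, x in cond_oxd.items()
    }
    den_scales = {c: (1.0 - x) + x * span for c, x in cond_oxd.items()}
    scenario = ImagingScenario(
        n_cells=config.sim_n_cells,
        true_ratio_per_condition=ratios,
        den_scale_per_condition=den_scales,
        dispersion=config.sim_dispersion,
        seed=config.seed,
    )
    fovs = []
    for condition in cond_oxd:
        for rep in range(1, config.sim_replicates + 1):
            fov, _ = simulate_fov(scenario, condition, replicate_id=f"R{rep}")
            fovs.append(fov)
    return fovs


def _run_rogfp(config: PipelineConfig, log: List[str]) -> Tuple[
    RoGfpRedoxResults, List[CellRatioRecord], List[ExclusionRecord]
]:
    if config.rogfp_manifest is not None:
        manifest = io.read_manifest(config.rogfp_manifest)
        base = os.path.dirname(os.path.abspath(config.rogfp_manifest))
        fovs = [
            io.read_fov_tiff(
                os.path.join(base, str(row.path)),
                condition=str(row.condition),
                replicate_id=str(row.replicate_id),
            )
            for row in manifest.itertuples()
        ]
        block = config.block
    else:
        fovs = _simulate_rogfp_fovs(config)
        block = config.sim_block
        log.append(
            f"[rogfp] simulated inputs at true E_GSH = "
            f"{config.sim_true_e_gsh_mV} mV"
        )
    records, exclusions = _analyze_fovs(
        fovs,
        block,
        config.threshold_k,
        config.spot_radius,
        config.min_cell_area,
        config.min_golgi_area,
        config.den_floor,
        log,
    )
    model = RoGfpRedoxModel.from_records(
        records,
        sensor=config.sensor,
        constants=config.constants,
        ph=config.ph,
    )
    result = model.fit(n_boot=config.n_boot, seed=config.seed)
    log.append(
        f"[rogfp] n_basal={result.per_cell_e.size} clamped={result.n_clamped} "
        f"E_GSH={result.e_gsh:.2f} mV"
    )
    return result, records, exclusions


def _run_traqg(config: PipelineConfig, log: List[str]) -> Tuple[
    TraqGshResults, List[CellRatioRecord], List[ExclusionRecord]
]:
    if config.calibration_csv is not None:
        points = io.read_calibration_csv(config.calibration_csv)
    else:
        points = simulate_calibration_plate(
            *SIM_TRAQG_CURVE,
            concentrations=SIM_PLATE_CONCS,
            seed=config.seed,
        )
        log.append("[traqg] simulated calibration plate")
    if config.traqg_manifest is not None:
        manifest = io.read_manifest(config.traqg_manifest)
        base = os.path.dirname(os.path.abspath(config.traqg_manifest))
        fovs = [
            io.read_fov_tiff(
                os.path.join(base, str(row.path)),
                condition=str(row.condition),
                replicate_id=str(row.replicate_id),
                channel_labels=("mGold", "TRaQ-G"),
            )
            for row in manifest.itertuples()
        ]
        block = config.block
    else:
        truth_curve = fit_calibration(
            simulate_calibration_plate(
                *SIM_TRAQG_CURVE,
                concentrations=SIM_PLATE_CONCS,
                rel_noise=0.0,
                seed=config.seed,
            )
        )
        scenario = ImagingScenario(
            n_cells=config.sim_traqg_cells_per_fov,
            true_ratio_per_condition={},
            true_gsh_per_condition={"basal": config.sim_true_gsh_M},
            calibration=truth_curve,
            dispersion=config.sim_traqg_dispersion,
            seed=config.seed + 1,
        )
        fovs = [
            simulate_fov(scenario, "basal", replicate_id=f"R{rep}")[0]
            for rep in range(1, config.sim_traqg_fovs + 1)
        ]
        block = config.sim_block
        log.append(
            f"[traqg] simulated cells at true [GSH] = "
            f"{config.sim_true_gsh_M * 1e3:.2f} mM"
        )
    records, exclusions = _analyze_fovs(
        fovs,
        block,
        config.threshold_k,
        config.spot_radius,
        config.min_cell_area,
        config.min_golgi_area,
        config.den_floor,
        log,
    )
    model = TraqGshModel(points, records, model=config.calibration_model)
    result = model.fit(n_boot=config.n_boot, seed=config.seed)
    log.append(
        f"[traqg] n_cells={len(result.quant.cells)} "
        f"extrapolated={result.quant.n_extrapolated} "
        f"[GSH]={result.gsh_median * 1e3:.3f} mM"
    )
    return result, records, exclusions


def _run_prm(config: PipelineConfig, log: List[str]) -> GrxPrmResults:
    # Validate the computed target masses before any quantification; a
    # disagreement with the reference table is fatal.
    targets = build_target_list()
    log.append(f"[prm] target list validated ({len(targets)} ions)")
    if config.xic_csv is not None:
        traces = io.read_xic_csv(config.xic_csv)
        try:
            light = traces[("y14", "light")]
            heavy = traces[("y14", "heavy")]
        except KeyError as exc:
            raise ConfigError(
                "XIC CSV must contain target_id 'y14' with labels "
                "'light' and 'heavy'"
            ) from exc
    else:
        light, heavy = simulate_xic_pair(
            XicScenario(
                true_sh_to_ssg=config.sim_true_sh_to_ssg,
                snr=config.sim_xic_snr,
                seed=config.seed,
            )
        )
        log.append(
            f"[prm] simulated XIC pair at true SH:SSG = "
            f"{config.sim_true_sh_to_ssg}"
        )
    model = GrxPrmModel(
        light, heavy, grx=config.grx, rt_window=config.rt_window
    )
    result = model.fit()
    log.append(
        f"[prm] areas L/H = {result.label_ratio.area_light:.4g}/"
        f"{result.label_ratio.area_heavy:.4g} R_GS={result.r_gs:.2f}"
    )
    return result


def _summary_rows(
    dataset: str,
    rogfp: Optional[RoGfpRedoxResults],
    traqg: Optional[TraqGshResults],
    prm: Optional[GrxPrmResults],
) -> List[Dict[str, object]]:
    rows: List[Dict[str, object]] = []
    if rogfp is not None:
        lo, hi = rogfp.e_gsh_interval
        rows.append(
            dict(
                dataset=dataset,
                quantity="E_GSH_mV",
                value=rogfp.e_gsh,
                lower=lo,
                upper=hi,
                method="roGFP",
            )
        )
        rows.append(
            dict(
                dataset=dataset,
                quantity="Q_M",
                value=rogfp.q,
                lower=np.nan,
                upper=np.nan,
                method="roGFP",
            )
        )
    if prm is not None:
        rows.append(
            dict(
                dataset=dataset,
                quantity="R_GS",
                value=prm.r_gs,
                lower=np.nan,
                upper=np.nan,
                method="sCGrx1p",
            )
        )
    if rogfp is not None and prm is not None:
        pool = combine_pool(rogfp, prm)
        rows.append(
            dict(
                dataset=dataset,
                quantity="GS_total_M",
                value=pool.gs_total,
                lower=np.nan,
                upper=np.nan,
                method="roGFP and sCGrx1p",
            )
        )
    if traqg is not None:
        rows.append(
            dict(
                dataset=dataset,
                quantity="GSH_M",
                value=traqg.gsh_median,
                lower=traqg.quant.gsh_lower,
                upper=traqg.quant.gsh_upper,
                method="TRaQ-G",
            )
        )
    return rows


def make_table1_report(summary: pd.DataFrame) -> str:
    """Plain-text results table: one row per quantity with its method."""
    if summary.empty:
        raise ValueError("summary table is empty")
    display = {
        "E_GSH_mV": ("E_GSH", "mV", 1.0, "{:.1f}"),
        "Q_M": ("[GSH]2:[GSSG]", "mM", 1e3, "{:.1f}"),
        "R_GS": ("R_GS", "", 1.0, "{:.1f}"),
        "GS_total_M": ("[GS]", "mM", 1e3, "{:.2f}"),
        "GSH_M": ("[GSH]", "mM", 1e3, "{:.2f}"),
    }
    lines = [
        f"{'Quantity':<16}{'Method':<20}{'Dataset':<14}{'Value':>12}  Interval",
        "-" * 76,
    ]
    for _, row in summary.iterrows():
        name, unit, scale, fmt = display.get(
            row["quantity"], (row["quantity"], "", 1.0, "{:.4g}")
        )
        value = fmt.format(row["value"] * scale)
        if np.isfinite(row.get("lower", np.nan)) and np.isfinite(
            row.get("upper", np.nan)
        ):
            interval = (
                f"[{fmt.format(row['lower'] * scale)}, "
                f"{fmt.format(row['upper'] * scale)}]"
            )
        else:
            interval = "-"
        lines.append(
            f"{name:<16}{row['method']:<20}{str(row['dataset']):<14}"
            f"{value + (' ' + unit if unit else ''):>12}  {interval}"
        )
    return "\n".join(lines)


def _write_redox_csv(
    path: str,
    rogfp: RoGfpRedoxResults,
    r_gs: Optional[float],
    config: PipelineConfig,
) -> None:
    """Per-cell chemistry table for the basal population."""
    consts = config.constants
    model = rogfp.model
    basal = model.data.loc[model.data["condition"] == model.basal]
    rows = []
    for (_, cell), e_cell in zip(basal.iterrows(), rogfp.per_cell_e):
        oxd_i = nernst.oxd_from_e_gsh(e_cell, rogfp.e0, consts)
        q_i = nernst.q_from_e_gsh(e_cell, rogfp.e0, consts)
        if r_gs is not None:
            pool = nernst.pool_from_q_and_rgs(q_i, r_gs)
            gsh, gssg, gs = pool.gsh, pool.gssg, pool.gs_total
        else:
            gsh = gssg = gs = np.nan
        rows.append(
            dict(
                cell_id=cell.get("cell_id", -1),
                condition=model.basal,
                ratio=cell["ratio"],
                oxd=oxd_i.oxd,
                e_gsh_mV=e_cell,
                q_M=q_i,
                r_gs=r_gs if r_gs is not None else np.nan,
                gsh_M=gsh,
                gssg_M=gssg,
                gs_total_M=gs,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, dataset: str = "simulated") -> PipelineResult:
    """Execute the requested arms and assemble the summary table.

    In ``simulate`` mode the synthetic inputs are written to ``out_dir``
    (TIFF fields + manifest, calibration CSV, XIC CSV) without analysis.
    Otherwise each requested arm runs end to end; with an ``out_dir`` set,
    per-cell records, exclusion logs, the summary CSV, the formatted text
    table and the structured log are written there.
    """
    log: List[str] = []
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)

    if config.mode == "simulate":
        if not out:
            raise ConfigError("simulate mode requires out_dir")
        _write_simulated_inputs(config, out, log)
        with open(os.path.join(out, "log.txt"), "w") as fh:
            fh.write("\n".join(log) + "\n")
        return PipelineResult(summary=pd.DataFrame(), log=log)

    rogfp = traqg = prm = None
    rogfp_records: List[CellRatioRecord] = []
    rogfp_excl: List[ExclusionRecord] = []
    if config.mode in ("rogfp", "all"):
        rogfp, rogfp_records, rogfp_excl = _run_rogfp(config, log)
    if config.mode in ("traqg", "all"):
        traqg, traqg_records, traqg_excl = _run_traqg(config, log)
        if out:
            io.write_records_csv(
                os.path.join(out, "traqg_cell_records.csv"), traqg_records
            )
            io.write_exclusions_csv(
                os.path.join(out, "traqg_exclusions.csv"), traqg_excl
            )
    if config.mode in ("prm", "all"):
        prm = _run_prm(config, log)

    summary = pd.DataFrame(
        _summary_rows(dataset, rogfp, traqg, prm),
        columns=["dataset", "quantity", "value", "lower", "upper", "method"],
    )
    if out:
        if rogfp_records:
            io.write_records_csv(
                os.path.join(out, "rogfp_cell_records.csv"), rogfp_records
            )
            io.write_exclusions_csv(
                os.path.join(out, "rogfp_exclusions.csv"), rogfp_excl
            )
        if rogfp is not None:
            _write_redox_csv(
                os.path.join(out, "redox_per_cell.csv"),
                rogfp,
                prm.r_gs if prm is not None else None,
                config,
            )
        summary.to_csv(os.path.join(out, "summary.csv"), index=False)
        if not summary.empty:
            with open(os.path.join(out, "summary.txt"), "w") as fh:
                fh.write(make_table1_report(summary) + "\n")
        with open(os.path.join(out, "log.txt"), "w") as fh:
            fh.write("\n".join(log) + "\n")
    return PipelineResult(
        summary=summary, rogfp=rogfp, traqg=traqg, prm=prm, log=log
    )


def _write_simulated_inputs(
    config: PipelineConfig, out: str, log: List[str]
) -> None:
    fovs = _simulate_rogfp_fovs(config)
    manifest_rows = []
    for i, fov in enumerate(fovs):
        name = f"rogfp_{fov.condition}_{fov.replicate_id}.tiff"
        io.write_fov_tiff(os.path.join(out, name), fov)
        manifest_rows.append(
            dict(
                field_id=f"F{i:02d}",
                path=name,
                condition=fov.condition,
                replicate_id=fov.replicate_id,
                channel_num="ex405",
                channel_den="ex445",
            )
        )
    io.write_manifest(os.path.join(out, "rogfp_manifest.csv"), manifest_rows)
    points = simulate_calibration_plate(
        *SIM_TRAQG_CURVE, concentrations=SIM_PLATE_CONCS, seed=config.seed
    )
    io.write_calibration_csv(os.path.join(out, "calibration.csv"), points)
    light, heavy = simulate_xic_pair(
        XicScenario(
            true_sh_to_ssg=config.sim_true_sh_to_ssg,
            snr=config.sim_xic_snr,
            seed=config.seed,
        )
    )
    io.write_xic_csv(
        os.path.join(out, "xic_traces.csv"),
        {("y14", "light"): light, ("y14", "heavy"): heavy},
    )
    log.append(
        f"[simulate] wrote {len(fovs)} fields, calibration plate and XIC pair"
    )
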