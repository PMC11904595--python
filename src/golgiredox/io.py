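"""File formats: multichannel TIFF fields, manifests, CSV tables, config.

Fields are stored as one TIFF per field with the two channels as planes,
plus a sidecar manifest CSV (field_id, path, condition, replicate_id,
channel_num, channel_den).  XIC traces and calibration plates travel as
plain CSV.  The pipeline config is a flat YAML key-value file.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationPoint, CellGshEstimate
from .imaging import CellRatioRecord, ExclusionRecord, FieldOfView
from .prm import XICTrace

__all__ = [
    "write_fov_tiff",
    "read_fov_tiff",
    "write_manifest",
    "read_manifest",
    "write_records_csv",
    "read_records_csv",
    "write_exclusions_csv",
    "write_xic_csv",
    "read_xic_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "load_flat_config",
    "write_flat_config",
]


def write_fov_tiff(path: str, fov: FieldOfView) -> None:
    """Write the two channel planes as a float32 TIFF stack."""
    stack = np.stack(
        [fov.numerator.astype(np.float32), fov.denominator.astype(np.float32)]
    )
    tifffile.imwrite(path, stack)


def read_fov_tiff(
    path: str,
    condition: str = "",
    replicate_id: str = "",
    channel_labels: Tuple[str, str] = ("ex405", "ex445"),
) -> FieldOfView:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(
            f"{path}: expected a 2-plane multichannel TIFF, got {stack.shape}"
        )
    return FieldOfView(
        channels=(stack[0], stack[1]),
        channel_labels=channel_labels,
        condition=condition,
        replicate_id=replicate_id,
    )


def write_manifest(path: str, rows: Sequence[Dict[str, str]]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"field_id", "path", "condition", "replicate_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return manifest


def write_records_csv(path: str, records: Sequence[CellRatioRecord]) -> None:
    pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "condition": [r.condition for r in records],
            "replicate_id": [r.replicate_id for r in records],
            "golgi_area": [r.golgi_area for r in records],
            "mean_num": [r.mean_num for r in records],
            "mean_den": [r.mean_den for r in records],
            "ratio": [r.ratio for r in records],
        }
    ).to_csv(path, index=False)


def read_records_csv(path: str) -> List[CellRatioRecord]:
    df = pd.read_csv(path)
    return [
        CellRatioRecord(
            cell_id=int(row.cell_id),
            golgi_area=int(row.golgi_area),
            mean_num=float(row.mean_num),
            mean_den=float(row.mean_den),
            ratio=float(row.ratio),
            condition=str(row.condition),
            replicate_id=str(row.replicate_id),
        )
        for row in df.itertuples()
    ]


def write_exclusions_csv(
    path: str, exclusions: Sequence[ExclusionRecord]
) -> None:
    pd.DataFrame(
        {
            "cell_id": [e.cell_id for e in exclusions],
            "condition": [e.condition for e in exclusions],
            "replicate_id": [e.replicate_id for e in exclusions],
            "reason": [e.reason for e in exclusions],
        }
    ).to_csv(path, index=False)


def write_xic_csv(
    path: str, traces: Dict[Tuple[str, str], XICTrace]
) -> None:
    """Write traces keyed by (target_id, label) as long-form CSV."""
    frames = []
    for (target_id, label), trace in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "rt_min": trace.rt,
                    "intensity": trace.intensity,
                    "target_id": target_id,
                    "label": label,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_xic_csv(path: str) -> Dict[Tuple[str, str], XICTrace]:
    """Read long-form XIC CSV (rt_min, intensity, target_id, label)."""
    df = pd.read_csv(path)
    required = {"rt_min", "intensity", "target_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"XIC CSV missing columns {sorted(missing)}")
    traces: Dict[Tuple[str, str], XICTrace] = {}
    for (target_id, label), group in df.groupby(["target_id", "label"]):
        group = group.sort_values("rt_min")
        traces[(str(target_id), str(label))] = XICTrace(
            rt=group["rt_min"].to_numpy(),
            intensity=group["intensity"].to_numpy(),
            label=str(label),  # type: ignore[arg-type]
        )
    return traces


def write_calibration_csv(
    path: str, points: Sequence[CalibrationPoint]
) -> None:
    pd.DataFrame(
        {
            "gsh_M": [p.gsh for p in points],
            "ratio": [p.ratio_mean for p in points],
            "ratio_sd": [p.ratio_sd for p in points],
            "n_fov": [p.n_fov for p in points],
        }
    ).to_csv(path, index=False)


def read_calibration_csv(path: str) -> List[CalibrationPoint]:
    """Read a calibration CSV: either per-FOV rows (gsh_M, ratio, field_id)
    or pre-aggregated rows (gsh_M, ratio, ratio_sd, n_fov)."""
    df = pd.read_csv(path)
    if "field_id" in df.columns:
        points = []
        for gsh, group in df.groupby("gsh_M"):
            ratios = group["ratio"].to_numpy(dtype=float)
            points.append(
                CalibrationPoint(
                    gsh=float(gsh),
                    ratio_mean=float(ratios.mean()),
                    ratio_sd=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
                    n_fov=int(ratios.size),
                )
            )
        return sorted(points, key=lambda p: p.gsh)
    return [
        CalibrationPoint(
            gsh=float(row.gsh_M),
            ratio_mean=float(row.ratio),
            ratio_sd=float(getattr(row, "ratio_sd", 0.0)),
            n_fov=int(getattr(row, "n_fov", 1)),
        )
        for row in df.itertuples()
    ]


def load_flat_config(path: str) -> Dict[str, object]:
    """Load a flat YAML key-value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_flat_config(path: str, cfg: Dict[str, object]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
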