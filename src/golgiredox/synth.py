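"""Seeded synthetic-data generators with recorded ground truth.

Every input the analysis consumes can be generated here with known truth:

* two-channel fields of disk-shaped cells carrying bright perinuclear
  Golgi blob clusters, with Poisson shot noise, Gaussian read noise and a
  linear background gradient (the minimal noise model that makes blockwise
  background correction and robust thresholding non-trivial);
* calibration plates for the saturating ratio-vs-[GSH] relation;
* light/heavy XIC trace pairs with Gaussian peaks on a noisy baseline.

Per-cell biological variability is lognormal (ratios are positive and
right-skewed).  All randomness derives from integer seeds through
``numpy.random.default_rng`` so identical scenarios are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationPoint
from .exceptions import SimulationError
from .imaging import FieldOfView
from .prm import XICTrace

__all__ = [
    "ImagingScenario",
    "XicScenario",
    "simulate_fov",
    "simulate_calibration_plate",
    "simulate_xic_pair",
]


def _rng(seed: int, *streams: "int | str") -> np.random.Generator:
    """Independent deterministic stream keyed by the seed plus labels."""
    key = [int(seed) & 0x7FFFFFFF]
    for s in streams:
        key.append(
            zlib.crc32(s.encode()) if isinstance(s, str) else int(s) & 0x7FFFFFFF
        )
    return np.random.default_rng(key)


@dataclass(frozen=True)
class ImagingScenario:
    """A synthetic two-channel imaging experiment.

    ``true_ratio_per_condition`` fixes the ground-truth numerator/denominator
    ratio for each treatment condition; alternatively
    ``true_gsh_per_condition`` plus a calibration curve generates ratios
    through the forward calibration model (TRaQ-G mode).  Per-cell truth is
    drawn lognormally around the condition value with sigma ``dispersion``
    (median preserved); per-cell expression varies lognormally with
    ``expression_sigma``.  ``den_scale_per_condition`` scales the
    denominator channel per condition (the I(445) drop upon sensor
    oxidation).
    """

    n_cells: int = 60
    true_ratio_per_condition: Mapping[str, float] = field(
        default_factory=lambda: {"basal": 1.5}
    )
    true_gsh_per_condition: Optional[Mapping[str, float]] = None
    calibration: Optional[CalibrationCurve] = None
    den_scale_per_condition: Optional[Mapping[str, float]] = None
    cell_radius: int = 16
    golgi_radius: int = 4
    photon_scale: float = 200.0
    body_fraction: float = 0.30
    golgi_gain: float = 5.0
    background_base: float = 10.0
    background_gradient: float = 20.0
    read_noise: float = 3.0
    dispersion: float = 0.10
    expression_sigma: float = 0.30
    shot_noise: bool = True
    frame_shape: Optional[Tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for cond, ratio in self.true_ratio_per_condition.items():
            if not ratio > 0:
                raise ValueError(f"ratio for {cond!r} must be positive")
        if self.true_gsh_per_condition is not None and self.calibration is None:
            raise ValueError("gsh mode needs a calibration curve")

    def frame(self) -> Tuple[int, int]:
        if self.frame_shape is not None:
            return self.frame_shape
        spacing = 3 * self.cell_radius + 16
        side = int(np.ceil(np.sqrt(self.n_cells))) * spacing + 2 * spacing
        return side, side


@dataclass(frozen=True)
class XicScenario:
    """A synthetic light/heavy chromatographic peak pair.

    The heavy (glutathionylated) peak has fixed amplitude; the light peak is
    scaled by ``true_sh_to_ssg``.  ``snr`` is the apex-to-baseline-noise
    ratio of each trace individually.
    """

    true_sh_to_ssg: float = 0.06
    apex_rt: float = 22.0
    peak_sigma: float = 0.10
    snr: float = 20.0
    heavy_height: float = 1.0e6
    rt_span: float = 2.0
    rt_step: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "true_sh_to_ssg",
            "apex_rt",
            "peak_sigma",
            "snr",
            "heavy_height",
            "rt_span",
            "rt_step",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _place_cells(
    rng: np.random.Generator,
    n: int,
    shape: Tuple[int, int],
    radius: int,
) -> np.ndarray:
    """Non-overlapping disk centres by rejection sampling."""
    h, w = shape
    margin = radius + 4
    min_dist = 2 * radius + 4
    centres: List[Tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * n
    while len(centres) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"could not place {n} non-overlapping cells in frame {shape}; "
                "use a larger frame or fewer/smaller cells"
            )
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all(
            (cy - y) ** 2 + (cx - x) ** 2 >= min_dist**2 for y, x in centres
        ):
            centres.append((cy, cx))
    return np.array(centres)


def simulate_fov(
    s: ImagingScenario,
    condition: str,
    replicate_id: str = "R1",
) -> Tuple[FieldOfView, pd.DataFrame]:
    """Render one field of view plus its ground-truth table.

    Each cell is a disk with a 3-blob perinuclear Golgi cluster.  The
    denominator channel is Poisson with expectation
    photon_scale · expression · (body or Golgi gain) · condition scale;
    the numerator is an independent Poisson draw at true_ratio times the
    same expectation.  A linear background gradient and Gaussian read noise
    are added to both channels.  Output is identical for identical seeds.
    """
    if s.true_gsh_per_condition is not None:
        truth_value = s.true_gsh_per_condition[condition]
    else:
        truth_value = s.true_ratio_per_condition[condition]
    den_scale = 1.0
    if s.den_scale_per_condition is not None:
        den_scale = s.den_scale_per_condition[condition]

    shape = s.frame()
    rng = _rng(s.seed, condition, replicate_id)
    centres = _place_cells(rng, s.n_cells, shape, s.cell_radius)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    den_expect = np.zeros(shape)
    num_expect = np.zeros(shape)
    rows = []
    for cell_id, (cy, cx) in enumerate(centres, start=1):
        lognorm = float(rng.lognormal(0.0, s.dispersion)) if s.dispersion else 1.0
        if s.true_gsh_per_condition is not None:
            true_gsh = truth_value * lognorm
            true_ratio = float(s.calibration.predict(true_gsh))  # type: ignore[union-attr]
        else:
            true_gsh = np.nan
            true_ratio = truth_value * lognorm
        expr = (
            float(rng.lognormal(0.0, s.expression_sigma))
            if s.expression_sigma
            else 1.0
        )
        body = (yy - cy) ** 2 + (xx - cx) ** 2 <= s.cell_radius**2
        # perinuclear cluster: three small blobs at ~0.45 R from the centre
        theta0 = rng.uniform(0, 2 * np.pi)
        golgi = np.zeros(shape, dtype=bool)
        for j in range(3):
            ang = theta0 + j * 0.55
            gy = cy + 0.45 * s.cell_radius * np.sin(ang)
            gx = cx + 0.45 * s.cell_radius * np.cos(ang)
            golgi |= (yy - gy) ** 2 + (xx - gx) ** 2 <= s.golgi_radius**2
        golgi &= body
        base = s.photon_scale * expr * den_scale
        cell_den = np.where(
            golgi, base * s.golgi_gain, np.where(body, base * s.body_fraction, 0.0)
        )
        den_expect += cell_den
        num_expect += true_ratio * cell_den
        rows.append(
            {
                "cell_id": cell_id,
                "y": cy,
                "x": cx,
                "true_ratio": true_ratio,
                "true_gsh": true_gsh,
                "expression": expr,
                "condition": condition,
                "replicate_id": replicate_id,
            }
        )

    gradient = s.background_base + s.background_gradient * (
        0.5 * (xx + yy) / max(shape)
    )
    channels = []
    for expect in (num_expect, den_expect):
        img = (
            rng.poisson(expect).astype(float) if s.shot_noise else expect.copy()
        )
        img += gradient
        if s.read_noise:
            img += rng.normal(0.0, s.read_noise, size=shape)
        channels.append(np.clip(img, 0.0, None))

    fov = FieldOfView(
        channels=(channels[0], channels[1]),
        condition=condition,
        replicate_id=replicate_id,
    )
    return fov, pd.DataFrame(rows)


def simulate_calibration_plate(
    r0: float,
    r_max: float,
    k_half: float,
    concentrations: "np.ndarray | list",
    rel_noise: float = 0.02,
    n_fov: int = 3,
    seed: int = 0,
) -> List[CalibrationPoint]:
    """Calibration points from the saturating model plus relative noise.

    Each concentration is measured as ``n_fov`` synthetic fields whose
    ratios scatter multiplicatively (Gaussian, sd ``rel_noise``) around the
    model value; the returned points carry the per-well mean and sd.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations")
    rng = _rng(seed, "calibration-plate")
    points = []
    for c in conc:
        model = r0 + (r_max - r0) * c / (k_half + c)
        fovs = model * (1.0 + rng.normal(0.0, rel_noise, size=n_fov))
        points.append(
            CalibrationPoint(
                gsh=float(c),
                ratio_mean=float(fovs.mean()),
                ratio_sd=float(fovs.std(ddof=1)) if n_fov > 1 else 0.0,
                n_fov=n_fov,
            )
        )
    return points


def simulate_xic_pair(s: XicScenario) -> Tuple[XICTrace, XICTrace]:
    """A light/heavy Gaussian peak pair on a noisy constant baseline.

    Both peaks share the apex retention time and width; the light amplitude
    is ``heavy_height · true_sh_to_ssg``.  Baseline noise is Gaussian with
    sd = apex/snr per trace, on a constant offset of five noise sd so the
    nonnegativity clip does not bias the noise.
    """
    rt = np.arange(
        s.apex_rt - s.rt_span, s.apex_rt + s.rt_span + s.rt_step / 2, s.rt_step
    )
    shape = np.exp(-0.5 * ((rt - s.apex_rt) / s.peak_sigma) ** 2)
    traces = []
    for label, height in (
        ("light", s.heavy_height * s.true_sh_to_ssg),
        ("heavy", s.heavy_height),
    ):
        rng = _rng(s.seed, "xic", label)
        noise_sd = height / s.snr
        baseline = 5.0 * noise_sd
        inten = height * shape + baseline + rng.normal(0.0, noise_sd, rt.size)
        traces.append(
            XICTrace(rt=rt, intensity=np.clip(inten, 0.0, None), label=label)  # type: ignore[arg-type]
        )
    return traces[0], traces[1]
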