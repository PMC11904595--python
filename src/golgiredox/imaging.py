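"""Ratiometric imaging: from two-channel fields to per-cell Golgi ratios.

The pipeline mirrors the standard CellProfiler-style analysis for
organelle-targeted ratiometric sensors:

1. blockwise-minimum background estimation, Gaussian-smoothed, subtracted;
2. cell identification by robust-background thresholding (trimmed
   mean + k·sd) and connected components;
3. Golgi spot enhancement by white top-hat, thresholding, masking to cell
   footprints, and grouping of fragments per cell;
4. per-cell ratio of Golgi-masked channel means (numerator/denominator);
5. nonparametric condition comparison (Mann-Whitney U).

Ratios are formed as the ratio of masked means, not the mean of pixel
ratios, which is stabler under shot noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage import measure, morphology

__all__ = [
    "FieldOfView",
    "SegmentationResult",
    "CellRatioRecord",
    "ExclusionRecord",
    "correct_background",
    "segment_cells",
    "segment_golgi",
    "per_cell_ratio_table",
    "compare_conditions",
    "default_denominator_floor",
]


@dataclass(frozen=True)
class FieldOfView:
    """One two-channel field: (numerator, denominator) intensity planes."""

    channels: Tuple[np.ndarray, np.ndarray]
    channel_labels: Tuple[str, str] = ("ex405", "ex445")
    pixel_size: Optional[float] = None
    condition: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        num = np.asarray(self.channels[0], dtype=float)
        den = np.asarray(self.channels[1], dtype=float)
        object.__setattr__(self, "channels", (num, den))
        if num.shape != den.shape:
            raise ValueError("channel planes must share a shape")
        for plane in (num, den):
            if not np.all(np.isfinite(plane)):
                raise ValueError("intensities must be finite")
            if np.any(plane < 0):
                raise ValueError("intensities must be nonnegative")

    @property
    def numerator(self) -> np.ndarray:
        return self.channels[0]

    @property
    def denominator(self) -> np.ndarray:
        return self.channels[1]


@dataclass(frozen=True)
class SegmentationResult:
    """Cell and Golgi label planes plus the Golgi-group → cell mapping."""

    cell_labels: np.ndarray
    golgi_labels: np.ndarray
    golgi_to_cell: Dict[int, int]

    def __post_init__(self) -> None:
        if self.cell_labels.shape != self.golgi_labels.shape:
            raise ValueError("label planes must share a shape")


@dataclass(frozen=True)
class CellRatioRecord:
    """Per-cell Golgi-masked channel means and their ratio."""

    cell_id: int
    golgi_area: int
    mean_num: float
    mean_den: float
    ratio: float
    condition: str = ""
    replicate_id: str = ""


@dataclass(frozen=True)
class ExclusionRecord:
    """A cell dropped from the ratio table, with the reason."""

    cell_id: int
    reason: str
    condition: str = ""
    replicate_id: str = ""


def correct_background(
    plane: np.ndarray,
    block: int = 600,
    smooth_scale: Optional[float] = None,
) -> np.ndarray:
    """Blockwise-minimum background subtraction with Gaussian smoothing.

    The background surface is the per-block minimum intensity, expanded to
    full resolution and smoothed with a Gaussian of scale ``smooth_scale``
    (default ``block/4`` pixels), then subtracted; the result is clipped at
    zero.  A flat plane maps to all zeros.  If ``block`` exceeds both image
    dimensions the method degrades to global-minimum subtraction with a
    warning.
    """
    img = np.asarray(plane, dtype=float)
    if block < 3:
        raise ValueError("block must be >= 3 pixels")
    h, w = img.shape
    if block > h and block > w:
        warnings.warn(
            f"block size {block} exceeds both image dimensions {img.shape}; "
            "falling back to global-minimum subtraction",
            stacklevel=2,
        )
        return np.clip(img - img.min(), 0.0, None)
    if smooth_scale is None:
        smooth_scale = block / 4.0
    nby, nbx = -(-h // block), -(-w // block)
    mins = np.empty((nby, nbx))
    for by in range(nby):
        for bx in range(nbx):
            mins[by, bx] = img[
                by * block : (by + 1) * block, bx * block : (bx + 1) * block
            ].min()
    background = np.repeat(np.repeat(mins, block, axis=0), block, axis=1)[:h, :w]
    if smooth_scale > 0:
        background = ndimage.gaussian_filter(
            background, sigma=smooth_scale, mode="nearest"
        )
    return np.clip(img - background, 0.0, None)


def _robust_threshold(values: np.ndarray, k: float, trim: float) -> float:
    """Trimmed mean + k·sd threshold (robust-background convention).

    The brightest and dimmest ``trim`` fractions of the pixel population are
    discarded before the mean and standard deviation are taken.
    """
    v = np.sort(values.ravel())
    cut = int(round(trim * v.size))
    core = v[cut : v.size - cut] if v.size - 2 * cut > 0 else v
    return float(core.mean() + k * core.std())


def segment_cells(
    plane: np.ndarray,
    k: float = 2.0,
    min_cell_area: int = 200,
    trim: float = 0.05,
    connectivity: int = 2,
) -> np.ndarray:
    """Identify cell objects by robust-background thresholding.

    Pixels above the trimmed mean + k·sd threshold are grouped into
    8-connected components; components below ``min_cell_area`` are removed
    and labels are renumbered contiguously.  An empty or pure-noise image
    yields zero objects.
    """
    img = np.asarray(plane, dtype=float)
    threshold = _robust_threshold(img, k, trim)
    mask = img > threshold
    labels = measure.label(mask, connectivity=connectivity)
    if labels.max():
        counts = np.bincount(labels.ravel())
        keep = counts >= min_cell_area
        keep[0] = False
        labels = measure.label(keep[labels], connectivity=connectivity)
    return labels.astype(np.int32)


def segment_golgi(
    plane: np.ndarray,
    cells: np.ndarray,
    spot_scale: int = 5,
    k: float = 2.0,
    min_golgi_area: int = 10,
    trim: float = 0.05,
) -> SegmentationResult:
    """Enhance Golgi spots, threshold, mask to cells and group per cell.

    Spots are enhanced with a white top-hat (disk structuring element of
    radius ``spot_scale``), thresholded with the same robust-background rule
    as the cells, and restricted to cell footprints.  All Golgi pixels
    inside one cell form one grouped region labelled after that cell, then
    relabelled contiguously; enhanced pixels outside every cell are
    discarded, and cells whose grouped region is smaller than
    ``min_golgi_area`` are omitted.
    """
    img = np.asarray(plane, dtype=float)
    cells = np.asarray(cells)
    tophat = morphology.white_tophat(img, footprint=morphology.disk(spot_scale))
    inside = cells > 0
    golgi_labels = np.zeros_like(cells, dtype=np.int32)
    golgi_to_cell: Dict[int, int] = {}
    if inside.any():
        threshold = _robust_threshold(tophat[inside], k, trim)
        spot_mask = (tophat > threshold) & inside
        next_label = 1
        for cell_id in np.unique(cells[cells > 0]):
            group = spot_mask & (cells == cell_id)
            if int(group.sum()) >= min_golgi_area:
                golgi_labels[group] = next_label
                golgi_to_cell[next_label] = int(cell_id)
                next_label += 1
    return SegmentationResult(
        cell_labels=cells.astype(np.int32),
        golgi_labels=golgi_labels,
        golgi_to_cell=golgi_to_cell,
    )


def default_denominator_floor(denominator: np.ndarray) -> float:
    """Denominator floor: 1 % of the field's 99th-percentile intensity."""
    return 0.01 * float(np.percentile(denominator, 99))


def per_cell_ratio_table(
    fov: FieldOfView,
    seg: SegmentationResult,
    den_floor: Optional[float] = None,
) -> Tuple[List[CellRatioRecord], List[ExclusionRecord]]:
    """Per-cell Golgi-masked channel means and the ratio of those means.

    Cells whose mean denominator intensity does not exceed ``den_floor``
    (default: 1 % of the 99th-percentile denominator intensity) are dropped
    and logged.  Both channels are expected background-corrected.
    """
    if den_floor is None:
        den_floor = default_denominator_floor(fov.denominator)
    records: List[CellRatioRecord] = []
    exclusions: List[ExclusionRecord] = []
    for label, cell_id in sorted(seg.golgi_to_cell.items()):
        mask = seg.golgi_labels == label
        area = int(mask.sum())
        mean_num = float(fov.numerator[mask].mean())
        mean_den = float(fov.denominator[mask].mean())
        if mean_den <= den_floor:
            exclusions.append(
                ExclusionRecord(
                    cell_id=cell_id,
                    reason=f"denominator mean {mean_den:.4g} <= floor {den_floor:.4g}",
                    condition=fov.condition,
                    replicate_id=fov.replicate_id,
                )
            )
            continue
        records.append(
            CellRatioRecord(
                cell_id=cell_id,
                golgi_area=area,
                mean_num=mean_num,
                mean_den=mean_den,
                ratio=mean_num / mean_den,
                condition=fov.condition,
                replicate_id=fov.replicate_id,
            )
        )
    return records, exclusions


def compare_conditions(
    a: Sequence[float], b: Sequence[float]
) -> Tuple[float, float]:
    """Unpaired two-tailed Mann-Whitney U test between two ratio samples.

    Uses exact enumeration when both samples have at most 8 values and no
    ties straddle the groups; otherwise the normal approximation with tie
    correction.  Returns ``(U statistic of the first sample, two-sided p)``.
    Identical pooled values give p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
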