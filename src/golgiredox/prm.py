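"""Targeted-proteomics (PRM) arm: masses, chromatogram areas, label ratios.

The glutathionylated fraction of the single-cysteine glutaredoxin probe is
read out by differential cysteine alkylation: free thiols are blocked with
light iodoacetamide (carbamidomethyl, +57.021464 Da) in live cells, the
glutathionylated fraction is later reduced and blocked with the heavy
reagent I¹³CD₂¹³CONH₂ (+61.040728 Da).  The light:heavy XIC area ratio of
the cysteine-containing tryptic peptide therefore equals
[probe-SH]:[probe-SSG], which K_ox converts to the GSH:GSSG ratio.

Monoisotopic residue masses come from :mod:`pyteomics.mass`; the target
assembly, fragment-ion arithmetic and peak integration are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _ptmass

from .exceptions import (
    MassValidationError,
    OutOfRangeError,
    UndefinedRatioError,
)
from .nernst import GRX_GOLGI, GrxEquilibrium

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "MOD_SHIFTS",
    "PeptideSpec",
    "TargetIon",
    "XICTrace",
    "LabelRatioResult",
    "peptide_mz",
    "fragment_mz",
    "build_target_list",
    "integrate_xic",
    "glutathionylation_ratio",
]

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863

# Isotope mass differences used to derive the heavy carbamidomethyl shift
# from the reagent formula I13CD2-13CONH2: two 13C-12C plus two 2H-1H.
_D13C = 13.00335483507 - 12.0
_D2H = 2.01410177812 - 1.00782503207

#: Defined cysteine-alkylation mass shifts (Da).
MOD_SHIFTS = {
    "CAM_light": 57.021464,
    "CAM_heavy": 57.021464 + 2.0 * _D13C + 2.0 * _D2H,
}

_RESIDUE_MASS = dict(_ptmass.std_aa_mass)


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide with site-localised modifications and a charge state.

    ``modifications`` is a tuple of ``(position, label)`` with 1-based
    positions and labels drawn from :data:`MOD_SHIFTS`.
    """

    sequence: str
    modifications: Tuple[Tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        for residue in self.sequence:
            if residue not in _RESIDUE_MASS:
                raise ValueError(f"unknown residue {residue!r}")
        for pos, label in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )
            if label not in MOD_SHIFTS:
                raise ValueError(f"unknown modification label {label!r}")

    def with_charge(self, charge: int) -> "PeptideSpec":
        return PeptideSpec(self.sequence, self.modifications, charge)


@dataclass(frozen=True)
class TargetIon:
    """One monitored ion: a precursor or a backbone fragment."""

    peptide: PeptideSpec
    ion_type: Literal["precursor", "y", "b"]
    mz: float
    fragment_index: Optional[int] = None
    isolation_window: float = 0.8
    label: str = ""
    printed_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.ion_type != "precursor":
            if self.fragment_index is None:
                raise ValueError("fragment ions need a fragment_index")
            if not self.fragment_index < len(self.peptide.sequence):
                raise ValueError("fragment_index must be < sequence length")


@dataclass(frozen=True)
class XICTrace:
    """An extracted-ion chromatogram: intensity vs. retention time."""

    rt: np.ndarray
    intensity: np.ndarray
    target: Optional[TargetIon] = None
    label: Literal["light", "heavy"] = "light"

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)
        if rt.shape != inten.shape:
            raise ValueError("rt and intensity must have equal length")
        if rt.size < 5:
            raise ValueError("trace needs at least 5 points")
        if not np.all(np.diff(rt) > 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class LabelRatioResult:
    """Light:heavy area ratio and the derived redox quantities."""

    area_light: float
    area_heavy: float
    sh_to_ssg: float
    fraction_oxidized: float
    r_gs: float
    unmodified_detected: bool = False


def _residue_sum(sequence: str) -> float:
    return sum(_RESIDUE_MASS[r] for r in sequence)


def _mod_sum(
    modifications: Sequence[Tuple[int, str]],
    lo: int,
    hi: int,
) -> float:
    """Sum of modification shifts on 1-based positions in [lo, hi]."""
    return sum(
        MOD_SHIFTS[label] for pos, label in modifications if lo <= pos <= hi
    )


def peptide_mz(spec: PeptideSpec) -> float:
    """Monoisotopic precursor m/z, rounded to 4 decimal places.

    (Σ residue masses + water + Σ modification shifts + z·proton) / z.
    """
    n = len(spec.sequence)
    neutral = (
        _residue_sum(spec.sequence)
        + WATER_MASS
        + _mod_sum(spec.modifications, 1, n)
    )
    return round((neutral + spec.charge * PROTON_MASS) / spec.charge, 4)


def fragment_mz(
    spec: PeptideSpec,
    ion_type: Literal["y", "b"],
    index: int,
    charge: int,
) -> float:
    """Monoisotopic m/z of a y- or b-series fragment ion.

    y_k covers the last k residues (with water); b_k the first k residues
    (without water).  Modifications on residues inside the fragment are
    included.  y_n at the precursor charge equals the precursor m/z.
    """
    n = len(spec.sequence)
    if not 1 <= index <= n:
        raise OutOfRangeError(
            f"fragment index {index} outside [1, {n}] for {spec.sequence}"
        )
    if ion_type == "y":
        residues = spec.sequence[n - index:]
        neutral = (
            _residue_sum(residues)
            + WATER_MASS
            + _mod_sum(spec.modifications, n - index + 1, n)
        )
    elif ion_type == "b":
        residues = spec.sequence[:index]
        neutral = _residue_sum(residues) + _mod_sum(
            spec.modifications, 1, index
        )
    else:
        raise ValueError(f"unsupported ion type {ion_type!r}")
    return round((neutral + charge * PROTON_MASS) / charge, 4)


# Reference PRM target table: (sequence, mods, charge, ion, index, label,
# reference m/z).  The cysteine peptide of the glutaredoxin probe is
# monitored unmodified, light- and heavy-carbamidomethylated at 2+ and 3+;
# the remaining peptides are unmodified probe peptides used for monitoring.
_CYS_PEPTIDE = "TYCPYSHAALNTLFEK"
_PRINTED_TARGETS: Tuple[
    Tuple[str, Tuple[Tuple[int, str], ...], int, str, Optional[int], str, float],
    ...,
] = (
    ("DLIAENEIFVASK", (), 2, "precursor", None, "", 724.8852),
    (_CYS_PEPTIDE, ((3, "CAM_light"),), 2, "precursor", None, "light", 957.9564),
    (_CYS_PEPTIDE, ((3, "CAM_heavy"),), 2, "precursor", None, "heavy", 959.966),
    (_CYS_PEPTIDE, ((3, "CAM_light"),), 3, "precursor", None, "light", 638.9733),
    (_CYS_PEPTIDE, ((3, "CAM_heavy"),), 3, "precursor", None, "heavy", 640.3131),
    (_CYS_PEPTIDE, (), 2, "precursor", None, "", 929.4456),
    (_CYS_PEPTIDE, (), 3, "precursor", None, "", 619.9662),
    ("VLVLQLNDMK", (), 2, "precursor", None, "", 586.839),
    ("EGADIQAALYEINGQR", (), 2, "precursor", None, "", 874.4341),
    ("TVPNIYINGK", (), 2, "precursor", None, "", 559.8139),
    ("HIGGNDDLQELR", (), 2, "precursor", None, "", 683.8391),
    # Quantifier fragment: doubly charged y14 of the light peptide.
    (_CYS_PEPTIDE, ((3, "CAM_light"),), 2, "y", 14, "light", 825.9009),
)


def build_target_list(tolerance: float = 0.001) -> List[TargetIon]:
    """Assemble the full PRM target list from sequences and modifications.

    Every target's m/z is computed from first principles and checked against
    its reference value; any disagreement beyond ``tolerance`` (default
    0.001 m/z) raises :class:`MassValidationError`.  This guards the whole
    quantification arm against residue-mass or modification-table typos.
    """
    targets: List[TargetIon] = []
    for seq, mods, charge, ion, index, label, ref in _PRINTED_TARGETS:
        spec = PeptideSpec(seq, mods, charge)
        if ion == "precursor":
            mz = peptide_mz(spec)
        else:
            mz = fragment_mz(spec, ion, index, charge)
        if abs(mz - ref) >= tolerance:
            raise MassValidationError(
                f"computed m/z {mz} for {seq} ({ion}{index or ''}, {charge}+, "
                f"{label or 'unmodified'}) deviates from reference {ref}"
            )
        targets.append(
            TargetIon(
                peptide=spec,
                ion_type=ion,  # type: ignore[arg-type]
                mz=mz,
                fragment_index=index,
                label=label,
                printed_mz=ref,
            )
        )
    # The heavy-labelled quantifier fragment is monitored alongside the
    # light one; no independent reference value exists for it.
    heavy_spec = PeptideSpec(_CYS_PEPTIDE, ((3, "CAM_heavy"),), 2)
    targets.append(
        TargetIon(
            peptide=heavy_spec,
            ion_type="y",
            mz=fragment_mz(heavy_spec, "y", 14, 2),
            fragment_index=14,
            label="heavy",
        )
    )
    return targets


def integrate_xic(
    trace: XICTrace,
    rt_window: Optional[Tuple[float, float]] = None,
    baseline: Literal["median", "zero"] = "median",
    boundary_fraction: float = 0.01,
) -> float:
    """Trapezoidal XIC peak area (intensity · min) above a baseline.

    The apex is located inside ``rt_window`` (whole trace when omitted) and
    the integration boundaries extend outward from it until the
    baseline-subtracted intensity falls below ``boundary_fraction`` of the
    apex or the window edge is reached.  The baseline is the median of the
    whole trace ("median") or zero.
    """
    rt, inten = trace.rt, trace.intensity
    if rt_window is None:
        window = np.ones(rt.size, dtype=bool)
    else:
        lo, hi = rt_window
        window = (rt >= lo) & (rt <= hi)
        if not window.any():
            warnings.warn(
                "retention-time window contains no trace points; area = 0",
                stacklevel=2,
            )
            return 0.0
    base = float(np.median(inten)) if baseline == "median" else 0.0
    signal = inten - base
    widx = np.flatnonzero(window)
    apex = widx[np.argmax(signal[widx])]
    apex_height = signal[apex]
    if apex_height <= 0:
        return 0.0
    cutoff = boundary_fraction * apex_height
    left = apex
    while left > widx[0] and signal[left - 1] >= cutoff:
        left -= 1
    right = apex
    while right < widx[-1] and signal[right + 1] >= cutoff:
        right += 1
    segment = np.clip(signal[left : right + 1], 0.0, None)
    return float(np.trapezoid(segment, rt[left : right + 1]))


def glutathionylation_ratio(
    light: XICTrace,
    heavy: XICTrace,
    grx: GrxEquilibrium = GRX_GOLGI,
    rt_window: Optional[Tuple[float, float]] = None,
    unmodified: Optional[XICTrace] = None,
    baseline: Literal["median", "zero"] = "median",
) -> LabelRatioResult:
    """Light:heavy area ratio of the quantifier fragment and derived values.

    ``sh_to_ssg`` = area_light/area_heavy = [probe-SH]:[probe-SSG];
    ``fraction_oxidized`` = 1/(1 + sh_to_ssg); ``r_gs`` = K_ox·sh_to_ssg.
    A zero heavy area makes the ratio undefined (distinct from a zero light
    area, which is a valid fully-oxidized readout).

    When an ``unmodified``-peptide trace is supplied it is integrated too and
    flagged as detected only if its area reaches 1 % of light + heavy (the
    probe's unlabelled form is expected below the limit of detection).
    """
    area_light = integrate_xic(light, rt_window, baseline=baseline)
    area_heavy = integrate_xic(heavy, rt_window, baseline=baseline)
    if area_heavy <= 0:
        raise UndefinedRatioError(
            "heavy (glutathionylated) area is zero; light:heavy ratio undefined"
        )
    sh_to_ssg = area_light / area_heavy
    detected = False
    if unmodified is not None:
        area_un = integrate_xic(unmodified, rt_window, baseline=baseline)
        detected = area_un >= 0.01 * (area_light + area_heavy)
    return LabelRatioResult(
        area_light=area_light,
        area_heavy=area_heavy,
        sh_to_ssg=sh_to_ssg,
        fraction_oxidized=1.0 / (1.0 + sh_to_ssg),
        r_gs=grx.k_ox * sh_to_ssg,
        unmodified_detected=detected,
    )
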