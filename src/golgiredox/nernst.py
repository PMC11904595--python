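"""Sensor-equilibrium and glutathione-pool algebra.

This module carries the chemistry that turns a ratiometric roGFP readout
into a glutathione redox potential and, combined with a glutaredoxin-derived
GSH:GSSG ratio, into absolute pool concentrations.

The chain is:

    405/445 excitation ratios  ──►  OxD (degree of sensor oxidation)
    OxD                        ──►  E_GSH          (Nernst, two-electron)
    E_GSH                      ──►  Q = [GSH]²/[GSSG]   (1 M standard state)
    Q and R_GS = [GSH]/[GSSG]  ──►  [GSH], [GSSG], [GS] = [GSH] + 2[GSSG]

All potentials are in millivolts, all concentrations in molar, temperatures
in kelvin.  Every Nernst computation reads R, F, T and the pH slope from a
:class:`RedoxConstants` instance so that the temperature assumption is
explicit and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvalidCalibrationError,
    OutOfRangeError,
)

__all__ = [
    "RedoxConstants",
    "SensorSpec",
    "RatioCalibration",
    "OxDValue",
    "GrxEquilibrium",
    "GlutathionePool",
    "RedoxStateResult",
    "ROGFP1_IE",
    "ROGFP2",
    "GRX_GOLGI",
    "OXD_EPS",
    "oxd_from_ratios",
    "ratio_from_oxd",
    "midpoint_at_ph",
    "e_gsh_from_oxd",
    "oxd_from_e_gsh",
    "q_from_e_gsh",
    "e_gsh_from_q",
    "r_gs_from_thiol_ratio",
    "pool_from_q_and_rgs",
    "propagate_uncertainty",
]

#: Clamp width applied to OxD at both ends of [0, 1].  The Nernst relation
#: diverges at exactly 0 or 1 and the Golgi sensor operates near saturation,
#: so clamped values are expected and flagged rather than rejected.
OXD_EPS = 1e-6


@dataclass(frozen=True)
class RedoxConstants:
    """Physical constants and assay conditions for Nernst computations.

    Parameters
    ----------
    gas_constant : float
        Molar gas constant R, J K⁻¹ mol⁻¹.
    faraday : float
        Faraday constant F, C mol⁻¹.
    temperature : float
        Absolute temperature, K.  Defaults to 310.15 K (cells at 37 °C).
    ph_slope : float
        Midpoint-potential shift per pH unit, mV, for the pH correction
        E°′(pH) = E°′ − slope·(pH − 7).
    """

    gas_constant: float = 8.315
    faraday: float = 96485.0
    temperature: float = 310.15
    ph_slope: float = 60.1

    def __post_init__(self) -> None:
        for name in ("gas_constant", "faraday", "temperature", "ph_slope"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 273.0 <= self.temperature <= 330.0:
            raise ValueError(
                f"temperature {self.temperature} K outside plausible range [273, 330]"
            )

    @property
    def nernst_slope_mv(self) -> float:
        """RT/2F in millivolts (two-electron couple)."""
        return (
            self.gas_constant * self.temperature / (2.0 * self.faraday) * 1000.0
        )


@dataclass(frozen=True)
class SensorSpec:
    """A roGFP variant: its consensus midpoint potential and optional
    working-pH override.

    ``midpoint_potential_override``, when set, is the midpoint potential at
    the working pH and takes precedence over the pH-slope computation.
    """

    name: str
    midpoint_potential_ph7: float
    midpoint_potential_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.midpoint_potential_ph7 < 0:
            raise ValueError("midpoint potential must be negative (mV)")
        if (
            self.midpoint_potential_override is not None
            and not self.midpoint_potential_override < 0
        ):
            raise ValueError("midpoint override must be negative (mV)")


#: roGFP1-iE, the variant suited to oxidizing compartments.  The override is
#: the published working value at the Golgi pH of 6.2 (−190 mV), which is
#: retained in preference to the pH-slope computation (−187.9 mV).
ROGFP1_IE = SensorSpec("roGFP1-iE", -236.0, midpoint_potential_override=-190.0)

#: roGFP2, the brighter variant used in reducing compartments.
ROGFP2 = SensorSpec("roGFP2", -272.0)


@dataclass(frozen=True)
class RatioCalibration:
    """Dynamic-range anchors of the ratiometric sensor.

    ``r_red`` and ``r_ox`` are the 405/445 ratios under full reduction (DTT)
    and full oxidation (H₂O₂); ``span_445`` is I(445)min/I(445)max, the
    relative drop of the denominator channel upon oxidation.
    """

    r_basal: float
    r_red: float
    r_ox: float
    span_445: float

    def __post_init__(self) -> None:
        if not self.r_ox > self.r_red:
            raise InvalidCalibrationError(
                f"degenerate calibration: r_ox ({self.r_ox}) must exceed "
                f"r_red ({self.r_red})"
            )
        if not 0.0 < self.span_445 <= 1.0:
            raise InvalidCalibrationError(
                f"span_445 must lie in (0, 1], got {self.span_445}"
            )


@dataclass(frozen=True)
class OxDValue:
    """Degree of oxidation of the sensor, clamped into [ε, 1−ε]."""

    oxd: float
    clamped_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.oxd <= 1.0:
            raise ValueError(f"OxD {self.oxd} outside [0, 1]")

    def __float__(self) -> float:
        return self.oxd


@dataclass(frozen=True)
class GrxEquilibrium:
    """Equilibrium constant of the single-cysteine glutaredoxin probe.

    K_ox relates the probe's glutathionylation state to the GSH:GSSG ratio:
    R_GS = K_ox · [probe-SH]/[probe-SSG].  The default 234 ± 6 is the
    published value at pH 6.2.
    """

    k_ox: float = 234.0
    k_ox_sd: float = 6.0
    valid_ph: float = 6.2

    def __post_init__(self) -> None:
        if not self.k_ox > 0:
            raise ValueError("k_ox must be positive")


#: Default glutaredoxin equilibrium used for Golgi quantification.
GRX_GOLGI = GrxEquilibrium()


@dataclass(frozen=True)
class GlutathionePool:
    """Absolute glutathione pool: Q, R_GS and the derived concentrations."""

    q: float
    r_gs: float
    gsh: float
    gssg: float
    gs_total: float

    def __post_init__(self) -> None:
        for name in ("q", "r_gs", "gsh", "gssg", "gs_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class RedoxStateResult:
    """A fully assembled redox-state estimate for one dataset."""

    e_gsh: float
    e_gsh_uncertainty: float
    oxd: OxDValue
    pool: Optional[GlutathionePool] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_gsh):
            raise ValueError("e_gsh must be finite")
        if self.e_gsh_uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")


def _clamp_oxd(x: float, eps: float = OXD_EPS) -> Tuple[float, bool]:
    if x < eps:
        return eps, True
    if x > 1.0 - eps:
        return 1.0 - eps, True
    return x, False


def oxd_from_ratios(cal: RatioCalibration, eps: float = OXD_EPS) -> OxDValue:
    """Degree of oxidation from the 405/445 ratio triplet.

    OxD = (R − R_red) / (span·(R_ox − R) + (R − R_red)), where span is
    I(445)min/I(445)max.  The result is clamped into [ε, 1−ε]; the flag
    records whether clamping occurred (expected when the basal ratio falls
    outside the [R_red, R_ox] window measured on different cells).
    """
    r, r_red, r_ox = cal.r_basal, cal.r_red, cal.r_ox
    num = r - r_red
    den = cal.span_445 * (r_ox - r) + num
    if den <= 0:
        # Basal ratio beyond the fully oxidized anchor: saturated sensor.
        oxd, clamped = 1.0 - eps, True
    else:
        oxd, clamped = _clamp_oxd(num / den, eps)
    return OxDValue(oxd=oxd, clamped_flag=clamped)


def ratio_from_oxd(
    oxd: "OxDValue | float", r_red: float, r_ox: float, span_445: float
) -> float:
    """Basal 405/445 ratio at a given degree of oxidation.

    Exact inverse of :func:`oxd_from_ratios` for fixed anchors:
    R = (OxD·span·R_ox + (1 − OxD)·R_red) / (OxD·span + (1 − OxD)),
    i.e. the linear two-state mixture of the fully reduced and fully
    oxidized sensor signals.
    """
    x = float(oxd)
    if not 0.0 <= x <= 1.0:
        raise OutOfRangeError(f"OxD {x} outside [0, 1]")
    w_ox = x * span_445
    w_red = 1.0 - x
    return (w_ox * r_ox + w_red * r_red) / (w_ox + w_red)


def midpoint_at_ph(
    sensor: SensorSpec, ph: float, consts: RedoxConstants = RedoxConstants()
) -> float:
    """Sensor midpoint potential (mV) at the working pH.

    Returns the explicit override when the sensor carries one; otherwise
    applies the linear pH correction E°′(pH) = E°′ − slope·(pH − 7).
    """
    if not 4.0 <= ph <= 9.0:
        raise OutOfRangeError(f"pH {ph} outside supported range [4, 9]")
    if sensor.midpoint_potential_override is not None:
        return sensor.midpoint_potential_override
    return sensor.midpoint_potential_ph7 - consts.ph_slope * (ph - 7.0)


def e_gsh_from_oxd(
    oxd: "OxDValue | float",
    e0: float,
    consts: RedoxConstants = RedoxConstants(),
) -> float:
    """Glutathione redox potential (mV) from the sensor's degree of oxidation.

    E = E°′ − (RT/2F)·ln((1 − OxD)/OxD); strictly increasing in OxD and
    equal to E°′ at OxD = 0.5.  OxD must lie strictly inside (0, 1);
    clamped values are acceptable, exact 0 or 1 is not (infinite potential).
    """
    x = float(oxd)
    if not 0.0 < x < 1.0:
        raise OutOfRangeError(f"OxD {x} must lie strictly inside (0, 1)")
    return e0 - consts.nernst_slope_mv * math.log((1.0 - x) / x)


def oxd_from_e_gsh(
    e: float, e0: float, consts: RedoxConstants = RedoxConstants()
) -> OxDValue:
    """Exact algebraic inverse of :func:`e_gsh_from_oxd`.

    OxD = 1 / (1 + exp((E°′ − E)/(RT/2F))), clamped into [ε, 1−ε].
    """
    if not math.isfinite(e):
        raise OutOfRangeError("potential must be finite")
    z = (e0 - e) / consts.nernst_slope_mv
    oxd, clamped = _clamp_oxd(1.0 / (1.0 + math.exp(z)))
    return OxDValue(oxd=oxd, clamped_flag=clamped)


def q_from_e_gsh(
    e: float, e0: float, consts: RedoxConstants = RedoxConstants()
) -> float:
    """Q = [GSH]²/[GSSG] (molar, 1 M standard state) from E_GSH.

    Inverts E = E°′ − (RT/2F)·ln Q, giving Q = exp((E°′ − E)·2F/RT).
    Strictly decreasing in E.
    """
    if not math.isfinite(e):
        raise OutOfRangeError("potential must be finite")
    return math.exp((e0 - e) / consts.nernst_slope_mv)


def e_gsh_from_q(
    q: float, e0: float, consts: RedoxConstants = RedoxConstants()
) -> float:
    """E_GSH (mV) from Q = [GSH]²/[GSSG] in molar (1 M standard state)."""
    if not q > 0:
        raise OutOfRangeError("Q must be positive")
    return e0 - consts.nernst_slope_mv * math.log(q)


def r_gs_from_thiol_ratio(
    sh_to_ssg: float, grx: GrxEquilibrium = GRX_GOLGI
) -> float:
    """R_GS = [GSH]/[GSSG] from the glutaredoxin probe's thiol:disulfide ratio.

    R_GS = K_ox · [probe-SH]/[probe-SSG]; linear in both arguments.
    """
    if sh_to_ssg < 0:
        raise OutOfRangeError("thiol:disulfide ratio must be nonnegative")
    return grx.k_ox * sh_to_ssg


def pool_from_q_and_rgs(q: float, r_gs: float) -> GlutathionePool:
    """Absolute pool concentrations from Q and R_GS.

    [GSH] = Q/R_GS, [GSSG] = Q/R_GS², and the total pool
    [GS] = [GSH] + 2[GSSG] = Q/R_GS + 2·Q/R_GS² (the two forms are
    algebraically identical).
    """
    if not q > 0:
        raise OutOfRangeError("Q must be positive")
    if not r_gs > 0:
        raise OutOfRangeError("R_GS must be positive")
    gsh = q / r_gs
    gssg = q / r_gs**2
    return GlutathionePool(
        q=q, r_gs=r_gs, gsh=gsh, gssg=gssg, gs_total=gsh + 2.0 * gssg
    )


def propagate_uncertainty(
    per_cell_values: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    statistic: str = "mean",
    ci: float = 0.95,
) -> Tuple[float, float, float]:
    """Percentile-bootstrap summary of a per-cell quantity.

    Returns ``(point, lower, upper)`` where ``point`` is the chosen statistic
    (mean or median) of the observed values and the interval is the
    percentile bootstrap at level ``ci``.  Reproducible under a fixed seed.
    """
    values = np.asarray(per_cell_values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError(
            f"need at least 3 values, got {values.size}"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = stat(values[idx], axis=1)
    alpha = (1.0 - ci) / 2.0
    lower, upper = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(stat(values)), float(lower), float(upper)
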