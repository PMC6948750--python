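"""Thin spherical-shell applanation model of the cornea.

The cornea is treated as a thin, linear-elastic spherical shell of anterior
radius R (mm), central thickness t (mm) and Poisson's ratio ν, applanated by
the Goldmann tonometer over a fixed area A (mm²). Two dimensionless shell
coefficients summarise the geometry:

    B = 0.6 π R (R − t/2) √(1 − ν²) / t²
    C = 2 π R (R − t/2) / ((1 − ν) A t)

B weights the Goldmann reading (IOPG) and C the true intraocular pressure
(IOPT, taken from dynamic contour tonometry) in the modulus equation

    E = (B·IOPG − C·IOPT) / 7500      [MPa, pressures in mmHg]

A "calibration cornea" — a cornea with the cohort-average curvature and
thickness — is assumed to read true pressure on the Goldmann tonometer
(IOPG = IOPT there), which yields both a Goldmann-only modulus estimator
(``eiopg``) and a corrected true pressure (``ioptcalc``) for any test cornea.

Corneal structural stiffness is the thickness-modulus product k = t·E (N/mm).

Because the source equations are typeset ambiguously in places, the module
keeps the alternative algebraic readings of B and C behind explicit ``parse``
keywords; :func:`validate_parses` ranks them against the reference cohort
means and only the default survives. Everything here is closed-form and
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

from .exceptions import (
    DegenerateModelError,
    InvalidConstantsError,
    InvalidGeometryError,
    InvalidInputError,
)
from .reference import REFERENCE_COHORT

__all__ = [
    "ModelConstants",
    "CorneaGeometry",
    "ShellCoefficients",
    "CalibrationCornea",
    "TonometryPair",
    "ModulusEstimate",
    "StiffnessValue",
    "DEFAULT_CONSTANTS",
    "coefficient_b",
    "coefficient_c",
    "ioptcalc",
    "ecalc",
    "eiopg",
    "stiffness",
    "predicted_iopg",
    "validate_parses",
    "B_PARSES",
    "C_PARSES",
]

IoptVariant = Literal["printed", "consistency"]

#: Plausibility screen (soft warning only, not rejection).
_PLAUSIBLE_R_MM = (6.5, 9.5)
_PLAUSIBLE_T_MM = (0.35, 0.75)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physical constants of the applanation model.

    poisson_ratio
        ν of the corneal tissue; 0.49 (near-incompressible).
    applanation_area_mm2
        Applanated area A of the Goldmann prism, 7.35 mm².
    mmhg_per_mpa
        Unit divisor converting the mmHg-scale bracket B·IOPG − C·IOPT to MPa.
    shell_factor
        The 0.6 shell-theory multiplier in B.
    """

    poisson_ratio: float = 0.49
    applanation_area_mm2: float = 7.35
    mmhg_per_mpa: float = 7500.0
    shell_factor: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio < 1.0:
            raise InvalidConstantsError(
                f"poisson_ratio must be in [0, 1), got {self.poisson_ratio}"
            )
        if self.applanation_area_mm2 <= 0:
            raise InvalidConstantsError(
                f"applanation_area_mm2 must be > 0, got {self.applanation_area_mm2}"
            )
        if self.mmhg_per_mpa <= 0:
            raise InvalidConstantsError(
                f"mmhg_per_mpa must be > 0, got {self.mmhg_per_mpa}"
            )


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class CorneaGeometry:
    """Anterior radius of curvature R and central thickness t, both in mm."""

    radius_mm: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if not (self.radius_mm > 0 and math.isfinite(self.radius_mm)):
            raise InvalidGeometryError(f"radius must be positive, got {self.radius_mm}")
        if not (0 < self.thickness_mm < self.radius_mm):
            raise InvalidGeometryError(
                f"thickness must satisfy 0 < t < R, got t={self.thickness_mm}, "
                f"R={self.radius_mm}"
            )
        lo, hi = _PLAUSIBLE_R_MM
        if not lo <= self.radius_mm <= hi:
            warnings.warn(
                f"radius {self.radius_mm} mm outside plausible corneal range "
                f"[{lo}, {hi}] mm",
                stacklevel=3,
            )
        lo, hi = _PLAUSIBLE_T_MM
        if not lo <= self.thickness_mm <= hi:
            warnings.warn(
                f"thickness {self.thickness_mm} mm outside plausible corneal "
                f"range [{lo}, {hi}] mm",
                stacklevel=3,
            )

    @property
    def thickness_um(self) -> float:
        return self.thickness_mm * 1000.0


def _b_default(R: float, t: float, nu: float, factor: float) -> float:
    return factor * math.pi * R * (R - t / 2.0) * math.sqrt(1.0 - nu * nu) / (t * t)


def _b_no_sqrt(R: float, t: float, nu: float, factor: float) -> float:
    return factor * math.pi * R * (R - t / 2.0) * (1.0 - nu * nu) / (t * t)


def _b_gap_squared(R: float, t: float, nu: float, factor: float) -> float:
    return factor * math.pi * (R - t) ** 2 * math.sqrt(1.0 - nu * nu) / (t * t)


def _c_default(R: float, t: float, nu: float, A: float) -> float:
    return 2.0 * math.pi * R * (R - t / 2.0) / ((1.0 - nu) * A * t)


def _c_two_in_denominator(R: float, t: float, nu: float, A: float) -> float:
    return math.pi * R * (R - t / 2.0) / (2.0 * (1.0 - nu) * A * t)


def _c_two_one_minus_nu_numerator(R: float, t: float, nu: float, A: float) -> float:
    return math.pi * R * (R - t / 2.0) * 2.0 * (1.0 - nu) / (A * t)


#: Alternative algebraic readings of the ambiguously typeset coefficients.
B_PARSES: dict[str, Callable[[float, float, float, float], float]] = {
    "default": _b_default,
    "no_sqrt": _b_no_sqrt,
    "gap_squared": _b_gap_squared,
}
C_PARSES: dict[str, Callable[[float, float, float, float], float]] = {
    "default": _c_default,
    "two_in_denominator": _c_two_in_denominator,
    "two_one_minus_nu_numerator": _c_two_one_minus_nu_numerator,
}


def coefficient_b(
    geometry: CorneaGeometry,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    parse: str = "default",
) -> float:
    """Dimensionless Goldmann-reading coefficient B of a cornea."""
    try:
        fn = B_PARSES[parse]
    except KeyError:
        raise InvalidInputError(f"unknown B parse {parse!r}") from None
    return fn(
        geometry.radius_mm,
        geometry.thickness_mm,
        constants.poisson_ratio,
        constants.shell_factor,
    )


def coefficient_c(
    geometry: CorneaGeometry,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    parse: str = "default",
) -> float:
    """Dimensionless true-pressure coefficient C of a cornea."""
    try:
        fn = C_PARSES[parse]
    except KeyError:
        raise InvalidInputError(f"unknown C parse {parse!r}") from None
    return fn(
        geometry.radius_mm,
        geometry.thickness_mm,
        constants.poisson_ratio,
        constants.applanation_area_mm2,
    )


@dataclass(frozen=True)
class ShellCoefficients:
    """The (B, C) pair of a given cornea under fixed model constants."""

    b_coeff: float
    c_coeff: float

    def __post_init__(self) -> None:
        if not (self.b_coeff > 0 and math.isfinite(self.b_coeff)):
            raise DegenerateModelError(f"B must be positive, got {self.b_coeff}")
        if not (self.c_coeff > 0 and math.isfinite(self.c_coeff)):
            raise DegenerateModelError(f"C must be positive, got {self.c_coeff}")

    @classmethod
    def from_geometry(
        cls,
        geometry: CorneaGeometry,
        constants: ModelConstants = DEFAULT_CONSTANTS,
        b_parse: str = "default",
        c_parse: str = "default",
    ) -> "ShellCoefficients":
        return cls(
            b_coeff=coefficient_b(geometry, constants, parse=b_parse),
            c_coeff=coefficient_c(geometry, constants, parse=c_parse),
        )


@dataclass(frozen=True)
class CalibrationCornea:
    """The average cornea at which the Goldmann reading equals true IOP.

    Its coefficients (Bc, Cc) are always derived from its geometry under the
    active constants; construct via :meth:`from_geometry`.
    """

    geometry: CorneaGeometry
    coefficients: ShellCoefficients
    constants: ModelConstants = field(default=DEFAULT_CONSTANTS)

    @classmethod
    def from_geometry(
        cls,
        geometry: CorneaGeometry,
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ) -> "CalibrationCornea":
        return cls(
            geometry=geometry,
            coefficients=ShellCoefficients.from_geometry(geometry, constants),
            constants=constants,
        )

    @classmethod
    def reference(
        cls, constants: ModelConstants = DEFAULT_CONSTANTS
    ) -> "CalibrationCornea":
        """Calibration cornea at the published reference-cohort means."""
        ref = REFERENCE_COHORT
        return cls.from_geometry(
            CorneaGeometry(ref.ccc_mean_mm, ref.cct_mean_um / 1000.0), constants
        )


@dataclass(frozen=True)
class TonometryPair:
    """A Goldmann reading and a true-pressure reading (mmHg) for one cornea.

    ``iopt`` is either a contour-tonometer measurement or a calculated true
    pressure. Negative pressures are rejected; zero is tolerated so the
    linear identities (E(0, 0) = 0) hold.
    """

    iopg: float
    iopt: float

    def __post_init__(self) -> None:
        for name, v in (("iopg", self.iopg), ("iopt", self.iopt)):
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidInputError(f"{name} must be a non-negative pressure, got {v}")


@dataclass(frozen=True)
class ModulusEstimate:
    """A Young's modulus estimate in MPa with its provenance tag.

    ``negative_flag`` marks raw values ≤ 0 (possible when C·IOPT > B·IOPG);
    the value is retained, never clamped.
    """

    value: float
    method_tag: str
    negative_flag: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InvalidInputError(f"modulus must be finite, got {self.value}")
        if self.negative_flag != (self.value <= 0):
            raise InvalidInputError("negative_flag inconsistent with value")


@dataclass(frozen=True)
class StiffnessValue:
    """Structural stiffness k = t·E in N/mm (MPa·mm ≡ N/mm)."""

    value: float


def ioptcalc(
    iopg: float,
    test: ShellCoefficients,
    calib: ShellCoefficients,
    variant: IoptVariant = "consistency",
) -> float:
    """Calculated true IOP (mmHg) from a Goldmann reading alone.

    Two subscript placements of the correction formula are supported:

    ``printed``       IOPG · (Bc − Cc + C) / B  — as typeset in the source;
    ``consistency``   IOPG · (B − C + Cc) / Bc  — subscript-swapped form whose
                      direction matches the reported negative correlation
                      between calculated true IOP and corneal thickness
                      (Goldmann over-reads thick corneas). Default.

    Both reduce exactly to IOPG when the test cornea is the calibration
    cornea.
    """
    if iopg < 0 or not math.isfinite(iopg):
        raise InvalidInputError(f"iopg must be non-negative, got {iopg}")
    if variant == "printed":
        return iopg * (calib.b_coeff - calib.c_coeff + test.c_coeff) / test.b_coeff
    if variant == "consistency":
        return iopg * (test.b_coeff - test.c_coeff + calib.c_coeff) / calib.b_coeff
    raise InvalidInputError(f"unknown ioptcalc variant {variant!r}")


def ecalc(
    pair: TonometryPair,
    test: ShellCoefficients,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    method_tag: str = "ecalc",
) -> ModulusEstimate:
    """Young's modulus from both tonometers: E = (B·IOPG − C·IOPT)/7500."""
    raw = (test.b_coeff * pair.iopg - test.c_coeff * pair.iopt) / constants.mmhg_per_mpa
    return ModulusEstimate(value=raw, method_tag=method_tag, negative_flag=raw <= 0)


def eiopg(
    iopg: float,
    test: ShellCoefficients,
    calib: ShellCoefficients,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    variant: IoptVariant = "consistency",
) -> ModulusEstimate:
    """Goldmann-only modulus: ``ecalc`` with the calculated true IOP.

    Proportional to IOPG at fixed geometry.
    """
    iopt = ioptcalc(iopg, test, calib, variant=variant)
    raw = (test.b_coeff * iopg - test.c_coeff * iopt) / constants.mmhg_per_mpa
    return ModulusEstimate(value=raw, method_tag="eiopg", negative_flag=raw <= 0)


def stiffness(thickness_mm: float, modulus_mpa: float) -> StiffnessValue:
    """Structural stiffness k = t·E (N/mm)."""
    if thickness_mm <= 0:
        raise InvalidGeometryError(f"thickness must be positive, got {thickness_mm}")
    return StiffnessValue(value=thickness_mm * modulus_mpa)


def predicted_iopg(
    true_iop: float,
    modulus_mpa: float,
    test: ShellCoefficients,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Forward model: the Goldmann reading a cornea of given modulus produces.

    Algebraic inverse of ``ecalc``: IOPG = (7500·E + C·IOPT)/B. Used by the
    error-decomposition curves and the synthetic-cohort simulator.
    """
    if test.b_coeff <= 0:
        raise DegenerateModelError(f"B must be positive, got {test.b_coeff}")
    return (constants.mmhg_per_mpa * modulus_mpa + test.c_coeff * true_iop) / test.b_coeff


def validate_parses(
    constants: ModelConstants = DEFAULT_CONSTANTS,
    tolerance_mpa: float = 0.04,
) -> dict[tuple[str, str], dict[str, float | bool]]:
    """Rank the candidate (B, C) parses against the reference cohort means.

    For each parse combination, evaluates the two modulus estimators at the
    reference cohort's mean geometry and mean pressures and accepts the
    combination only if both land within ``tolerance_mpa`` of the published
    cohort means (0.25 / 0.29 MPa). Only the default-default combination
    survives this screen.
    """
    ref = REFERENCE_COHORT
    geom = CorneaGeometry(ref.ccc_mean_mm, ref.cct_mean_um / 1000.0)
    out: dict[tuple[str, str], dict[str, float | bool]] = {}
    for b_name in B_PARSES:
        for c_name in C_PARSES:
            coeffs = ShellCoefficients.from_geometry(
                geom, constants, b_parse=b_name, c_parse=c_name
            )
            e_both = ecalc(
                TonometryPair(ref.iopg_mean_mmhg, ref.pdct_mean_mmhg), coeffs, constants
            ).value
            e_goldmann = eiopg(
                ref.iopg_mean_mmhg, coeffs, coeffs, constants
            ).value
            out[(b_name, c_name)] = {
                "ecalc_at_means_mpa": e_both,
                "eiopg_at_means_mpa": e_goldmann,
                "accepted": (
                    abs(e_both - ref.ecalc_mean_mpa) <= tolerance_mpa
                    and abs(e_goldmann - ref.eiopg_mean_mpa) <= tolerance_mpa
                ),
            }
    return out
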