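"""Decomposition of the Goldmann tonometry error over corneal thickness.

Two mechanisms pull the Goldmann reading away from true IOP as central
corneal thickness (CCT) varies across a population:

* **effect of CCT** — at fixed tissue modulus, a thicker shell resists
  applanation more, so the reading rises with t;
* **effect of E** — in real cohorts the fitted modulus falls as CCT rises,
  which pushes the reading back down.

Each curve is the predicted Goldmann reading minus its value at the
calibration thickness (positive = over-reading), so component curves vanish
at the calibration point by construction. Their near-cancellation in normal
young cohorts is the reason Goldmann error appears insensitive to CCT alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .exceptions import InvalidInputError
from .shell import (
    DEFAULT_CONSTANTS,
    CalibrationCornea,
    CorneaGeometry,
    ModelConstants,
    ShellCoefficients,
    predicted_iopg,
)

__all__ = [
    "ErrorCurve",
    "default_grid_um",
    "effect_of_cct_curve",
    "effect_of_e_curve",
    "net_error_curve",
    "curve_span",
]

CurveLabel = Literal["effect_of_cct", "effect_of_e", "net"]


@dataclass(frozen=True)
class ErrorCurve:
    """Predicted Goldmann-reading error (mmHg) over a CCT grid (μm)."""

    grid_um: np.ndarray
    errors_mmhg: np.ndarray
    label: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_um, dtype=float)
        errors = np.asarray(self.errors_mmhg, dtype=float)
        object.__setattr__(self, "grid_um", grid)
        object.__setattr__(self, "errors_mmhg", errors)
        if grid.ndim != 1 or grid.size == 0:
            raise InvalidInputError("grid must be a non-empty 1-d array")
        if not np.all(np.diff(grid) > 0):
            raise InvalidInputError("grid must be strictly increasing")
        if errors.shape != grid.shape:
            raise InvalidInputError("errors must align with the grid")
        if not np.all(np.isfinite(errors)):
            raise InvalidInputError("errors must be finite")


def default_grid_um(
    lo_um: float = 450.0, hi_um: float = 650.0, step_um: float = 5.0
) -> np.ndarray:
    """The default 200 μm thickness grid, 450-650 μm in 5 μm steps."""
    if not (hi_um > lo_um > 0 and step_um > 0):
        raise InvalidInputError("grid bounds must satisfy 0 < lo < hi, step > 0")
    n = int(round((hi_um - lo_um) / step_um))
    return lo_um + step_um * np.arange(n + 1)


def _reading_at_thickness(
    t_um: float,
    radius_mm: float,
    modulus_mpa: float,
    true_iop: float,
    constants: ModelConstants,
) -> float:
    geom = CorneaGeometry(radius_mm, t_um / 1000.0)
    coeffs = ShellCoefficients.from_geometry(geom, constants)
    return predicted_iopg(true_iop, modulus_mpa, coeffs, constants)


def effect_of_cct_curve(
    grid_um: Sequence[float],
    calib: CalibrationCornea,
    fixed_modulus_mpa: float,
    true_iop_mmhg: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ErrorCurve:
    """Goldmann error attributable to thickness alone, at fixed modulus.

    Sweeps t over the grid with radius held at the calibration value; the
    error at each point is the predicted reading minus the predicted reading
    at the calibration thickness.
    """
    if fixed_modulus_mpa <= 0 or true_iop_mmhg <= 0:
        raise InvalidInputError("fixed modulus and true IOP must be positive")
    grid = np.asarray(grid_um, dtype=float)
    R = calib.geometry.radius_mm
    with np.errstate(all="raise"):
        base = _reading_at_thickness(
            calib.geometry.thickness_um, R, fixed_modulus_mpa, true_iop_mmhg, constants
        )
        errors = np.array(
            [
                _reading_at_thickness(t, R, fixed_modulus_mpa, true_iop_mmhg, constants)
                - base
                for t in grid
            ]
        )
    return ErrorCurve(grid_um=grid, errors_mmhg=errors, label="effect_of_cct")


def effect_of_e_curve(
    grid_um: Sequence[float],
    calib: CalibrationCornea,
    modulus_of_cct: Callable[[float], float],
    true_iop_mmhg: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ErrorCurve:
    """Goldmann error attributable to the modulus-vs-thickness trend alone.

    Geometry is held at the calibration cornea; only the modulus varies with
    thickness through ``modulus_of_cct`` (CCT in μm → E in MPa), typically an
    OLS fit of the Goldmann-only modulus on CCT from a loaded cohort.
    """
    if true_iop_mmhg <= 0:
        raise InvalidInputError("true IOP must be positive")
    grid = np.asarray(grid_um, dtype=float)
    coeffs = calib.coefficients
    try:
        e_at_calib = float(modulus_of_cct(calib.geometry.thickness_um))
        e_values = [float(modulus_of_cct(t)) for t in grid]
    except Exception as exc:
        raise InvalidInputError(
            f"modulus_of_cct is not defined over the grid: {exc}"
        ) from exc
    base = predicted_iopg(true_iop_mmhg, e_at_calib, coeffs, constants)
    errors = np.array(
        [predicted_iopg(true_iop_mmhg, e, coeffs, constants) - base for e in e_values]
    )
    return ErrorCurve(grid_um=grid, errors_mmhg=errors, label="effect_of_e")


def net_error_curve(
    cct_curve: ErrorCurve,
    e_curve: ErrorCurve,
    mode: Literal["sum", "empirical"] = "sum",
    empirical_slope_mmhg_per_um: float | None = None,
    calibration_cct_um: float | None = None,
) -> ErrorCurve:
    """Net Goldmann error over the thickness grid.

    ``sum`` adds the two component curves pointwise. ``empirical`` evaluates
    a cohort-fitted linear regression of (IOPG − true IOP) on CCT, centred to
    zero at the calibration thickness; pass its slope and the calibration
    thickness.
    """
    if cct_curve.grid_um.shape != e_curve.grid_um.shape or not np.allclose(
        cct_curve.grid_um, e_curve.grid_um
    ):
        raise InvalidInputError("component curves must share one grid")
    grid = cct_curve.grid_um
    if mode == "sum":
        errors = cct_curve.errors_mmhg + e_curve.errors_mmhg
    elif mode == "empirical":
        if empirical_slope_mmhg_per_um is None or calibration_cct_um is None:
            raise InvalidInputError(
                "empirical mode needs a fitted slope and the calibration CCT"
            )
        errors = empirical_slope_mmhg_per_um * (grid - calibration_cct_um)
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    return ErrorCurve(grid_um=grid, errors_mmhg=errors, label="net")


def curve_span(curve: ErrorCurve) -> float:
    """Peak-to-peak error over the grid, max − min (mmHg, non-negative)."""
    return float(np.max(curve.errors_mmhg) - np.min(curve.errors_mmhg))
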