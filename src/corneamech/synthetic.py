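"""Synthetic clinical cohorts from the forward observation model.

Each subject carries a latent state (anterior radius R, central thickness t,
true intraocular pressure, true Young's modulus E). Geometry is drawn from a
bivariate normal with the weak positive thickness-curvature correlation seen
in young normal cohorts; pressure and modulus are independent normals. All
draws are truncated to physical validity. The instruments then observe:

* keratometry: R + noise, two readings;
* pachymetry: t + noise, three readings (emitted in μm);
* contour tonometry: true IOP + noise, three readings with quality grades
  (the contour reading is modelled as unbiased for true pressure);
* Goldmann tonometry: the shell model's predicted reading for (R, t, E,
  true IOP) + noise, three readings.

With zero noise the pipeline inverts the forward model exactly, so the
dual-tonometer modulus estimate recovers the latent E to round-off — the
basis of the parameter-recovery study. Population SDs default to the
reference cohort's between-subject SDs; instrument noise defaults to 25% of
each (a declared assumption: the two variance sources are not separable
from a single cohort's summary statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import GenerationError, InvalidInputError
from .pipeline import (
    DEFAULT_COLUMNS,
    SubjectRecord,
    cohort_calibration,
    estimate_subject,
    prepare_subject,
)
from .reference import REFERENCE_COHORT
from .shell import (
    DEFAULT_CONSTANTS,
    CorneaGeometry,
    ModelConstants,
    ShellCoefficients,
    predicted_iopg,
)

__all__ = [
    "SyntheticSpec",
    "TrueState",
    "draw_true_states",
    "simulate_readings",
    "records_to_frame",
    "write_cohort_csv",
    "recovery_study",
    "RecoveryReport",
]

_REF = REFERENCE_COHORT

#: Quality-grade distribution over grades 1-5 (1 best); grades 4-5 are rare
#: and rejected by the default quality filter.
_QUALITY_GRADES = np.array([1, 2, 3, 4, 5])
_QUALITY_PROBS = np.array([0.38, 0.38, 0.19, 0.03, 0.02])


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration; defaults emulate the reference cohort."""

    n_subjects: int = 100
    r_mean_mm: float = _REF.ccc_mean_mm
    r_sd_mm: float = _REF.ccc_sd_mm
    t_mean_um: float = _REF.cct_mean_um
    t_sd_um: float = _REF.cct_sd_um
    iop_mean_mmhg: float = _REF.pdct_mean_mmhg
    iop_sd_mmhg: float = _REF.pdct_sd_mmhg
    e_mean_mpa: float = _REF.eiopg_mean_mpa
    e_sd_mpa: float = _REF.eiopg_sd_mpa
    corr_t_r: float = _REF.corr_cct_ccc
    # per-reading instrument noise SDs (25% of the between-subject SDs)
    noise_keratometry_mm: float = 0.25 * _REF.ccc_sd_mm
    noise_pachymetry_um: float = 0.25 * _REF.cct_sd_um
    noise_goldmann_mmhg: float = 0.25 * _REF.iopg_sd_mmhg
    noise_pdct_mmhg: float = 0.25 * _REF.pdct_sd_mmhg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        if not abs(self.corr_t_r) < 1:
            raise InvalidInputError("|corr_t_r| must be < 1")
        for name in (
            "r_sd_mm",
            "t_sd_um",
            "iop_sd_mmhg",
            "e_sd_mpa",
            "noise_keratometry_mm",
            "noise_pachymetry_um",
            "noise_goldmann_mmhg",
            "noise_pdct_mmhg",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    def with_noise_scale(self, scale: float) -> "SyntheticSpec":
        """Scale every instrument-noise SD by a common factor."""
        return replace(
            self,
            noise_keratometry_mm=scale * self.noise_keratometry_mm,
            noise_pachymetry_um=scale * self.noise_pachymetry_um,
            noise_goldmann_mmhg=scale * self.noise_goldmann_mmhg,
            noise_pdct_mmhg=scale * self.noise_pdct_mmhg,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticSpec":
        """Parse a plain-text ``key = value`` spec file."""
        kwargs: dict[str, float | int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidInputError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise InvalidInputError(f"unknown spec key {key!r} in {path}")
            kwargs[key] = int(value) if key in {"n_subjects", "seed"} else float(value)
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TrueState:
    """Latent per-subject state of the forward model."""

    radius_mm: float
    thickness_mm: float
    true_iop_mmhg: float
    true_e_mpa: float


_MAX_REDRAWS = 1000


def draw_true_states(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[TrueState]:
    """Draw latent subject states, truncated to physical validity.

    (R, t) come from a bivariate normal with correlation ``corr_t_r``;
    pressure and modulus are independent normals truncated positive.
    Invalid draws (non-positive, or t ≥ R) are redrawn; failure to produce a
    valid cohort within a bounded number of redraws (pathological spec, e.g.
    SD far exceeding the mean) raises a generation error.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cov = np.array(
        [
            [spec.r_sd_mm**2, spec.corr_t_r * spec.r_sd_mm * spec.t_sd_um / 1000.0],
            [
                spec.corr_t_r * spec.r_sd_mm * spec.t_sd_um / 1000.0,
                (spec.t_sd_um / 1000.0) ** 2,
            ],
        ]
    )
    mean = np.array([spec.r_mean_mm, spec.t_mean_um / 1000.0])
    states: list[TrueState] = []
    attempts = 0
    while len(states) < spec.n_subjects:
        if attempts > _MAX_REDRAWS + spec.n_subjects:
            raise GenerationError(
                f"could not draw {spec.n_subjects} valid subjects after "
                f"{attempts} attempts; check the spec's means and SDs"
            )
        attempts += 1
        r, t = rng.multivariate_normal(mean, cov)
        iop = rng.normal(spec.iop_mean_mmhg, spec.iop_sd_mmhg)
        e = rng.normal(spec.e_mean_mpa, spec.e_sd_mpa)
        if r <= 0 or t <= 0 or t >= r or iop <= 0 or e <= 0:
            continue
        states.append(
            TrueState(radius_mm=r, thickness_mm=t, true_iop_mmhg=iop, true_e_mpa=e)
        )
    return states


def simulate_readings(
    states: Sequence[TrueState],
    spec: SyntheticSpec,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    eye: str = "left",
) -> list[SubjectRecord]:
    """Observe each latent state through the four instruments.

    Replicate counts follow clinical practice: 2 keratometry, 3 pachymetry,
    3 Goldmann, 3 contour readings with quality grades. Noise is additive,
    zero-mean, per reading. Readings that would come out non-positive under
    extreme noise are clamped away from zero at a tiny floor (never hit at
    realistic noise levels).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    records: list[SubjectRecord] = []
    floor = 1e-6
    for i, st in enumerate(states):
        coeffs = ShellCoefficients.from_geometry(
            CorneaGeometry(st.radius_mm, st.thickness_mm), constants
        )
        goldmann_true = predicted_iopg(st.true_iop_mmhg, st.true_e_mpa, coeffs, constants)
        ccc = st.radius_mm + rng.normal(0.0, spec.noise_keratometry_mm, 2)
        cct_um = st.thickness_mm * 1000.0 + rng.normal(0.0, spec.noise_pachymetry_um, 3)
        iopg = goldmann_true + rng.normal(0.0, spec.noise_goldmann_mmhg, 3)
        pdct = st.true_iop_mmhg + rng.normal(0.0, spec.noise_pdct_mmhg, 3)
        quality = rng.choice(_QUALITY_GRADES, size=3, p=_QUALITY_PROBS)
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                eye=eye,
                ccc_readings_mm=tuple(np.maximum(ccc, floor)),
                cct_readings_mm=tuple(np.maximum(cct_um, floor) / 1000.0),
                iopg_readings_mmhg=tuple(np.maximum(iopg, floor)),
                pdct_readings_mmhg=tuple(np.maximum(pdct, floor)),
                pdct_quality=tuple(int(q) for q in quality),
            )
        )
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Emit records in the canonical CSV schema the pipeline reads."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"subject_id": rec.subject_id, "eye": rec.eye}
        for col, val in zip(DEFAULT_COLUMNS["ccc"], rec.ccc_readings_mm):
            row[col] = val
        for col, val in zip(DEFAULT_COLUMNS["cct"], rec.cct_readings_mm):
            row[col] = val * 1000.0
        for col, val in zip(DEFAULT_COLUMNS["iopg"], rec.iopg_readings_mmhg):
            row[col] = val
        for col, val in zip(DEFAULT_COLUMNS["pdct"], rec.pdct_readings_mmhg):
            row[col] = val
        for col, val in zip(DEFAULT_COLUMNS["pdct_quality"], rec.pdct_quality):
            row[col] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")
    return path


@dataclass(frozen=True)
class RecoveryReport:
    """Bias / RMSE of the dual-tonometer modulus estimate against truth."""

    noise_scale: float
    n_replicates: int
    n_subjects: int
    bias_mpa: float
    rmse_mpa: float
    per_replicate_bias: tuple[float, ...] = field(repr=False, default=())


def _replicate_errors(
    spec: SyntheticSpec, rng: np.random.Generator, constants: ModelConstants
) -> np.ndarray:
    states = draw_true_states(spec, rng)
    records = simulate_readings(states, spec, constants, rng)
    means = [prepare_subject(r) for r in records]
    calib = cohort_calibration(means, constants)
    errs = []
    for st, m in zip(states, means):
        est = estimate_subject(m, calib, constants)
        if est.ecalc is None:  # quality filter removed all contour readings
            continue
        errs.append(est.ecalc.value - st.true_e_mpa)
    return np.asarray(errs)


def recovery_study(
    spec: SyntheticSpec,
    n_replicates: int = 50,
    seed: int | None = None,
    noise_scales: Sequence[float] = (0.0, 1.0),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[RecoveryReport]:
    """Generate → analyse → compare, over replicates and noise levels.

    For each noise scale, runs ``n_replicates`` independent cohorts through
    the full pipeline and reports the bias and RMSE of the dual-tonometer
    modulus estimate against the latent truth. At scale 0 the pipeline
    inverts the forward model exactly, so bias and RMSE vanish to round-off.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    base_seed = spec.seed if seed is None else seed
    reports = []
    for scale in noise_scales:
        scaled = spec.with_noise_scale(scale)
        all_errs = []
        biases = []
        for rep in range(n_replicates):
            rng = np.random.default_rng((base_seed, int(scale * 1e6), rep))
            errs = _replicate_errors(scaled, rng, constants)
            all_errs.append(errs)
            biases.append(float(np.mean(errs)) if errs.size else math.nan)
        pooled = np.concatenate(all_errs) if all_errs else np.array([])
        reports.append(
            RecoveryReport(
                noise_scale=float(scale),
                n_replicates=n_replicates,
                n_subjects=spec.n_subjects,
                bias_mpa=float(np.mean(pooled)),
                rmse_mpa=float(np.sqrt(np.mean(pooled**2))),
                per_replicate_bias=tuple(biases),
            )
        )
    return reports
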