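"""Cohort pipeline: read clinical records, average readings, estimate moduli.

A subject record carries the raw repeated readings of one eye: two
keratometry readings (central corneal curvature), three pachymetry readings
(central corneal thickness), three Goldmann tonometry readings and three
contour-tonometry readings with their quality grades. The pipeline averages
readings per instrument (dropping contour readings whose quality grade
exceeds the acceptance grade), forms the corneal geometry in mm, computes
the shell coefficients and both modulus estimators against a calibration
cornea (by default the cohort's own mean geometry), and summarises the
cohort with the statistical battery in :mod:`corneamech.stats`.

Input is CSV or XLSX with a plain-text column-mapping file (``key = column``
lines) because deposited clinical workbooks rarely share a layout. Lengths
are stored in mm internally; pachymetry columns declared in μm are divided
by 1000 and keratometry columns declared in dioptres are converted through
r = 337.5/K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError
from .reference import radius_from_dioptres
from .shell import (
    DEFAULT_CONSTANTS,
    CalibrationCornea,
    CorneaGeometry,
    IoptVariant,
    ModelConstants,
    ModulusEstimate,
    ShellCoefficients,
    StiffnessValue,
    TonometryPair,
    ecalc,
    eiopg,
    ioptcalc,
    stiffness,
)
from .stats import (
    BlandAltmanResult,
    CorrelationMatrix,
    RegressionFit,
    bland_altman,
    correlation_matrix,
    ols_fit,
)

__all__ = [
    "ColumnMapping",
    "SubjectRecord",
    "SubjectMeans",
    "SubjectEstimate",
    "CohortSummary",
    "load_cohort",
    "prepare_subject",
    "cohort_calibration",
    "estimate_subject",
    "summarize_cohort",
    "write_results",
    "run_cohort",
    "estimates_frame",
]

logger = logging.getLogger(__name__)

Eye = Literal["left", "right"]

#: Canonical CSV schema emitted by the synthetic generator and accepted
#: without a mapping file.
DEFAULT_COLUMNS: dict[str, object] = {
    "subject_id": "subject_id",
    "eye": "eye",
    "ccc": ["ccc_mm_1", "ccc_mm_2"],
    "ccc_unit": "mm",
    "cct": ["cct_um_1", "cct_um_2", "cct_um_3"],
    "cct_unit": "um",
    "iopg": ["iopg_mmhg_1", "iopg_mmhg_2", "iopg_mmhg_3"],
    "pdct": ["pdct_mmhg_1", "pdct_mmhg_2", "pdct_mmhg_3"],
    "pdct_quality": ["pdct_q_1", "pdct_q_2", "pdct_q_3"],
}


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical fields to the source file's column names."""

    subject_id: str = "subject_id"
    eye: str | None = "eye"
    ccc: tuple[str, ...] = ("ccc_mm_1", "ccc_mm_2")
    cct: tuple[str, ...] = ("cct_um_1", "cct_um_2", "cct_um_3")
    iopg: tuple[str, ...] = ("iopg_mmhg_1", "iopg_mmhg_2", "iopg_mmhg_3")
    pdct: tuple[str, ...] = ("pdct_mmhg_1", "pdct_mmhg_2", "pdct_mmhg_3")
    pdct_quality: tuple[str, ...] = ("pdct_q_1", "pdct_q_2", "pdct_q_3")
    ccc_unit: Literal["mm", "dioptre"] = "mm"
    cct_unit: Literal["um", "mm"] = "um"

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        """Parse a ``key = value`` mapping file.

        Repeated-reading fields take comma-separated column lists, e.g.
        ``cct = CCT1, CCT2, CCT3``. ``#`` starts a comment. Unknown keys are
        a configuration error, as is a missing required field.
        """
        entries: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            entries[key] = value
        kwargs: dict[str, object] = {}
        multi = {"ccc", "cct", "iopg", "pdct", "pdct_quality"}
        for key, value in entries.items():
            if key in multi:
                kwargs[key] = tuple(col.strip() for col in value.split(",") if col.strip())
            elif key in {"subject_id", "eye", "ccc_unit", "cct_unit"}:
                kwargs[key] = value if value.lower() != "none" else None
            else:
                raise ConfigurationError(f"unknown mapping key {key!r} in {path}")
        try:
            return cls(**kwargs)  # type: ignore[arg-type]
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def required_columns(self) -> list[str]:
        cols = [self.subject_id, *self.ccc, *self.cct, *self.iopg]
        if self.eye:
            cols.append(self.eye)
        cols.extend(self.pdct)
        cols.extend(self.pdct_quality)
        return cols


@dataclass(frozen=True)
class SubjectRecord:
    """Raw repeated readings for one eye of one subject.

    Curvature in mm, thickness in mm (converted at load), pressures in mmHg.
    Quality grades align with the contour-tonometry readings (1 best).
    """

    subject_id: str
    eye: str
    ccc_readings_mm: tuple[float, ...]
    cct_readings_mm: tuple[float, ...]
    iopg_readings_mmhg: tuple[float, ...]
    pdct_readings_mmhg: tuple[float, ...] = ()
    pdct_quality: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("ccc_readings_mm", "cct_readings_mm", "iopg_readings_mmhg"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise InvalidInputError(f"{name} empty for subject {self.subject_id}")
            if any(v <= 0 or not math.isfinite(v) for v in vals):
                raise InvalidInputError(
                    f"non-positive {name} for subject {self.subject_id}: {vals}"
                )
        if any(v <= 0 for v in self.pdct_readings_mmhg):
            raise InvalidInputError(
                f"non-positive contour reading for subject {self.subject_id}"
            )
        if self.pdct_quality and len(self.pdct_quality) != len(self.pdct_readings_mmhg):
            raise InvalidInputError(
                f"quality grades misaligned for subject {self.subject_id}"
            )


@dataclass(frozen=True)
class SubjectMeans:
    """Per-instrument mean readings, ready for estimation."""

    subject_id: str
    eye: str
    geometry: CorneaGeometry
    iopg_mean_mmhg: float
    pdct_mean_mmhg: float | None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SubjectEstimate:
    """All derived quantities for one subject."""

    subject_id: str
    eye: str
    geometry: CorneaGeometry
    iopg_mean_mmhg: float
    pdct_mean_mmhg: float | None
    coefficients: ShellCoefficients
    ioptcalc_mmhg: float
    ecalc: ModulusEstimate | None
    eiopg: ModulusEstimate
    k_calc: StiffnessValue | None
    k_iopg: StiffnessValue
    flags: tuple[str, ...] = ()


def _parse_row(
    row: pd.Series, mapping: ColumnMapping, row_number: int
) -> SubjectRecord:
    def floats(cols: Sequence[str]) -> tuple[float, ...]:
        out = []
        for col in cols:
            val = row[col]
            if pd.isna(val):
                continue
            out.append(float(val))
        return tuple(out)

    ccc = floats(mapping.ccc)
    if mapping.ccc_unit == "dioptre":
        ccc = tuple(radius_from_dioptres(k) for k in ccc)
    cct = floats(mapping.cct)
    if mapping.cct_unit == "um":
        cct = tuple(v / 1000.0 for v in cct)
    pdct = floats(mapping.pdct) if mapping.pdct else ()
    quality: tuple[int, ...] = ()
    if mapping.pdct_quality:
        qvals = floats(mapping.pdct_quality)
        quality = tuple(int(q) for q in qvals)
        if len(quality) != len(pdct):
            raise InvalidInputError(f"row {row_number}: quality grades misaligned")
    eye = str(row[mapping.eye]).strip().lower() if mapping.eye else "left"
    return SubjectRecord(
        subject_id=str(row[mapping.subject_id]),
        eye=eye,
        ccc_readings_mm=ccc,
        cct_readings_mm=cct,
        iopg_readings_mmhg=floats(mapping.iopg),
        pdct_readings_mmhg=pdct,
        pdct_quality=quality,
    )


def load_cohort(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    sheet: int | str = 0,
) -> list[SubjectRecord]:
    """Read subject records from a CSV or XLSX file.

    Malformed rows are skipped and logged with their row numbers; a missing
    mapped column is a configuration error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    mapping = mapping or ColumnMapping()
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, sheet_name=sheet)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in mapping.required_columns() if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped columns absent from file: {missing}; "
            f"available: {list(frame.columns)}"
        )
    records: list[SubjectRecord] = []
    for idx, row in frame.iterrows():
        row_number = int(idx) + 2  # header is row 1
        try:
            records.append(_parse_row(row, mapping, row_number))
        except (InvalidInputError, ValueError) as exc:
            logger.warning("skipping row %d of %s: %s", row_number, path, exc)
    return records


def prepare_subject(record: SubjectRecord, quality_max: int = 3) -> SubjectMeans:
    """Average the repeated readings, filtering low-quality contour readings.

    Contour readings with a grade above ``quality_max`` (grade 1 best) are
    dropped before averaging. If none survive, the subject is flagged
    ``pdct-missing``; the Goldmann-only modulus is still computable.
    """
    flags: list[str] = []
    pdct = list(record.pdct_readings_mmhg)
    if record.pdct_quality:
        pdct = [
            v
            for v, q in zip(record.pdct_readings_mmhg, record.pdct_quality)
            if q <= quality_max
        ]
        if len(pdct) < len(record.pdct_readings_mmhg):
            flags.append("pdct-quality-filtered")
    pdct_mean = float(np.mean(pdct)) if pdct else None
    if pdct_mean is None:
        flags.append("pdct-missing")
    geometry = CorneaGeometry(
        radius_mm=float(np.mean(record.ccc_readings_mm)),
        thickness_mm=float(np.mean(record.cct_readings_mm)),
    )
    return SubjectMeans(
        subject_id=record.subject_id,
        eye=record.eye,
        geometry=geometry,
        iopg_mean_mmhg=float(np.mean(record.iopg_readings_mmhg)),
        pdct_mean_mmhg=pdct_mean,
        flags=tuple(flags),
    )


def cohort_calibration(
    means: Iterable[SubjectMeans],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> CalibrationCornea:
    """Calibration cornea at the cohort's mean curvature and thickness."""
    means = list(means)
    if not means:
        raise InvalidInputError("cannot calibrate on an empty cohort")
    geometry = CorneaGeometry(
        radius_mm=float(np.mean([m.geometry.radius_mm for m in means])),
        thickness_mm=float(np.mean([m.geometry.thickness_mm for m in means])),
    )
    return CalibrationCornea.from_geometry(geometry, constants)


def estimate_subject(
    means: SubjectMeans,
    calib: CalibrationCornea,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    variant: IoptVariant = "consistency",
) -> SubjectEstimate:
    """Compute coefficients, corrected IOP, both moduli and both stiffnesses."""
    coeffs = ShellCoefficients.from_geometry(means.geometry, constants)
    iopt_calc = ioptcalc(means.iopg_mean_mmhg, coeffs, calib.coefficients, variant)
    e_goldmann = eiopg(
        means.iopg_mean_mmhg, coeffs, calib.coefficients, constants, variant
    )
    t_mm = means.geometry.thickness_mm
    e_both: ModulusEstimate | None = None
    k_both: StiffnessValue | None = None
    if means.pdct_mean_mmhg is not None:
        e_both = ecalc(
            TonometryPair(means.iopg_mean_mmhg, means.pdct_mean_mmhg), coeffs, constants
        )
        k_both = stiffness(t_mm, e_both.value)
    return SubjectEstimate(
        subject_id=means.subject_id,
        eye=means.eye,
        geometry=means.geometry,
        iopg_mean_mmhg=means.iopg_mean_mmhg,
        pdct_mean_mmhg=means.pdct_mean_mmhg,
        coefficients=coeffs,
        ioptcalc_mmhg=iopt_calc,
        ecalc=e_both,
        eiopg=e_goldmann,
        k_calc=k_both,
        k_iopg=stiffness(t_mm, e_goldmann.value),
        flags=means.flags,
    )


#: Column order and units of the per-subject results table.
_FRAME_COLUMNS = [
    ("subject_id", ""),
    ("eye", ""),
    ("ccc_mm", "mm"),
    ("cct_um", "um"),
    ("iopg_mmhg", "mmHg"),
    ("pdct_mmhg", "mmHg"),
    ("b_coeff", ""),
    ("c_coeff", ""),
    ("ioptcalc_mmhg", "mmHg"),
    ("ecalc_mpa", "MPa"),
    ("eiopg_mpa", "MPa"),
    ("k_calc_n_per_mm", "N/mm"),
    ("k_iopg_n_per_mm", "N/mm"),
    ("negative_flags", ""),
    ("flags", ""),
]


def estimates_frame(estimates: Sequence[SubjectEstimate]) -> pd.DataFrame:
    """Per-subject results as a DataFrame (one row per subject)."""
    rows = []
    for est in estimates:
        neg = []
        if est.ecalc is not None and est.ecalc.negative_flag:
            neg.append("ecalc")
        if est.eiopg.negative_flag:
            neg.append("eiopg")
        rows.append(
            {
                "subject_id": est.subject_id,
                "eye": est.eye,
                "ccc_mm": est.geometry.radius_mm,
                "cct_um": est.geometry.thickness_um,
                "iopg_mmhg": est.iopg_mean_mmhg,
                "pdct_mmhg": est.pdct_mean_mmhg,
                "b_coeff": est.coefficients.b_coeff,
                "c_coeff": est.coefficients.c_coeff,
                "ioptcalc_mmhg": est.ioptcalc_mmhg,
                "ecalc_mpa": None if est.ecalc is None else est.ecalc.value,
                "eiopg_mpa": est.eiopg.value,
                "k_calc_n_per_mm": None if est.k_calc is None else est.k_calc.value,
                "k_iopg_n_per_mm": est.k_iopg.value,
                "negative_flags": ";".join(neg),
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(rows, columns=[name for name, _ in _FRAME_COLUMNS])


#: Variables entering the cohort correlation matrix, in report order.
MATRIX_VARIABLES = [
    ("ccc_mm", "CCC (mm)"),
    ("iopg_mmhg", "IOPG (mmHg)"),
    ("pdct_mmhg", "PDCT (mmHg)"),
    ("ioptcalc_mmhg", "IOPTcalc (mmHg)"),
    ("cct_um", "CCT (um)"),
    ("ecalc_mpa", "Ecalc (MPa)"),
    ("eiopg_mpa", "Eiopg (MPa)"),
]


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level descriptive and inferential summary.

    ``descriptives`` holds mean/sd/n per variable; the correlation matrix
    uses pairwise-complete subjects; named regressions cover the
    modulus-vs-pressure and modulus-vs-thickness relations used downstream
    by the error decomposition.
    """

    n: int
    descriptives: pd.DataFrame
    correlations: CorrelationMatrix | None
    regressions: Mapping[str, RegressionFit]
    bland_altman_ecalc_eiopg: BlandAltmanResult | None
    diff_threshold_mmhg: float
    n_large_tonometry_difference: int
    n_negative_ecalc: int
    n_negative_eiopg: int
    mean_pdct_minus_ioptcalc_mmhg: float | None
    mean_k_iopg: float | None
    calibration: CalibrationCornea | None = None


def _describe(frame: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "ccc_mm",
        "cct_um",
        "iopg_mmhg",
        "pdct_mmhg",
        "ioptcalc_mmhg",
        "ecalc_mpa",
        "eiopg_mpa",
        "k_calc_n_per_mm",
        "k_iopg_n_per_mm",
    ]
    rows = []
    for col in cols:
        series = frame[col].dropna() if col in frame else pd.Series(dtype=float)
        rows.append(
            {
                "variable": col,
                "n": int(series.size),
                "mean": float(series.mean()) if series.size else math.nan,
                "sd": float(series.std(ddof=1)) if series.size > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def summarize_cohort(
    estimates: Sequence[SubjectEstimate],
    diff_threshold_mmhg: float = 4.0,
    calibration: CalibrationCornea | None = None,
) -> CohortSummary:
    """Descriptives, correlation matrix, regressions and agreement analysis.

    With fewer than 3 estimates only descriptives are produced. The
    correlation matrix drops subjects missing any matrix variable
    (pairwise-complete across the contour-tonometry gap is reduced to
    complete-case here; exclusion counts are logged).
    """
    frame = estimates_frame(estimates)
    n = len(frame)
    descriptives = _describe(frame)

    correlations = None
    regressions: dict[str, RegressionFit] = {}
    ba = None
    if n >= 3:
        complete = frame.dropna(subset=[key for key, _ in MATRIX_VARIABLES])
        dropped = n - len(complete)
        if dropped:
            logger.info("correlation matrix excludes %d incomplete subjects", dropped)
        if len(complete) >= 3:
            try:
                correlations = correlation_matrix(
                    {label: complete[key].to_numpy() for key, label in MATRIX_VARIABLES}
                )
            except InvalidInputError as exc:
                logger.warning("correlation matrix undefined: %s", exc)
            try:
                regressions["ecalc_on_iopg"] = ols_fit(
                    complete["iopg_mmhg"], complete["ecalc_mpa"]
                )
                regressions["eiopg_on_cct"] = ols_fit(
                    complete["cct_um"], complete["eiopg_mpa"]
                )
                regressions["goldmann_error_on_cct"] = ols_fit(
                    complete["cct_um"],
                    complete["iopg_mmhg"] - complete["pdct_mmhg"],
                )
                ba = bland_altman(complete["ecalc_mpa"], complete["eiopg_mpa"])
            except InvalidInputError as exc:
                logger.warning("cohort regressions undefined: %s", exc)

    with_pdct = frame.dropna(subset=["pdct_mmhg"])
    n_large = int(
        (np.abs(with_pdct["iopg_mmhg"] - with_pdct["pdct_mmhg"]) >= diff_threshold_mmhg).sum()
    )
    mean_gap = (
        float((with_pdct["pdct_mmhg"] - with_pdct["ioptcalc_mmhg"]).mean())
        if len(with_pdct)
        else None
    )
    return CohortSummary(
        n=n,
        descriptives=descriptives,
        correlations=correlations,
        regressions=regressions,
        bland_altman_ecalc_eiopg=ba,
        diff_threshold_mmhg=diff_threshold_mmhg,
        n_large_tonometry_difference=n_large,
        n_negative_ecalc=int(frame["negative_flags"].str.contains("ecalc").sum()),
        n_negative_eiopg=int(frame["negative_flags"].str.contains("eiopg").sum()),
        mean_pdct_minus_ioptcalc_mmhg=mean_gap,
        mean_k_iopg=(
            float(frame["k_iopg_n_per_mm"].mean()) if n else None
        ),
        calibration=calibration,
    )


def format_summary(summary: CohortSummary) -> str:
    """Plain-text cohort report."""
    lines = [f"subjects analysed: n = {summary.n}", "", "descriptives (mean, sd):"]
    lines.append(summary.descriptives.to_string(float_format=lambda v: f"{v:.4f}"))
    if summary.calibration is not None:
        g = summary.calibration.geometry
        lines.append(
            f"\ncalibration cornea: R = {g.radius_mm:.4f} mm, t = {g.thickness_um:.1f} um"
        )
    if summary.correlations is not None:
        lines.append("\nPearson r:")
        lines.append(summary.correlations.r_frame().to_string(float_format=lambda v: f"{v:+.3f}"))
        lines.append("\nsignificance (* p<0.05, ** p<0.001):")
        lines.append(summary.correlations.star_frame().to_string())
    for name, fit in summary.regressions.items():
        lines.append(
            f"\nregression {name}: slope = {fit.slope:.6g}, intercept = "
            f"{fit.intercept:.6g}, r = {fit.r:.3f}, p = {fit.p_slope:.3g}, n = {fit.n}"
        )
    ba = summary.bland_altman_ecalc_eiopg
    if ba is not None:
        lines.append(
            f"\nBland-Altman Ecalc vs Eiopg: bias = {ba.bias:.4f} MPa, "
            f"LoA = [{ba.loa_low:.4f}, {ba.loa_high:.4f}], proportional slope = "
            f"{ba.proportional_slope:.4f} (p = {ba.proportional_p:.3g})"
        )
    lines.append(
        f"\nsubjects with |IOPG - PDCT| >= {summary.diff_threshold_mmhg:g} mmHg: "
        f"{summary.n_large_tonometry_difference}"
    )
    if summary.mean_pdct_minus_ioptcalc_mmhg is not None:
        lines.append(
            f"mean PDCT - IOPTcalc: {summary.mean_pdct_minus_ioptcalc_mmhg:.2f} mmHg"
        )
    lines.append(
        f"negative modulus estimates: ecalc {summary.n_negative_ecalc}, "
        f"eiopg {summary.n_negative_eiopg}"
    )
    return "\n".join(lines) + "\n"


def write_results(
    estimates: Sequence[SubjectEstimate],
    summary: CohortSummary,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the per-subject CSV and the plain-text summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = estimates_frame(estimates)
    subjects_path = out / "subjects.csv"
    frame.to_csv(subjects_path, index=False)
    summary_path = out / "summary.txt"
    summary_path.write_text(format_summary(summary))
    return {"subjects": subjects_path, "summary": summary_path}


def run_cohort(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    eye: Eye = "left",
    quality_max: int = 3,
    calibration: CalibrationCornea | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    variant: IoptVariant = "consistency",
    diff_threshold_mmhg: float = 4.0,
    sheet: int | str = 0,
) -> tuple[list[SubjectEstimate], CohortSummary]:
    """Full pipeline: load → select eye → average → calibrate → estimate.

    When ``calibration`` is None it is recomputed from the selected cohort's
    mean curvature and thickness, which is the defining convention of the
    Goldmann-only estimator.
    """
    records = load_cohort(path, mapping=mapping, sheet=sheet)
    records = [r for r in records if r.eye == eye]
    means = [prepare_subject(r, quality_max=quality_max) for r in records]
    calib = calibration or cohort_calibration(means, constants)
    estimates = [estimate_subject(m, calib, constants, variant) for m in means]
    summary = summarize_cohort(
        estimates, diff_threshold_mmhg=diff_threshold_mmhg, calibration=calib
    )
    return estimates, summary
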