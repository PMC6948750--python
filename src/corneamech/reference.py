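"""Published reference moments for the young-adult normal cohort.

These are the cohort summary statistics of the 100-eye study the method was
developed on (left eyes, subjects aged 17-30). They seed the synthetic-cohort
generator defaults and the default calibration cornea when no cohort file is
supplied. Pressures in mmHg, curvature in mm, thickness in μm, moduli in MPa,
stiffness in N/mm.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortMoments:
    """Mean ± SD summary of the reference cohort's measured variables."""

    n: int = 100
    ccc_mean_mm: float = 7.75
    ccc_sd_mm: float = 0.26
    cct_mean_um: float = 549.9
    cct_sd_um: float = 32.8
    pdct_mean_mmhg: float = 16.89
    pdct_sd_mmhg: float = 2.49
    iopg_mean_mmhg: float = 15.06
    iopg_sd_mmhg: float = 2.71
    # derived-variable summaries reported for the same cohort
    ecalc_mean_mpa: float = 0.25
    ecalc_sd_mpa: float = 0.10
    eiopg_mean_mpa: float = 0.29
    eiopg_sd_mpa: float = 0.06
    stiffness_mean_n_per_mm: float = 0.16
    stiffness_sd_n_per_mm: float = 0.03
    corr_cct_ccc: float = 0.230


REFERENCE_COHORT = CohortMoments()

#: Keratometric index constant: anterior radius r (mm) = 337.5 / K (dioptres).
KERATOMETRIC_CONSTANT = 337.5


def radius_from_dioptres(k_dioptres: float) -> float:
    """Convert a keratometry reading in dioptres to anterior radius in mm."""
    if k_dioptres <= 0:
        raise ValueError(f"keratometry must be positive, got {k_dioptres}")
    return KERATOMETRIC_CONSTANT / k_dioptres
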