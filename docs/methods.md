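# Methods

## Model and assumptions

The cornea is idealised as a thin, spherical, isotropic, linear-elastic
shell of uniform thickness, loaded by the intraocular pressure and
applanated by the Goldmann tonometer over a fixed area. Under these
assumptions the Goldmann reading of a cornea with anterior radius R (mm),
central thickness t (mm) and Young's modulus E (MPa) at true pressure IOPT
(mmHg) satisfies

    B·IOPG = 7500·E + C·IOPT

with the dimensionless shell coefficients

    B = 0.6 π R (R − t/2) √(1 − ν²) / t²
    C = 2 π R (R − t/2) / ((1 − ν) A t)

Real corneal tissue is anisotropic, viscoelastic and hyperelastic; the
linear-elastic idealisation is justified by the small applanation load
(~1.5 gf) and small indentation (~150 μm), and all outputs should be read
as effective small-strain moduli under Goldmann-type loading, not intrinsic
material constants.

Solving for E with a measured true pressure (contour tonometry) gives the
dual-tonometer estimator `ecalc`. The Goldmann-only estimator `eiopg`
replaces the measured true pressure by `ioptcalc`, derived from the
assumption that a cornea with the cohort-average (R, t) — the calibration
cornea — reads true pressure on the Goldmann tonometer. That assumption is
population-specific: `eiopg` is meaningful for corneas drawn from the same
kind of normal cohort the calibration was computed on, while `ecalc`
remains valid for atypical corneas (oedema, post-surgical) provided the
contour reading is trusted.

Structural stiffness is k = t·E (N/mm): the thickness–modulus product that
applanation actually probes, which is why it correlates with the Goldmann
reading more strongly than either factor alone.

## Resolved ambiguities

Two algebraic choices were genuinely open and are resolved explicitly,
with the rejected readings kept available for inspection:

* **Coefficient parses.** The source equations for B and C lost their
  fraction/radical structure in typesetting. All candidate readings are
  implemented behind `parse` keywords; `validate_parses()` evaluates each
  combination at the reference cohort's mean inputs and accepts only
  combinations whose two modulus estimates land within ±0.04 MPa of the
  published cohort means (0.25 / 0.29 MPa). Only the default shown above
  survives: the alternate C readings give C ≈ 44–46 and moduli above
  0.5 MPa; the alternate B readings (no square root; squared gap) give
  0.15–0.21 MPa.
* **Correction-formula subscripts.** The typeset correction
  IOPG·(Bc − Cc + C)/B *rises* with thickness, contradicting both the
  physics (Goldmann over-reads thick corneas) and the reported negative
  correlation between the corrected pressure and CCT (r = −0.413). The
  default is therefore the subscript-swapped `consistency` variant
  IOPG·(B − C + Cc)/Bc, which falls with thickness; the `printed` variant
  stays available behind a flag. Both satisfy the calibration identity
  exactly. The choice does not affect `ecalc`.

The calibration cornea defaults to the analysed cohort's own mean (R, t),
recomputed per run; a fixed (R, t) override is accepted for reproducing
published calibrations. Negative modulus results (possible when
C·IOPT > B·IOPG) are flagged and retained, never clamped.

## Error decomposition

Curves are predicted-reading differences from the calibration point
(positive = over-reading), over a default 450–650 μm grid in 5 μm steps —
a 200 μm range centred near the reference mean CCT (the exact endpoints of
the published figure are not printed; they are exposed as flags).

* *Effect of CCT*: thickness sweeps the grid at fixed modulus (anchored at
  the calibration-cornea Goldmann-only estimate, 0.2775 MPa) and fixed
  true pressure (the cohort-mean contour reading, 16.89 mmHg). Under the
  default parse this curve **increases** with thickness, spanning
  8.35 mmHg over the grid (published estimate: 8.9 mmHg).
* *Effect of E*: geometry stays at the calibration cornea; the modulus
  follows a CCT→E mapping, by default the cohort-fitted OLS line of the
  Goldmann-only modulus on CCT. With the negative slope seen in normal
  cohorts this curve decreases, partially cancelling the thickness effect.
* *Net*: pointwise sum of the components, or (in `empirical` mode) a
  cohort-fitted regression of the tonometer difference on CCT centred at
  the calibration thickness. Both constructions are provided because the
  published description of the net curve is ambiguous about which
  regression is evaluated where.

## Statistics

Parametric, two-tailed, α = 0.05 throughout; correlations are additionally
starred at p < 0.001 (strict inequalities); sample (n−1) moment
denominators; no multiple-testing correction (raw p-values are reported, as
in the clinical report this mirrors). Pearson p-values use the t-transform
t = r·√((n−2)/(1−r²)) with n−2 df. Proportional bias in the Bland–Altman
analysis is tested as the OLS slope of the paired differences on the
pairwise means (the phenomenon is named, not the test, in the source; the
slope test is the standard choice). scipy.stats provides the computations;
the test suite checks them against independent brute-force moment
arithmetic to 1e−9 on a thousand random fixtures.

## Synthetic cohorts

The generator draws latent per-subject states: (R, t) from a bivariate
normal (means 7.75 mm / 549.9 μm, SDs 0.26 mm / 32.8 μm, correlation 0.23,
truncated to 0 < t < R), true pressure ~ N(16.89, 2.49²) mmHg and true
modulus ~ N(0.29, 0.06²) MPa, both truncated positive. Instruments then
observe: keratometry ×2, pachymetry ×3, contour tonometry ×3 (unbiased for
true pressure, with quality grades drawn 0.38/0.38/0.19/0.03/0.02 over
grades 1–5 to exercise the ≤3 quality filter) and Goldmann ×3 centred on
the shell model's predicted reading. Per-reading noise SDs default to 25%
of each between-subject SD — a declared assumption, since instrument and
biological variance are not separable from a single cohort's summary
table; all are overridable.

What this emulates: the moment structure and the forward physics of a
young-normal cohort, so every pipeline stage and the parameter-recovery
study run end-to-end. What it does not: tonometer calibration offsets,
surface-tension effects, diurnal pressure variation, observer effects, and
any true-modulus–thickness correlation (latent E is drawn independent of
geometry). Passing recovery tests therefore demonstrates the pipeline
inverts its own forward model — not that the shell model is an accurate
constitutive description of real corneas.

At zero noise the pipeline recovers each subject's latent modulus to
round-off (≤ 1e−10 relative). The recovery study uses 50 replicates of
n = 100 at default noise — sizes chosen to put Monte-Carlo error well below
the effects tested; pooled bias is required to sit within 3 standard errors
of zero or below 0.001 MPa (≈0.4% of the modulus scale), the declared
floor covering the estimator's small linearisation (Jensen) bias from
noise entering nonlinearly through 1/t².

## Numerical choices

Closed-form operations are validated to 1e−12 relative against a symbolic
(sympy) oracle; geometry outside R ∈ [6.5, 9.5] mm or t ∈ [0.35, 0.75] mm
triggers a warning, not rejection; non-positive readings are rejected at
parse with the row logged and skipped; zero pressures are tolerated in the
algebra so the linear identities hold at the origin. The generator redraws
truncation-violating samples and raises after a bounded number of
attempts. Seeds fix all randomness; identical inputs give byte-identical
outputs.

## Known limitations

* `eiopg` inherits the calibration-cornea assumption and should not be
  applied to corneas far from the calibration population.
* The modulus-effect curve needs a cohort-fitted modulus-vs-CCT mapping;
  with synthetic cohorts (independent latent E) its fitted slope mostly
  reflects estimation-error correlation, not biology.
* The model is static and linear-elastic; it cannot represent hysteresis
  or strain-stiffening, and the 7500 unit divisor ties the modulus scale
  to the specific applanation geometry assumed.
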