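# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the limitations of `hipshape`.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Procrustes alignment

Shapes are 82 ordered 2-D landmarks in millimetres, y-up.  Alignment is
*full* Procrustes: each configuration is centred, scaled to unit centroid
size (the square root of summed squared distances to the centroid), and
rotated to the running consensus.  GPA iterates rotation and consensus
re-estimation; the consensus is re-normalised to unit centroid size each
iteration to fix the scale gauge, and is initialised to the first shape,
which fixes the rotation gauge.  Convergence is declared when the RMS change
between successive *estimated* consensus shapes falls below `tol`
(default 1e-8); the change from the arbitrary first-shape initialisation to
the first estimate is not counted.  Non-convergence within `max_iter`
(default 100) returns `converged=False` with a warning, never silently.

The rotation subproblem is solved in closed form from the SVD of the 2×2
cross-covariance, with the determinant constrained to +1: the alignment
never reflects.  Chirality is handled exclusively by `mirror_left`, which
flips `x → −x` on left hips *before* GPA so both sides pool into one
per-sex model.  A vanishing cross-covariance returns the identity with a
warning.

No tangent-space projection is applied before PCA; at the dispersions of
interest (per-landmark residuals well below a tenth of centroid size) the
variance figures differ negligibly, and PCA on aligned coordinates keeps
the reconstruction identities exact.  This choice is recorded here and in
the module docstrings.

## Shape model

PCA is computed by SVD of the aligned rows centred on their mean.  The rank
is capped at `min(n − 1, 160)`: centering removes one degree of freedom and
the four similarity constraints (two translations, rotation, scale) remove
four of the 164 coordinates.  Eigenvector signs are fixed by making each
mode's largest-magnitude loading positive, so mode orientation is
reproducible; the anatomical direction of a mode is otherwise arbitrary.

Scores are standardized in-sample (n−1 denominator) so the unit of every
downstream effect is one SD of mode score.  Modes with an *unrounded*
variance fraction ≥ the threshold (default 1%) are retained.  The variance
table prints one-decimal percentages; the cumulative column is computed on
unrounded fractions and rounded last, so it is internally consistent even
when the rounded per-mode column sums a tenth away — reporting conventions
that round each column independently can disagree with themselves, and this
package prefers internal consistency.

## Clinical rules

* Hip status: *symptomatic* = self-reported hip/groin pain for over six
  months AND a positive FADIR provocation test; a non-symptomatic hip of a
  participant with a symptomatic hip is *other*; else *asymptomatic*.  The
  "other" level is kept distinct from "asymptomatic" in adjustment because
  the two hips of a participant are correlated.
* KL exclusion is per hip: a hip with Kellgren–Lawrence grade > 0 is
  removed, its contralateral hip may remain.
* Cartilage defect = any of the ten SHOMRI cartilage subregions graded ≥ 1
  (partial- or full-thickness loss).  Labral tear = any of the four labral
  subregions graded ≥ 2; grade 1 (signal change/fraying) does not count.
  Both rules are verified against brute-force enumeration of the full
  3^10 and 6^4 grade lattices in the test suite.
* Cohort summaries use linear-interpolation (type-7) quantiles and
  one-decimal percentages with hips as the denominator for hip-level rows.

## Association model

One GEE logistic model per (mode, outcome) pair, crude and adjusted
(age, BMI, two status dummies).  Estimation follows Liang–Zeger: Fisher
scoring on the estimating equations with working covariance
`V_i = A_i^{1/2} R(α) A_i^{1/2}`, initialised at the independence IRLS fit
(tolerance 1e-10 on coefficient change).  The exchangeable `α` is
re-estimated each iteration by the moment estimator from within-cluster
cross-products of standardized Pearson residuals, divided by the Pearson
dispersion, with denominator `Σ n_i(n_i−1)/2 − p`; it is clipped to
(−0.99, 0.99) with a warning.  The robust covariance is the sandwich
`B⁻¹MB⁻¹`; the model-based covariance is `φ·B⁻¹`.  With independence
working correlation or all-singleton clusters the estimating equations
coincide with the score equations, so coefficients equal the ML fit and the
sandwich reduces to the heteroskedasticity-robust form — both identities
are asserted to 1e-8 in the tests, and the whole estimator is cross-checked
against statsmodels' GEE on shared data.

Inference is Wald with z = 1.96 for 95% intervals, matching the
OR (95% CI) reporting convention; no score or likelihood-ratio option is
provided.  No small-sample sandwich correction is applied by default — at
the target scale (~180 clusters) the plain sandwich is adequately
calibrated, which the acceptance suite verifies empirically (CI coverage
93–97% and type-I error 3–7% under paired-hip clustering).  Missing
covariates are handled complete-case per model with a warning carrying the
dropped count.  Separation and rank deficiency raise typed errors; the scan
catches them per row and flags the row failed rather than aborting.

`or_at_k_sd` converts a per-SD OR to the odds ratio of a hip k SDs from the
mean: `OR^k`, reported to two decimals.  `bonferroni_alpha` is
`0.05/n_modes` to four decimals.

`minimal_detectable_or` is simulation-based by design: power-formula
implementations for GEE logistic models vary enough across software that a
direct Monte-Carlo definition (empirical Wald rejection rate over simulated
cohorts with common random numbers, bisected over the log-OR) is both
simpler and self-consistent with the estimator it describes.  Its intercept
is the logit of the target prevalence; the participant random intercept
slightly attenuates the realised marginal effect, which is acceptable at
the default `σ_u = 0.5` (attenuation ≈ 4% on the log scale).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not radiographic
appearance.

**Template.**  A fixed parametric 82-point contour per sex: a 30-point
femoral-head arc (radius 25 mm men, 22 mm women; 200° → −20°), a 7-point
head-neck-junction blending arc (radius 10 mm), 15 lateral-neck /
greater-trochanter and 8 medial-neck points on cubic Béziers, and a
22-point acetabular-rim arc (radius 28 mm, concentric with the head,
30° → 150°), centred at the origin.  Within each segment consecutive
points are ≤ 6 mm apart.  The geometry is a convention, fixed so that all
tests share deterministic fixtures; real anatomy enters only through the
statistical structure layered on top.

**Deformation basis.**  Smoothed standard-normal draws (centered moving
average, width 7, per coordinate channel) orthogonalised against the four
similarity directions at the template and against each other.  Because the
basis is similarity-orthogonal, true shape variation is not absorbed by
Procrustes alignment — asserted to 1e-10/1e-8 in the tests.  A degenerate
draw (Gram–Schmidt residual < 1e-8) raises rather than silently redrawing.

**Spectrum.**  `λ_j = c·j^−γ` with γ = 1.2 and c fixed so mode-1 RMS
landmark displacement is 2 mm (`c = 4·82 mm²`).  This mimics the decaying
variance profile seen in radiographic hip SSMs, where the leading mode
explains ~25% and the 15th ~1% of variance.

**Cohort defaults** (the study conditions; chosen once):
229 participants, 77.7% male; age ~ Normal(26, 4²) truncated to 18–50 y;
BMI ~ Normal(24.5, 2.5²) kg/m²; hip-level symptomatic-status marginals
(0.629, 0.157, 0.214) produced exactly by drawing participant status first
and, within symptomatic participants, both hips symptomatic with
probability 2q−1 (q = 0.8); KL > 0 with probability 0.041 per hip;
landmark noise 0.5 mm per coordinate; nuisance transforms up to ±10°,
scale 0.9–1.1, translation ±20 mm.  Left hips are mirrored from the
right-hip convention before the nuisance transform.  Outcomes follow a
logistic model with per-SD log-ORs log 0.75, log 1.34 and log 0.61 on true
modes 1, 12, 15 (cartilage) and log 1.30 on mode 12 (labral), modest
covariate effects (0.03/y age, 0.04 per kg/m² BMI, 0.6/0.2 status dummies,
centred at age 26 and BMI 24.5), and a participant-level random intercept
σ_u = 0.5 shared by both hips.  Baseline logits (−0.33 cartilage, 0.46
labral) put marginal prevalences near 52% and 70%.

**SHOMRI grades** are generated backwards from the binary outcomes so they
round-trip exactly through the dichotomization rules: a cartilage-positive
hip gets `1 + Binomial(3, 0.3)` subregions at grade 1–2; a labral-positive
hip gets `1 + Binomial(3, 0.25)` subregions at grade 2–5 with the rest at
0–1; negative hips are all-zero (cartilage) or 0–1 (labral).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: radiographic projection and positioning
effects (pelvic tilt/rotation), annotation error that is correlated along
the contour, anatomical asymmetry between a person's hips beyond
independent mode scores, non-logistic outcome mechanisms, reader
variability in SHOMRI scoring, and any 3-D structure.  Tests on synthetic
cohorts validate the *machinery* (alignment, decomposition, estimation,
calibration), not anatomical claims.

## Problem sizes in the test suite

Simulation tests use cohort sizes of 40–300 participants and replicate
counts of 200–2000, chosen to give stable Monte-Carlo margins (3-SE bands,
binomial tolerances) for each property: CI coverage uses 500 replicates of
150-participant paired cohorts; type-I error uses 2000; the detectable-OR
checks use 120–300 replicates.  All randomness is seeded; hypothesis runs
derandomised.

## Known limitations

* 2-D contours only; no image I/O and no automatic landmark detection —
  landmarks arrive as `.pts` files from upstream annotation.
* The GEE implementation supports exchangeable and independence working
  structures only, sized for small clusters (pairs in practice; arbitrary
  sizes are accepted).
* No mixed-effects (conditional) alternative and no multiple imputation;
  adjustment is complete-case per model.
* The 1% mode-retention rule is a convention, not an inferential criterion;
  with small strata the retained-mode count is sample dependent.
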