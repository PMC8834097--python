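# Methods

This note documents the statistical procedures implemented in `cytosig`,
the assumptions they rest on, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Preprocessing

**Z-scoring.** Each analyte column is centered and scaled to unit *sample*
SD (divisor n − 1, the default of the usual statistical environments).
Scaling is always computed within the dataset being analyzed; when a model
is projected onto a second dataset, that dataset is z-scored with its own
means and SDs (`project(..., scaling="self")`).  The rationale is that
absolute concentration scales are not comparable across species,
compartments, or assay kits, while within-cohort relative variation is.
`scaling="training"` is available when the two datasets genuinely share a
scale.  A constant column cannot be scaled and is reported as an error
naming the analyte, rather than silently dropped.

**Missing values.** Multiplexed immunoassays censor out-of-range readings.
Three policies are provided: `half_min` (default; missing → half the
column's minimum observed value, the common below-detection-limit
convention), `column_min`, and `drop_sample`.  Imputation happens before
scaling, so the stored scaling parameters reflect the completed matrix.
An all-missing column is an error.

**Outlier screen.** Samples are screened iteratively: z-score, PCA (plain
SVD of the z-matrix), squared Mahalanobis distance of each sample in the
first `n_components` PC scores (scores divided by their eigenvalues),
compared against the chi-square quantile at `confidence` with
df = `n_components`.  The single worst offender above the cutoff is removed
(ties broken by the smaller row index), everything is refit, and the loop
stops when no sample exceeds the cutoff.  Defaults: `confidence = 0.995`
(a 99.5% ellipse) and `n_components = 2` — an ellipse is a 2-D object, so
two components are the most literal reading; the count is configurable
because more components are defensible.  One-at-a-time removal with a full
refit is deliberate: removing a gross outlier changes the PCs, and batch
removal against stale axes over-rejects.  Because the cutoff is applied to
re-estimated eigenvalues each round, the null removal fraction is slightly
above the nominal tail mass (measured ≈ 0.7–0.9% pooled over 20 null
cohorts of n = 1000, p = 10, against a nominal 0.5%); individual cohorts
can reach ~2.5%.  The screen assumes roughly elliptical bulk data; on
strongly skewed raw concentrations it flags heavy-tail samples more often,
which is the expected behavior of a Mahalanobis rule, not a defect.

## PLS core

A 2-component single-response PLS is fit by NIPALS (deterministic for one
response column; no random initialization exists to seed).  The response is
either a ±1 group encoding — case label +1, the other group −1; exactly two
distinct labels are required — or a continuous clinical score, centered
internally.  Weight vectors are orthonormal across components and raw score
columns are mutually orthogonal; both properties are asserted by tests.

**Rotation.** The two raw latent variables are post-multiplied by an
orthogonal 2 × 2 rotation chosen so that all group separation (discriminant
case: the squared difference of group mean scores) or all response
covariance (regression case) lies on LV1, with the case group — or better
clinical score — positive.  Both criteria have a closed-form optimum: the
optimal LV1 axis is the direction of the 2-D group-mean-difference vector
(resp. the score–response covariance vector), so no grid search is needed.
Applying the same rotation to scores and weights leaves the reconstruction
T·Wᵀ unchanged, which is the invariant the tests check.  Two-component
models are used everywhere because the study design reads LV1/LV2 planes;
a panel reduced to a single analyte yields a 1-component model whose only
"rotation" is the case-positive sign flip.

**Projection.** New samples are scored as Z·R where R is the rotated
x-rotation matrix W(PᵀW)⁻¹; this reproduces training scores exactly on the
training panel, which pins down the convention among the several "project
with the weights" variants in the PLS literature.

## Leave-K-out loading stability (LKOCV)

Each of `n_iterations` (default 100) replicates removes a uniformly random
K-subset of samples (drawn without replacement within the replicate;
independent across replicates, since 100 disjoint draws are impossible at
these cohort sizes), reruns the full z-score → fit → rotate pipeline, and
sign-aligns the replicate LV1 weights to the full-model reference by dot
product — PLS weights are sign-indeterminate across refits, and without
alignment the mean loading of a stable analyte would be biased toward 0.
For discriminant targets a draw that would leave any group with fewer than
two samples is redrawn and counted (`n_redraws` on the profile); this guard
stands in for explicit stratification and never triggers at the study's
cohort sizes with the study's K values (K = 5 human case-control, K = 3
human score regressions, K = 1 mouse).  The profile reports per-analyte
mean, SD (ddof = 1), and CV = SD/|mean| (∞ at mean 0).  K = 0 reproduces
the full model exactly with SD pinned to exactly zero.  Profiles are fully
reproducible from the seed.

## Univariate screens

**Dunn's test** on joint midranks with the tie-corrected variance

    z = (R̄_a − R̄_b) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_a + 1/n_b)]

two-sided normal p, Bonferroni over the pairwise comparisons *within one
analyte* (m = 3 for control/typical/mild) — the per-analyte annotation
style of the study figures; correcting across analytes instead is left to
the caller since the family choice is a judgment call.  No Kruskal–Wallis
gate precedes Dunn's test.

**Wilcoxon rank-sum**, two-sided.  For untied data with pooled size ≤ 50
the exact permutation p is computed from the rank-sum distribution (a
dynamic program over subset sums — equivalent to full enumeration and
verified against it); otherwise the normal approximation with midranks, tie
correction and continuity correction is used.  The 50 cutoff is the
conventional exact/asymptotic switch point.  This matters for calibration:
at n = 8 vs 8 the exact test rejects at 0.0499 at nominal α = 0.05, while
the continuity-corrected normal approximation under-rejects at 0.0379, so
using the approximation in the exact-feasible regime would make the test
conservative.

The per-analyte screen applies Dunn (≥ 3 groups) or Wilcoxon (2 groups),
drops missing cells analyte-wise, and flags per-analyte failures in an
`error` column instead of aborting the table.

## Coincident signatures and transfer

Given two case-positive stability profiles restricted to their shared
analytes, an analyte joins the signature iff |mean LV1 loading| ≥ 0.2 in
both, CV < 1 in both, and the loading signs agree.  The magnitude reading
of the ≥ 0.2 rule (rather than signed) plus the explicit direction match is
deliberate: a signed threshold alone would silently discard analytes that
are consistently *down* in cases, while direction agreement is what makes a
cross-dataset signature meaningful.  `require_direction_match=False`
exposes the signed-agnostic variant.  Selection is symmetric in the two
profiles and monotone in both thresholds (property-tested).

Transfer projects a model fit on dataset A onto dataset B (name map →
internal z-scoring → projection) and reports the AUC of case vs control
separation along LV1 (the Mann–Whitney statistic normalized by
n_case·n_ctrl) together with a rank-sum p value.  AUC was chosen as the
separation metric because it is scale-free and invariant to any positive
rescaling of B's raw columns, matching the z-scoring convention.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Log-normal concentrations**: analyte a has baseline log10 level
  μ_a ~ U(0.5, 2.5) (≈ 3–316 pg/mL) and within-cohort log10 SD
  σ_a ~ U(0.1, 0.3) (≈ 26–100% geometric CV).  The SD range matters: at
  much larger σ the raw-concentration z-scoring that the pipeline applies
  is dominated by log-normal skew and planted effects lose calibration, so
  the default stays in the range typical of real plasma panels.
* **One latent inflammation factor** f per sample (standard normal,
  shifted by `case_shift` = 1.0 in typical cases), loading on every analyte
  with λ_a ~ U(0.2, 0.7).  This produces the positive co-regulation that
  makes a rank-one LV1 profile meaningful, and ties clinical scores to
  disease.
* **Planted case effects**: a chosen subset of analytes (8 of 41 by
  default) is shifted by δ = 1.5 log10 units (≈ 30-fold) in cases — strong,
  unambiguous markers, as expected of a genuine inflammatory signature.
* **Mild cases** (3 of 18 by default) receive both shifts attenuated by
  0.25, so they cluster with controls on LV1.
* **Clinical scores**: five 0–10 motor-function scores (higher = better)
  via round(clamp(10 − (2.5f + noise·η))), and a muscle-tone grade on the
  ordered scale {0, 1, 1.5, 2, 3, 4} (1.5 encodes the "1+" grade, keeping
  the scale numeric and ordered) as a monotone bucketing of f.  Rounding
  and clamping create ties, so rank correlations with f approach but cannot
  equal ±1 even at zero noise; tests assert perfect monotone concordance
  instead.
* **Paired cohorts** share a planted sub-signature with common analyte
  names (26 names shared between the 41-analyte human-like and 32-analyte
  mouse-like presets).  In `disjoint` mode the planted sets are disjoint
  *and* the latent factor carries no group shift — without the latter the
  co-regulated case elevation alone would transfer and the mode would not
  be a null.

Ground truth (planted analytes, directions, per-sample severity, config)
accompanies every panel.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: assay-level artifacts (plate effects, bead
counts, standard-curve nonlinearity), heavier-than-log-normal tails,
multiple correlated inflammation programs (a single factor is rank one by
construction), analyte-specific detection limits, and any relationship
between age/sex and cytokines (age and sex are bookkeeping columns).  A
severity *regression* on these cohorts ranks latent-factor-tracking
analytes highly by construction — constant group-shifted analytes carry no
within-group severity information — so planted-marker recovery claims are
made for the discriminant analysis, not the score regressions.

## Numerical and reproducibility choices

* NIPALS aborts with "no predictive direction" when ‖Xᵀy‖ < 1e-12.
* Rotation requires a nonzero separation direction (‖d‖ ≥ 1e-12).
* Outlier ties break toward the smaller row index; removal order is
  recorded.
* All resampling uses `numpy.random.default_rng`; every stochastic stage
  takes an explicit seed, and the pipeline derives per-stage seeds from a
  single run seed, making reruns bit-identical (stage outputs are hashed
  into the run summary).
* Model files are JSON with a schema version; deserialization errors name
  the missing field.

## Problem sizes used in the validation suite

Simulation-backed checks run at the study's own scale — cohorts of 18 + 18
(human-like) and 4–6 per group (mouse-like), 100 LKOCV refits — with 20
generator seeds per claim and 10,000 replicates for test-calibration rates;
these sizes give binomial error small enough for the asserted bounds while
keeping the suite quick.

## Known limitations

* Two-class discriminant encoding only; the three-group human design is
  handled as case vs control multivariately plus three-group univariate
  follow-up, mirroring the study, not as a multi-class PLS-DA.
* The rotation criterion formalizes "consistent separation along LV1" as
  variance/covariance alignment; other formalizations (e.g. varimax on
  loadings) would give different LV2 orientations, though identical
  subspaces.
* The exact analyte lists of the commercial 41- and 32-plex kits are not
  public here; the shipped human↔mouse name map covers commonly shared
  analytes (including the GRO↔KC class pairing) and users supply full maps.
* No batch correction or robust-covariance (MCD) outlier variant.
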