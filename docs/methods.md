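# Methods

This note documents the statistical models, the synthetic-cohort
generator, the numerical choices, and the limitations of the package. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Association models

### Differential methylation

Betas are regressed directly (not M-values), so the diagnosis coefficient
is the adjusted beta-scale difference Δβ that association tables report
and that the simulator's truth ledger stores. The design is

    intercept + diagnosis + age + sex + batch (one-hot, first level
    dropped) + 5 cell proportions

with neutrophils — the most abundant type — dropped from the six
proportions because they sum to one and would alias the intercept.
Constant covariate columns are dropped with a warning (this is what makes
the female-only X-chromosome scan, where sex is constant, well posed);
a constant diagnosis indicator is an error. Rank deficiency is detected
by incremental rank and reported with the aliased column names. Inference
is a two-sided t-test on the OLS coefficient; there is no empirical-Bayes
moderation — with 255 shared controls the residual-variance estimates are
already stable, and plain linear models keep the effect estimate equal to
the adjusted group difference.

The scan is vectorized: one shared design across probes, a single
`(X'X)^{-1}X'` solve, per-probe residual variances. Unit tests pin the
engine to explicit normal-equations and statsmodels-OLS oracles at 1e-8.
Zero-variance probes (possible after clipping at array saturation) are
skipped, never called, and counted in the scan report.

### Differential variability

Variability is tested on the residuals of the covariate-only model
(diagnosis excluded), which removes mean differences before comparing
spreads, using the Brown–Forsythe statistic: absolute deviations from the
*group median*, then a one-way ANOVA F with (k−1, N−k) degrees of
freedom. The median-centered variant is the robust default; the
mean-centered classical form is a one-line change in `levene_bf` if ever
needed. Degenerate probes (every observation equal to its group median)
are skipped; equal constant deviations return W = 0, p = 1; zero
within-group deviation with unequal group spread returns W = ∞, p = 0.

### Replication rule

A discovery call is *testable* when its probe exists (and was scanned) on
the replication platform; it *replicates* when the replication effect has
the same sign and P < 0.05. Summary percentages are reported as
replicated/testable × 100 rounded to an integer, matching how such tables
are printed. The same direction-consistency requirement is applied to
meQTL replication (at P < 0.001) and to treatment-specific calls.

### Multiple testing

Genome-wide calls use Bonferroni α/m with m = tests actually run, kept at
full precision internally and rounded to two significant digits only for
display ("6.4 x 10^-08"). meQTL significance uses Benjamini–Hochberg FDR
applied jointly across all tested cis pairs (the Matrix-eQTL convention),
not per probe. The BH implementation is the statsmodels step-up; tests
compare it against a hand-written step-up oracle.

## Cell deconvolution

Per sample, proportions solve min‖β_s − R·w‖² s.t. w ≥ 0, Σw = 1. Because
the optimum of this convex QP lies on a face of the simplex, the solver
enumerates supports (≤ 2⁶−1 = 63 for six cell types), solves each face's
equality-constrained normal equations through its KKT system, and keeps
the feasible candidate with the smallest objective — exact, deterministic,
and independent of starting points. Above 12 cell types it falls back to
SLSQP. The equality-constrained solve (rather than unconstrained solve +
truncation + renormalization) yields proportions that are valid
regression covariates without post-hoc rescaling; the truncate-and-
renormalize variant remains available as `method="truncate"` for
comparison. The reference matrix is rejected if its smallest singular
value is below 1e-8 of the largest, with advice to supply more
discriminating probes.

## Genetic integration

*cis* pairs are SNP–CpG pairs on the same chromosome within 1 Mb,
**boundary inclusive** ("within" is read as ≤; the convention is
configurable via `window`). The meQTL model adds the dosage to the EWAS
covariates plus disease status and the first genetic principal component
(SVD of standardized, mean-imputed dosages; sign fixed by the first
polymorphic variant's loading). The per-pair coefficient is computed by
Frisch–Waugh–Lovell residualization against the shared covariates, which
is algebraically the full-model OLS coefficient with n − p − 1 residual
df; pairs with missing dosages fall back to a complete-case full solve.
MAF is computed on the analysis cohort after complete-case reduction, and
sub-MAF (default < 0.05) SNPs are skipped with counts.

Case/control association is additive logistic regression fitted by
Newton/IRLS (tolerance 1e-8, max 100 iterations). Complete separation is
flagged and no odds ratio is reported for the SNP; the scan's
genomic-control λ is attached to the table but never applied as a
correction. In the biomarker panels, where separation is routine for
strongly discriminating CpG sets, the linear score direction still
converges, so a lightly ridge-penalized fit supplies the score and the
result is flagged.

The mediation triangle is a pure intersection report: SNPs in a
significant meQTL whose CpG is disease-associated and whose association
P is below the suggestive level (default 0.05). The
`direction_consistent` flag (does the risk allele move methylation toward
the case profile, i.e. sign(meQTL effect × log OR) = sign(EWAS effect)?)
is reported but not used as a filter — no formal causal mediation test is
performed, and Mendelian randomization is out of scope.

## The synthetic cohort generator

The generator's defaults are the study conditions the pipeline is
designed for: discovery 31 MCTD cases vs 255 shared controls (plus 234
SLE, 206 SjS, 217 RA, 177 SSc cases against the same pool), a 21/103
replication cohort on a legacy platform covering ~55% of probes, an
extended genotype-only sample bringing the association cohort to 89 cases
vs 550 controls, disease effects drawn in Δβ ∈ [−0.5, −0.07] at 150
interferon-like probes (6% flipped hypermethylated, so called sets are
~94% hypomethylated), six-fold case variance inflation at 80 variable
probes (85% overlapping the affected set), treatments assigned to exact
counts 12/13/9 of 31 cases, and cross-disease effect multipliers
1.0/1.0/0.15/0.2 for SLE/SjS/RA/SSc.

Model, per probe j and sample i:

    logit(beta_ij) = logit(Σ_c w_ic B_jc) + batch_(probe,batch) +
                     s_age,j·(age_i − 45) + s_sex,j·male_i +
                     γ*_j·g_ij + shift_j(group_i) + e_ij,
    e_ij ~ N(0, σ² · inflation_ij),  beta clipped to (1e-6, 1−1e-6).

Design choices worth recording:

* **Cell mixing on the beta scale.** The cell term is logit(Σ w·B) — a
  linear mixture of cell-type beta profiles pushed through the logit —
  rather than a logit-linear term, because methylated fractions of a cell
  mixture mix linearly by construction. This keeps the beta-scale
  least-squares deconvolution consistent with the generative model, so
  the proportion-recovery checks test the solver, not a model mismatch.
* **Effects live on the beta scale.** Disease and meQTL effects are
  specified as beta-scale differences and converted to logit shifts by
  solving, per probe and sample group, E[β(μ+s)] − E[β(μ)] = target with
  25-node Gauss–Hermite integration over the noise and Brent root
  finding (xtol 1e-10). Expected differences therefore match the truth
  ledger without linearization bias; the recovery tests verify Δβ bias
  < 0.02 at truth −0.3 and meQTL effect bias < 0.01.
* **Mean-preserving variance inflation.** Widening logit-scale noise
  pulls the expected beta toward 0.5, which would leak a mean effect into
  purely variance-inflated probes; the case group is therefore re-centered
  at each inflated probe so VMS-only probes stay invisible to the DMS
  scan.
* **Treatment attenuation** multiplies the case effect by (1 − a) for
  treated cases (a = 0.25 by default, applied to the union of the three
  therapy flags), plus a handful of probes fully specific to one therapy
  (effect zero in treated cases) to exercise the stratified decision
  rule. There is no dose or duration model.
* **Cross-disease idiosyncrasy.** Each non-index disease's target is
  share × Δβ plus N(0, 0.016) per probe. Without this term the shared
  control pool makes estimated effect vectors almost perfectly correlated
  even at share 0.15; 0.016 was chosen so the realized correlation
  pattern reproduces the concordance structure the pipeline is meant to
  detect (≈0.97 for fully shared diseases, ≈0.8 at share 0.15).
* **The wired mediated locus** couples one risk SNP (MAF 0.30,
  case/control allele-frequency shift 0.18, meQTL effect −0.10 on an
  affected probe) so the triangle stage has a known answer. The shift is
  deliberately stronger than the ~0.10 shifts typical of suggestive
  association tables: at n = 89/550 the logistic Wald power at P < 0.05
  is ≈99% for shift 0.18 but only ≈90% for 0.15, and the recovery
  property (wired locus found in ≥48/50 seeds) requires the former. All
  other sub-streams (probes, genotypes, cohorts) derive deterministically
  from one seed via `numpy.random.SeedSequence.spawn`.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent except the wired loci), probe–probe correlation within CpG
islands, batch effects that are shared across probes (batch shifts are
probe-specific), realistic genomic annotation, array measurement error
models (type I/II probe chemistry), or missing data. Passing recovery
tests therefore demonstrate the estimators are correct under the assumed
sampling model, not that the pipeline is robust to artefacts these
features cause in real arrays — probe filtering and the exclusion-list
hooks exist for that purpose but their content must come from the user.

## Problem sizes

Desk-scale runs use 2,000-probe panels (plus 120 reference and 120
X-chromosome probes) with the full default cohort for pipeline-shape
checks; calibration uses a 2,000-probe null cohort; recovery loops use
40–100-probe panels over 10–50 seeds. These sizes give binomial/KS checks
enough resolution (e.g. λ estimated from 2,000 null tests has sd ≈ 0.03)
while keeping the whole suite fast enough to run routinely.

## Known limitations

* In-sample panel AUCs are optimistic, as with any unpenalized logistic
  refit; no cross-validation is applied by default (matching standard
  pROC-style usage), and separation is common for strong panels — the
  reported AUC then comes from the ridge-stabilized score and is flagged.
* The treatment-specific rule inherits the low power of 9–13-case strata;
  its false calls are controlled by the replication requirement, not by
  the discovery thresholds.
* Bonferroni thresholds use m = tests actually run; two analyses that
  filter probes differently will legitimately report different
  thresholds.
* X-chromosome analysis is female-only; no male X or Y-chromosome model
  is provided (Y probes are dropped at filtering).
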