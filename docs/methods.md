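# Methods

## The analysis model

The pipeline treats adipose-tissue inflammation as a per-subject scalar, the
composite inflammation Z-score (AT-InSc): targeted gene counts are divided by
the subject's total aligned reads (×100, "percent of total transcript
reads"), each gene column is standardized to mean 0 / sd 1 with the sample
standard deviation (n − 1), and the score is the unweighted mean of the gene
Z-scores. Z-scoring pools both timepoints by default so that week-0 → week-4
score changes are expressed on a common scale — required for the paired and
interaction analyses of the score; per-timepoint standardization is available
(`per_timepoint=True`) for strictly cross-sectional use. Both choices are
defensible; pooling is the default because the intervention contrast is the
primary question.

Associations between eicosanoids and AT-InSc use Spearman correlations
(mid-ranks for ties, pairwise deletion of missing pairs, n ≥ 4). Each r is
Fisher transformed, z = atanh(r). Within a group of k analytes — a
(precursor, pathway) pair inside one genotype × timepoint cell, or all
analytes of a precursor ("ALL") — the mean z̄ is tested against zero with a
one-sample t across analytes (df = k − 1, two-sided). The reported pooled
correlation is tanh(z̄); the raw mean of r is also emitted because the two
back-transforms differ slightly and the convention is not canonical. The
Fisher transform is applied to Spearman coefficients exactly as it would be
to Pearson ones; the modest variance inflation of Spearman-z is deliberately
ignored in the t statistic (which uses the empirical spread of z across
analytes, not an analytic SE), and the permutation test exists precisely to
quantify that approximation: it permutes subject labels of the score against
the intact analyte panel, preserving inter-analyte correlation, with
p = (1 + #{|z̄*| ≥ |z̄|}) / (n_perm + 1).

Two single-correlation standard-error conventions are carried as metadata
and never enter any test statistic: `as-printed` |1 − r|/√(n − 2) and the
textbook `pearson-se` √(1 − r²)/√(n − 2). The first is the default for
fidelity to the formula as published in this line of work; it is most likely
a typesetting artifact of the second (they coincide at r = 0), so both are
implemented and the choice is recorded in every output. Timepoint contrasts
are paired t-tests on per-analyte z differences; all-zero differences are
reported as the documented no-change convention (t = 0, p = 1) instead of an
undefined statistic.

Multiple-comparison correction is Bonferroni with an explicit family size.
The default family is 14: the 7 group-level tests per genotype (LA: ALL,
LOX, CYP450/sEH; AA: ALL, LOX, CYP450/sEH, COX) × 2 timepoints. For the same
reason the default report surface omits the unlabelled OTHER pathway as a
group of its own — OTHER analytes still enter the precursor-wide ALL pools —
and `include_other=True` restores it.

Cohort-level tests: genotype baseline differences use the pooled-variance
Student t (Welch via `equal_var=False`); within-genotype changes use the
paired t; the diet-genotype interaction uses the two-timepoint split-plot
GLM, computed from the interaction contrast of cell change means, whose
F(1, N − 2) equals the squared pooled t on change scores — the identity is
exact for two timepoints and is asserted in the tests against an independent
mixed-ANOVA implementation. Designs with more than two timepoints are
rejected explicitly. Tertile ANOVA is one-way fixed-effects with all three
pairwise t-tests on the pooled within-group mean square and a Bonferroni
factor of 3. Age-adjusted association uses the partial Pearson correlation
(residuals on age with intercept), with inputs routed through the normality
rule first.

Normality routing: Shapiro–Wilk at α = 0.05 (no threshold is canonical;
0.05 is fixed here); non-normal all-positive variables are natural-log
transformed (natural rather than base-10 — the choice is arbitrary and
recorded); a non-normal variable containing non-positive values is an error
demanding an explicit offset policy, never a silent shift. Tertiles use
linear-interpolation percentiles at 33.33/66.67 with ties assigned to the
lower tertile for determinism; the assignment is invariant under strictly
increasing transforms.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes, not the
biology producing it. One Gaussian latent inflammation factor exists per
(subject, timepoint), AR(1)-correlated across timepoints (autocorrelation
0.5 by default — a placeholder for the unknown within-subject dependence of
repeated measures, chosen as a moderate middle ground; it affects paired-test
power, not calibration). Observables link to it monotonically:

* eicosanoid (standardized) = ρ·latent + √(1 − ρ²)·noise, then an
  exponential link to a positive concentration scale. Because every
  downstream statistic is rank-based, the induced Spearman correlation with
  the latent factor follows the Gaussian-copula identity
  ρ_S = (6/π)·asin(ρ/2); injected Pearson targets are set with the inverse
  map 2·sin(πρ_S/6) where a Spearman-scale target is wanted.
* gene count ~ Poisson(base·exp(λ·latent − λ²/2)), giving realistic
  discreteness for the percent-of-total and Z-score steps. Defaults
  (10 genes, λ = 0.5, base mean 200 counts on ~5000 off-panel reads) were
  fixed by a pre-build calibration study: across λ ∈ [0.4, 1.0] and base
  ∈ [150, 500] the score–latent Spearman exceeds 0.99, so pooled-correlation
  recovery against the score is attenuated by < 0.01 relative to targets
  set against the latent factor itself.
* fatty-acid proportions are genotype × timepoint means plus Gaussian noise
  (optionally latent-coupled the same way), clipped at zero and rescaled so
  each fraction's sum stays below 100 %.
* a `latent_shift` per (genotype, timepoint) moves the latent mean; this is
  what produces a diet-genotype interaction in AT-InSc. It is the one
  generator parameter beyond the correlation structure itself, added because
  no configuration of correlations alone can shift the score's mean.

Default design: arms TT n = 25 and CC n = 28 with ages 55.1 ± 2.2 and
58.8 ± 3.1 years (drawn genotype-specifically so the age-adjustment path is
exercised by construction), timepoints week0/week4; the cross-sectional
variant defaults to TT n = 42 / CC n = 28 at a single timepoint with a
per-tertile log-mean IL1B step injectable per genotype. The default
eicosanoid panel is 11 LA-derived (LOX 4, CYP450/sEH 4, 3 non-enzymatic) and
21 AA-derived analytes (COX 4, LOX 6, CYP450/sEH 7, 4 other); the pathway
labels drive grouping and are fully configurable. The default (showcase)
effect specification injects the qualitative pattern the method is built to
detect — positive CYP450/sEH coupling in TT after the diet, negative LOX
coupling in CC, a COX sign flip in CC, an LA–score correlation of 0.544 in
TT at week 4, and a latent fall in CC (−0.45) against a small rise in TT
(+0.25) — while `null_effects()` sets every coupling to zero with
independent analytes.

What the generator does **not** emulate: measurement physics of GC/LC–MS,
inter-analyte correlation beyond the shared latent factor (real oxylipin
panels are strongly co-correlated within pathways; under the null here,
analytes are independent by construction, which is exactly the setting in
which the pooled t's type-I error is interpretable), batch effects, and
non-Gaussian tail behaviour. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model — not
that the model captures every feature of real plasma lipidomics.

## Numerical and degeneracy conventions

* Zero rank variance in a correlation: flagged undefined (NaN), dropped from
  pooling; never an exception.
* Pooled group with zero z-spread and nonzero mean: p reported at the
  machine floor with a `degenerate` flag.
* |r| = 1 is rejected by the Fisher transform upstream; the permutation
  statistic clips rank correlations away from ±1 before atanh.
* Groups of a single analyte are rejected, never silently reported.
* All tests are two-sided; sidedness is never inferred from the data.
* Determinism: one `numpy` Generator seeded from the design; identical
  inputs give byte-identical cohort CSVs and report bodies.

## Problem sizes

The test suite runs the null-calibration study at 2000 simulated single-arm
cohorts (n = 25) and the parameter-recovery study at 500 two-arm cohorts
(n = 25/arm), the sizes at which a ±0.015 band on a 0.05 rejection rate and
a ±0.05 band on a mean pooled correlation are comfortably resolvable. The
standalone acceptance script uses 600 and 300 replicates respectively — the
package's own choice of a quick-reproduction size; at 300 replicates the
Monte-Carlo standard error of the recovered mean pooled r is ≈ 0.005, an
order of magnitude below the band it is compared against.

## Known limitations

* The min-p identification rate of a weakly coupled cell (ρ ≈ 0.25 on seven
  analytes at n = 25) is ≈ 0.5, not high: the injected cell's one-sample t
  has median p ≈ 0.02 while the minimum of the ~27 remaining null group
  p-values has median ≈ 0.025, so weak true signals are flagged as the top
  group only about half the time at this sample size. This is a property of
  the design's power, reported as measured, not a defect of the machinery;
  strongly coupled cells (ρ ≥ 0.6) are flagged first in ≥ 90 % of runs.
* The GLM supports exactly two timepoints; longer designs need a proper
  mixed model and are rejected rather than approximated.
* The Spearman-z variance inflation is uncorrected in the pooled t, matching
  the published procedure; the permutation route is the recommended check
  whenever a pooled p sits near a decision threshold.
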