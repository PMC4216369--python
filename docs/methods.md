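# Methods notes

This note records the statistical conventions, simulation design and
numerical choices behind `mirsmoke`, in the order the pipeline runs.

## Expression model and detection floor

All analyses consume RPKM, a continuous non-negative quantity. The
detection floor is 1 RPKM: values below it are treated as not
expressed, the comparison is strict (a value of exactly 1.0 counts as
expressed), and a miRNA below the floor in every sample is removed
before analysis. Fold changes are detection-floored ratios
`max(t, 1) / max(n, 1)`; this makes ratios at or below the floor equal
to 1 instead of exploding at zero denominators, consistent with the
floor's meaning. Test statistics operate on `log2(RPKM + 1)`.

"Average fold change" between two groups is the ratio of detection-
floored group means (ratio of means, not mean of ratios). The
mean-of-ratios alternative is attenuated by the floor for weakly
expressed miRNAs and does not match the pooled-normal logic used in
external validation, where per-tumor folds are taken against a pooled
normal mean.

## Statistical primitives (`mirsmoke.stats`)

All tests are implemented from first principles; scipy supplies only
distribution tail functions (normal, chi-square, F) and midranks.

- **Permutation test**: statistic is the difference of group means on
  log2(RPKM+1). When the number of distinct label assignments C(n, n1)
  is at most `n_perm`, the full null support is enumerated (exact);
  otherwise `n_perm` random reassignments with the add-one estimator
  `p = (1 + hits) / (n_perm + 1)`, which cannot return p = 0 and is
  slightly conservative. Constant pooled data returns p = 1. The
  genome-scale variant shares one permutation set across all miRNAs of
  a scan (a single matrix product per batch); this is the standard
  vectorization and leaves each row's marginal p-value unchanged.
- **Wilcoxon signed-rank**: zero differences dropped before ranking
  (Wilcoxon's original treatment), midranks for ties. For n ≤ 15
  non-zero differences the two-sided p enumerates all 2^n sign
  assignments of the observed midranks (exact even under ties);
  otherwise a normal approximation with tie-corrected variance
  (Σr²/4) and a 0.5 continuity correction.
- **Benjamini–Hochberg**: step-up q-values, order-preserving,
  clipped at 1. Applied within each analysis family: the whole tested
  miRNA set of a scan, and per smoking group for recurrence calling
  (each group's calls are their own family, since the criteria are
  stated per group).
- **Fisher exact (2×2)**: two-sided by the point-probability rule
  (sum of all hypergeometric outcomes no more probable than the
  observed table, with a 1e-9 relative tolerance for ties). The
  doubling rule is a known alternative; the point-probability rule
  matches the convention of R's `fisher.test` and scipy.
- **Chi-square**: Pearson X² without continuity correction; a zero
  expected cell raises an error advising the Fisher test.
- **Kruskal–Wallis**: H with tie correction, chi-square reference with
  k−1 df.
- **MANOVA**: Wilks' Λ = det(W)/det(W+B) with Rao's F approximation;
  with a single response this reduces exactly to one-way ANOVA. The
  per-response univariate F table is returned alongside so individual
  clinical factors can be reported. Singular within-group scatter is
  reported with the offending columns.

## Clustering

Ward clustering operates on samples using Euclidean distance of
row-standardized log2(RPKM+1) profiles (zero-variance rows dropped);
the criterion is Ward.D2 via the Lance–Williams update as implemented
in scipy, and the tree is cut to exactly k clusters with labels
renumbered in order of first appearance. Cluster-composition tests use
Fisher for 2×2 and chi-square otherwise. Covariate scans encode
categorical covariates as integers (stage ordinally, ethnicity by
sorted label order) and report the one-way F across cluster labels;
pairwise pack-year / years-quit contrasts between two named clusters
use a Welch t-test.

## Differential expression and classification

The smoke-response contrast (CS vs NS normals, and FS vs NS normals
for reversibility) flags a miRNA as DE when the B-H q is below 0.05
(strict) and the mean fold is above 2.0 or below 0.5 (strict).
Recurrence calling within a group requires the paired Wilcoxon q
below 0.05 and the per-pair fold beyond the threshold in at least 25%
of pairs (inclusive, so exactly 25% qualifies). If both tails pass,
the larger frequency wins and an exact tie yields no call.

Specificity is evaluated per direction: criteria met in exactly one
group ⇒ `<group>-specific`, in two ⇒ `partial`, in all three ⇒
`shared-all`. A miRNA may carry one call per direction (underexpressed
in one group's tumors and overexpressed in another's).

Reversibility takes the FS-normal vs NS-normal contrast as the
reference comparison (the natural operationalization of "returned to
never-smoker levels"): irreversible = same-direction DE, reversible =
DE criteria not met, opposite-direction DE = demoted to
not-smoke-responsive with a warning flag.

The CS-vs-NS tumor comparison is the same unpaired permutation
machinery applied to tumor columns with identical thresholds.

## Synthetic cohorts (`mirsmoke.simdata`)

The generator emulates a paired tumor/normal miRNA-seq cohort of 94
patients (43 CS / 24 FS / 27 NS) over 1372 miRNAs, of which 445 sit
below the detection floor (so filtering yields 927). Resting
expression is log-normal (natural-log mean 2.5, sd 1.5, clipped below
at 2 RPKM for detectable rows) — heavy-tailed with two parameters,
appropriate for a continuous RPKM quantity; planted rows are clipped
below at 10 RPKM because a 4-fold drop from a near-floor baseline
saturates at the floor and carries no recoverable signal, which no
real recurrently altered miRNA would show. Per-sample noise is
multiplicative log-normal with natural-log sd 0.2 (≈ 20% CV; null
per-pair |log2 fold| sd ≈ 0.41). This represents matched-pair
technical plus sampling noise — patient-level biology cancels within
a pair — and keeps the planted conditions (4-fold effects at 50%
penetrance) within the power envelope of the smallest (24-pair)
group. Real unmatched tumor-to-tumor heterogeneity is larger, so
passing recovery tests here demonstrates the machinery, not field
performance on noisy cohorts.

Planted tumor effects mirror the published cohort shape: 196/36
over/under rows shared by all groups, 56/12 altered in exactly two
groups (cycling over the three group pairs), and group-specific
counts 14/11 (CS), 12/2 (FS), 26/1 (NS), all multiplicative 4-fold
effects. Penetrance selects exactly `round(0.5 · n)` carrier pairs
per planted row (rather than i.i.d. Bernoulli flags), so the
configured recurrence fraction is realized in every row; Bernoulli
sampling makes single-row planted classes unrecoverable roughly 15%
of the time purely through carrier-count variance, which would defeat
the generator's role as a ground-truth test bed.

Smoke-response planting shifts 37 rows (25 up, 12 down, 4-fold) in
current-smoker tissue. The shift applies to both tissues of the
affected group, so the CS-vs-NS normal contrast sees it while paired
tumor/normal folds do not. Former-smoker behavior partitions those
rows into 2 reversible (FS at NS level), 15 irreversible (full shift)
and 20 boundary rows shifted by fold^0.4 ≈ 1.74 and labelled
`partial` in the ground truth: their classification is
boundary-dependent by construction, emulating real cohorts where only
a subset of smoke-responsive miRNAs classifies cleanly, and they are
excluded from reversibility recovery scoring on both sides.

Survival: one designated prognostic miRNA (the first shared-over row)
drives an exponential event model, hazard = h₀ · exp(β · z) with
h₀ = 0.02 events/month, β = 0.7 per SD of log2(RPKM+1). Censoring is
administrative with uniform entry: the horizon is solved numerically
(Brent) so the expected censored fraction equals the configured rate
(default 0.30). Exponential hazards satisfy proportional hazards
exactly, so the Cox stage is estimating a well-specified parameter;
uniform censoring keeps the KM/log-rank assumptions exact.

Ethnicity skews Asian among never smokers, pack-years are gamma for
smokers and zero for never smokers, and years-quit exists only for
former smokers — enough structure to exercise the covariate plumbing;
the generator does not model confounding between expression and
clinical covariates beyond the planted survival effect.

## Survival analysis

Eligibility requires RPKM ≥ 1 in at least ⌈2n/3⌉ patients (ceiling
rule: 145 of 218 fails, 146 passes). Tertiles sort ascending by
(value, patient id) — the id makes tie order deterministic — and take
the first and last ⌊n/3⌋ patients; the middle is discarded. On merged
multi-cohort data, tertiles are computed within each cohort of origin
and then pooled for the log-rank test, because systematic platform-
level RPKM differences between cohorts would otherwise turn the
expression strata into cohort strata. The log-rank statistic is the
1-df Mantel–Haenszel form with hypergeometric variance; zero events
give p = 1. Direction reports which tail's KM curve lies lower at the
stratum's median follow-up.

Cox models maximize the Breslow-tie partial likelihood by
Newton–Raphson (centered covariates, at most 50 iterations,
log-likelihood tolerance 1e-9), with Wald tests from the inverse
observed information. Efron's tie correction would be slightly more
accurate under heavy ties but the closed-form Breslow likelihood is
the simpler canonical choice; the fit matches `lifelines` to ≥ 5
decimals on test problems. Expression enters as log2(RPKM+1),
categoricals are one-hot with a reference level, stage is ordinal.
Significance conventions: log-rank p < 0.05, Cox p < 0.1, MANOVA
p < 0.05.

The expression-vs-covariate MANOVA discretizes numeric covariates into
quantile bins for grouping; with a single response per run it is a
one-way ANOVA per covariate.

## Networks

Predictions with fewer than six supporting sources are discarded
(inclusive at six). "Most highly connected" is operationalized as a
`min_degree` parameter on miRNA nodes (applied after optional
restriction to a reference gene list, with degrees recomputed after
the drop); there is no published cutoff, so the value is a per-run
config choice recorded in the output. A gene is unique to a group when
every miRNA targeting it carries that single group tag; genes reached
by two or more groups are shared. Export is GraphML plus a flat TSV
edge list; rendering and pathway enrichment are out of scope.

## Problem sizes in tests and the acceptance script

Calibration suites use 1000 replicates (499 permutations each for the
permutation test); Cox recovery uses 200 replicates of n = 300 with
~30% censoring; recovery runs use the full default 94-patient,
1372-miRNA cohort with 10,000 permutations per contrast. These sizes
give binomial standard errors of about 0.007 on rejection rates and
keep the entire suite within a few minutes on one core.

## Known limitations

- The generator's noise is i.i.d. per cell: no sample-level library
  effects, no miRNA–miRNA correlation, no overdispersed counts; FDR
  behavior on real data with correlated miRNAs will be less clean.
- Reversibility classification is binary per contrast; intermediate
  ("partially reversible") states are only representable as the
  boundary rows described above.
- External validation assumes the external cohort shares the fold
  thresholds and floor; no cross-platform normalization is attempted
  beyond the within-cohort tertile rule in survival.
- The Cox stage fits one miRNA at a time; no multi-miRNA selection or
  penalization.
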