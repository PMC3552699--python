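# Methods

This note documents the statistical model behind `pathclust`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Quantification model

Intensities enter on the log2 scale.  Quantile normalization forces every
sample-replicate column onto the across-column mean of the rank-ordered
values; ties within a column receive the mean of the reference values
their rank range spans (the standard deterministic dialect).  Columns with
missing entries are mapped onto the pooled reference distribution by
quantile interpolation; missing cells stay missing.  Normalization must
precede peptide-to-protein averaging — the matrix carries a scale flag
(`raw → log2 → log2-quantile-normalized`) and re-normalization or
out-of-order aggregation is rejected.

Per-protein subtype effects come from the linear mixed model

    y_ijk = mu + S_j + I_i + e_ijk

with fixed subtype effects S_j, a Gaussian random intercept I_i per
individual, and residual e_ijk over replicate injections.  Since every
individual belongs to exactly one subtype, a subtype-within-individual
random term is confounded with I_i and is absorbed by it rather than
fitted separately.  Identifiability: S_j are sum-to-zero coded, so effect
vectors are directly comparable across proteins when they are correlated
for the intensity distance.

Estimation is REML (statsmodels `MixedLM`).  On balanced complete designs
— equal replicate counts, no missing cells — the REML fixed effects
coincide *exactly* with per-subtype means of per-individual means
(the GLS weights are equal), so the default `method="auto"` detects this
case and uses the closed form, with method-of-moments variance components
(within-individual mean square for sigma_e; between-individual,
within-subtype mean square minus sigma_e^2/r for sigma_I, truncated at
zero).  The equivalence is asserted in the tests at 1e-6.  Unbalanced or
incomplete data use the iterative fit; non-convergent proteins fall back
to the closed form and are flagged (`converged = False`).  Designs
without replication cannot separate I_i from e_ijk; the model
auto-simplifies with a logged warning.

## The variance-adaptive permutation test

For each protein, healthy samples and one cancer subtype are compared.
The test statistic is chosen adaptively: an F test (F = s1²/s2², two-sided
p = 2·min(P(F≤f), P(F≥f)) under F(n1−1, n2−1)) decides at level 0.05
(configurable) between

* the pooled-variance two-sample t statistic, df = n1+n2−2, and
* Welch's t statistic with Satterthwaite degrees of freedom.

The branch decision is re-made at **every** permutation — permuting
labels changes the variance split, and freezing one statistic for all
permutations mis-calibrates the test whenever group variances differ.
The permutation p-value is #{permuted t-test p ≤ observed t-test p}/B.
This count/B estimator (the default) can return 0; the standard
(1+count)/(1+B) estimator is available as `estimator="plus-one"`.
A permuted relabelling that leaves a group with zero variance is
assigned p = 1 (it carries no evidence) and counted; an *observed*
zero-variance group makes the protein untestable, reported with p = 1 and
flagged, rather than aborting a whole screen.

Permutation unit: all replicate injections of one individual move
together, because technical replicates are not exchangeable with
biological samples.  One exception: the per-patient screen (one patient's
replicates vs the whole healthy cohort, used to build patient q-value
profiles for prediction) permutes at the injection level — with a
single-patient group, individual-level blocks admit only n_healthy + 1
distinct relabellings, a p-value grid far too coarse to rank hundreds of
proteins through the q-value cutoffs.

When C(n1+n2, n1) ≤ B the test enumerates all relabellings and is exact;
the Monte-Carlo and exhaustive estimators are tested against a brute-force
enumeration oracle.  The subtype-level screen draws an independent
permutation stream per protein (spawned from one seed, so results are
independent of protein order).  The batch screen used for the 80
per-patient profiles shares one set of shuffles across proteins — the
per-protein p-values are unbiased either way; sharing only correlates
their Monte-Carlo noise, and cuts the cost of a screen to a few matrix
products.

## Multiple testing

Permutation p-values receive Benjamini–Hochberg step-up adjustment and
Storey–Tibshirani q-values.  pi0 is estimated as
#{p > λ}/(m(1−λ)) on the grid λ = 0, 0.05, …, 0.90, smoothed with a cubic
spline and read off at λ = 0.90, clamped to (0, 1]; with fewer than 100
p-values the estimate is too unstable and pi0 = 1 is used, which makes
q identical to BH-adjusted p (an identity kept under test).  At m = 1000
the estimator's sampling sd is ≈ 0.1 — single-draw assertions on pi0 are
meaningless, so the tests average over independent null draws.

Three nested screens declare significance: q < 0.2, q < 0.1, q < 0.05.
The expected number of false positives at a cutoff is threshold × set
size.

## Pathway matrices and distances

Pathway membership comes from a GMT database.  Cutoff matrix Q_k holds k
where a protein is both a pathway member and in the cutoff-k set; the
merged matrix is the elementwise maximum, i.e. the strictest cutoff
passed.  All per-subtype matrices share one global (pathway, protein)
union index — zero-padded — so the distance score is computed over a
common m×n grid and all pairwise distances are mutually consistent.

The distance score sums |q_ij^s − q_ij^t| over the grid.  `mean` mode
(default) divides by m·n and is bounded by 3; `sum` mode reports the raw
sum (the bundled cohort-level reference matrix, with entries 151–1190, is
on the sum scale).  Clustering is invariant to the positive factor
1/(m·n), so the two modes give identical dendrograms.

The three correlation metrics use Pearson correlation over
pairwise-complete entries (minimum 3; no imputation — imputing would
manufacture signal).  Zero-variance profiles make a correlation
undefined: scalar calls raise, while matrix assembly for prediction can
degrade such pairs to distance 1 with a logged message
(`on_constant="one"`), since a patient with an empty significance profile
is genuinely uninformative rather than erroneous.

## Clustering and prediction

Agglomerative clustering on the labelled distance matrix; average linkage
(UPGMA) by default, single and complete supported — no linkage is
canonical for this analysis, and on the 5×5 subtype matrices the
qualitative topology is linkage-stable (tested).  Dendrograms export to
Newick with ultrametric branch lengths: a child hanging from a merge at
height h gets (h − h_child)/2, so every leaf-to-root path is half the
root height.

Nearest-neighbor prediction matches a patient profile to subtype
exemplars under each metric: replicate-mean intensity change relative to
the healthy mean (centered to the same scale as the sum-to-zero effect
exemplars), the patient q-value vector, and the pathway profile/merged
matrix from the patient's own three-cutoff screen.  Exemplars are
computed from all patients of a subtype (resubstitution), matching how
the prediction experiment is defined; a leave-one-out mode recomputes the
held-out patient's subtype exemplar without that patient.  Ties are broken
by the canonical subtype order and flagged.  Accuracy is reported over
all five classes and over the four known subtypes (Unknown excluded).
The per-patient screen rests on two replicate injections and is the
noisiest part of the chain; pathway-level prediction accuracy reflects
that and should be read as a comparison between metrics, not an absolute.

## Synthetic cohorts

The generator reproduces the study conditions: 80 patients with subtype
counts 24 (luminal A), 15 (luminal B), 10 (HER2+), 19 (basal-like) and
12 (Unknown), 80 healthy controls, and 2 replicate injections per sample
(replicates are required for the per-patient test to exist).  The protein
universe defaults to 616.  Intensities are

    baseline_p + effect_p·[cancer, subtype] + ind_{p,i} + rep_c + res_{p,c}

with baseline ~ N(25, 2²) log2 units, a per-(protein, individual)
biological effect (sd 0.4), a per-column injection shift shared by all
proteins of a replicate (sd 0.1; quantile normalization removes most of
it, as in real data), and a per-cell residual (sd 0.3).  No study-specific
variance components are published; these defaults are configuration
chosen to give per-protein effect-to-noise ratios typical of plasma
biomarker work, not estimates.  Receptor statuses are derived from the
true subtype by inverting the assignment rules (Unknown patients get
missing statuses), so true labels are exactly recoverable from the
annotation table.

The default planted structure (`make_block_plan`) gives each subtype 40
differential proteins with log2 effect ±1.0 (two-fold), drawn from
designated active pathways: the luminal pair shares 90% of its proteins,
the basal pair 90%, the two pairs overlap by 10%, and the Unknown class
has its own set.  Shared proteins share effect signs, so within-pair
effect vectors correlate strongly.

What the generator does **not** emulate: peptide-level structure and
missingness mechanisms beyond optional completely-at-random dropout,
intensity-dependent variance, batch effects, or correlated protein
co-regulation outside the planted sets.  Passing recovery tests therefore
shows that the machinery detects the planted structure under the stated
noise model — not that real plasma cohorts would yield the same accuracy.

## Problem sizes used in the tests

The replicated recovery study runs 20 independent cohorts at 200 proteins
and B = 500 permutations with the full 160-sample design and default
effect sizes; the type-I-error calibration uses 500 null proteins at
n = 10 + 10 and B = 1000.  The pipeline default is B = 1000 (the
reference analysis used 100,000, reachable through configuration).

## Known limitations

* The count/B permutation p-value can be exactly 0, which then propagates
  q = 0; use `plus-one` when downstream analysis cannot tolerate zeros.
* pi0 estimation below a few hundred tests falls back to 1 (conservative).
* The q-value distance is computed over proteins with a defined q in both
  subtypes; proteins untestable in either are dropped pairwise.
* Receptor-based subtyping is itself an approximation of the molecular
  subtypes (a sizeable share of true luminal B tumors are HER2−); no
  correction is attempted, and cohort labels inherit that approximation.
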