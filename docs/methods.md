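# Methods

This note documents the statistical models implemented in `metaconsensus`,
the conventions chosen where several were defensible, and what the
synthetic-data generators do and do not emulate.

## Profile handling and cross-classifier matching

A `TaxonProfile` is a taxa × samples matrix of relative abundances in
[0, 1] at a single taxonomic rank, tagged with the classifier that
produced it. Parsers accept two dialects: merged marker-gene tables
(rank-prefixed lineages `k__...|p__...|...|s__...`, one column per
sample, percentages or fractions) and per-sample k-mer reports (taxon
name, NCBI taxonomy ID, read counts, fraction of total reads). Fractions
are preserved exactly as printed; renormalization to unit sum is an
explicit, separate step so that "what the classifier reported" and "what
the analysis used" never blur.

Marker-gene rows whose terminal label is a genome-bin identifier
(SGB/GGB/FGB numbers) have no NCBI taxonomy mapping and are excluded by
default (`retain_bins=True` keeps them). Cross-classifier taxon matching
uses the NCBI taxonomy ID when both sides carry one, otherwise a
normalized name (lowercase, rank prefix stripped, whitespace/underscore
runs collapsed). This is deliberately conservative: no taxonomy-tree
reconciliation is attempted, so taxa renamed between database versions
count as unique to each classifier unless their IDs agree.

**Evidence filtering.** k-mer classifiers assign reads to many spurious
low-abundance taxa. `filter_low_evidence` zeroes cells whose assigned
read count or distinct-minimizer count falls below thresholds given on
the log10 scale; defaults are the strictest grid point we expose
(log10 reads ≥ 1, i.e. ≥ 10 reads; log10 unique minimizers ≥ 3), with
{0, 0.5, 1} × {0, 1, 3} the intended exploration grid. After zeroing,
taxa empty in every sample are dropped globally (matrices stay
rectangular) and samples are renormalized to sum exactly to 1. The
filter is idempotent at fixed thresholds. Minimum-prevalence and
minimum-abundance QC knobs exist but default to 0 (off); they are
approximations, not a validated QC pipeline.

## Diversity

*Normalized alpha diversity* is Pielou's evenness H/ln S, with H the
Shannon entropy of the nonzero renormalized abundances and S the
richness; a one-taxon sample scores 0 by convention (the 0/0 case). The
score is invariant to rescaling and bounded in [0, 1], making samples of
very different richness comparable. Richness is the count of strictly
positive entries — note it is threshold-free and therefore sensitive to
upstream filtering choices.

*Age trends* are ordinary least-squares slopes per year with the
two-sided slope p-value. *Beta diversity* is Bray–Curtis,
d(x, y) = Σ|x−y| / Σ(x+y), on renormalized profiles.

*PCoA* is classical metric scaling: eigendecomposition of the
Gower-centered matrix −½ J D² J. Negative eigenvalues (from
non-Euclidean dissimilarities like Bray–Curtis) are dropped and variance
fractions reported over the positive eigenvalues only; no Cailliez or
Lingoes correction is applied. On a Euclidean distance matrix the
embedding reproduces the input distances to numerical precision, which
the tests verify.

*PERMANOVA* uses the McArdle–Anderson pseudo-F for a continuous
covariate: with H the hat matrix of the design [1, age] and G the
Gower-centered matrix, F = tr(HGH) / [tr((I−H)G(I−H)) / (n−2)]. Age is
treated continuously, not binned. *Procrustes* concordance centers and
scales both ordinations (truncated to their shared axis count) and
reports √(1−m²) from the symmetric superposition; the *Mantel* statistic
is the Pearson correlation of off-diagonal distances.

All permutation tests share one convention: p = (1 + #{stat ≥ obs}) /
(1 + n_perm) with n_perm = 999 by default and an explicit seed, so p is
never 0 and runs are reproducible. For n ≤ 9 samples, `exact=True`
enumerates all n! permutations (including the identity), which the test
suite checks against brute-force oracles at n = 5.

## Differential abundance

Each taxon's relative abundance is log-transformed after adding a
pseudocount, by default half the smallest nonzero abundance in the whole
matrix — a single matrix-wide floor so that zeros are comparable across
taxa. The model is a Gaussian GEE of log abundance on age with sex and
education as covariates, exchangeable working correlation within family
clusters (the cohorts this is designed for include parent–offspring
pairs), and robust sandwich standard errors. When every cluster has size
one the fit degenerates to OLS with HC0 errors, and the two routes agree
to numerical precision (tested). Degenerate designs fail loudly:
zero-variance covariates and collinear columns raise errors naming the
offending columns rather than being silently dropped. A constant
response returns (estimate 0, p 1) by convention. FDR is
Benjamini–Hochberg, computed within each classifier's taxon set for the
individual scans and over the union of combined p-values in the
meta-analysis.

## The AdjMaxP correlated meta-analysis

For a feature tested in both studies, the combined p-value is
max(p_A, p_B) raised to an effective number of studies k_eff ∈ [1, 2].
The dependence input is a single tetrachoric correlation r_t per cohort,
estimated from *all* shared features: each probit-transformed p-value
vector is dichotomized at p = 0.5 (the probit-scale median; the cut is
configurable), and the latent bivariate-normal correlation is fitted by
maximum likelihood with thresholds fixed at the observed marginals
(a 1-D root-finding problem on the bivariate-normal orthant). The
estimate is clamped to [−0.999, 0.999] and unidentifiable tables (a
margin entirely on one side) raise an error; fewer than 20 pairs warn.

**The k_eff rule.** Two rules are implemented:

* `calibrated` (default): k_eff solves the orthant equation
  P(Z₁ > c, Z₂ > c; r_t) = α with c = Φ⁻¹(1 − α^{1/k_eff}) at reference
  level α = 0.05 — i.e. the exponent for which thresholding the combined
  p-value at α has size exactly α under the latent bivariate-normal
  model. It equals 2 exactly at r_t = 0, decreases monotonically, and
  approaches 1 as r_t → 1.
* `linear`: k_eff = 2 − max(r_t, 0). Simpler and exponent-wise close,
  but mildly anticonservative at small positive correlations (measured
  type-I error ≈ 5.2% at latent correlation 0.2 versus 5.0% for the
  calibrated rule), which is why it is not the default.

Negative r_t is truncated to 0 in both rules: exponents above 2 would be
anticonservative and negative dependence between two classifiers run on
the same samples is not a regime we model. Two-sided p-values are
combined without sign gating; direction concordance is reported as an
annotation column, not used as a filter. p-values are clamped to
[1e-15, 1−1e-15] before probit/log transforms.

**Harmonization.** The meta-table covers the union of the two
association tables: shared features get the AdjMaxP combination and the
unweighted mean of the two effect estimates (both scans cover the same
samples, so neither deserves more weight; inverse-variance weighting
would let the classifiers' different zero patterns drive the weights),
single-classifier features keep their own p and estimate, and BH FDR is
computed once over all combined p-values. An empty intersection warns
and degenerates to concatenation.

**Comparators.** Province–Borecki is a Fisher-type combination:
X = −2(ln p_A + ln p_B) referred to a scaled chi-square c·χ²_f matching
the dependent null's first two moments, with cov(−2 ln p₁, −2 ln p₂)
taken from Brown's polynomial r(3.263 + 0.710 r + 0.027 r²); at r_t = 0
it reduces exactly to Fisher's 4-df method. The naive rule flags a
feature when both studies are individually significant (q < α, or p < α
for nominal-level evaluation) with the same effect direction.

## Simulation design

`simulate_study_pair` draws, per feature, latent statistics (Z₁, Z₂)
from a bivariate normal with the scenario's background correlation ρ.
Conserved features receive a positive mean shift δ in both coordinates;
unconserved features in one coordinate chosen uniformly at random.
P-values are the upper-tail probability Φ(−Z) and the effect sign is
sign(Z). Under the null the probit-transformed p-values are therefore
*exactly* bivariate normal with correlation ρ — the dependence knob and
the quantity the tetrachoric estimator targets are the same thing, so
estimator consistency is testable, and null p-values are exactly
uniform. (A two-sided construction p = 2(1−Φ(|Z|)) was considered and
rejected: it decouples the probit-scale dependence from ρ — probit
correlation ≈ 0.03/0.18/0.51 at ρ = 0.2/0.5/0.8 — and makes the maximum-p
combination anticonservative at its own estimated correlation, with
measured type-I error up to 6.6%.) One consequence of the one-tailed
construction: features significant in both studies necessarily share a
positive sign, so the naive rule's null rate is the bivariate orthant
probability (α² at ρ = 0) rather than α²/2.

The benchmark re-estimates r_t from each replicate's own 400 p-values —
estimation error is part of every evaluated pipeline, not assumed away.
The default grid is ρ ∈ {0.2, 0.5, 0.8} × unconserved proportion ∈
{0, 0.1, 0.25} × signal ∈ {2, 3, 4} SD with 20% conserved features, 200
replicates of 400 features per scenario; the null (type-I) runs use the
same sizes with no signal. These sizes are a reconstruction of "varying
levels" of each knob, chosen to span weak-to-strong signal and low-to-high
dependence, and run in about a minute on one CPU. Metrics treat conserved
features as positives and *both* null and unconserved features as
negatives — specificity is exactly the ability not to call features whose
signal is not shared. Precision is recorded as missing in replicates
where a method calls nothing; AUC is the rank-based area using the
combined p-value as score (for the naive rule: worst-case per-study
q-value, with sign-discordant features ranked last).

`simulate_paired_profiles` emulates two classifiers viewing one
community: a ground-truth log-abundance matrix (taxon baselines
N(0, 1.5), residual noise SD 0.5, planted per-year age slopes), two
views that each drop a share of taxa (controlled by `overlap_frac`),
multiplicative log-normal quantification noise (SD 0.3 by default), and
renormalization to relative abundances. Metadata mirrors a
family-structured ageing cohort: ages uniform 55–105, binary sex, three
education levels, two-person family clusters for roughly half the
participants. What this does *not* emulate: classifier-specific false
positives correlated with genome similarity, compositional artifacts of
sequencing depth, database-version mismatches, or non-linear age
effects — passing end-to-end tests show the pipeline recovers planted
effects through dropout, noise and closure, not that real classifier
disagreement is this benign.

## Numerical conventions and limitations

* Permutation p-values are never 0; exact enumeration is refused above
  n = 9 (9! permutations).
* Tetrachoric root-finding uses Brent's method on [−0.999, 0.999] with
  boundary clamping when the observed table is more extreme than the
  bracket allows; the calibrated k_eff solver guards both brackets
  against CDF round-off.
* The per-cohort r_t is a single pooled estimate over shared features;
  per-feature correlation modeling is out of scope.
* The calibrated k_eff is exact at its reference level α = 0.05; at
  other thresholds it remains an approximation (as any fixed exponent
  must be).
* With k > 2 studies only the linear k_eff generalization is provided.
* Results at very small feature counts are fragile: the tetrachoric
  estimate is unstable below ~20 shared features and `harmonize` falls
  back to r_t = 0 with a warning when the estimate is unidentifiable.
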