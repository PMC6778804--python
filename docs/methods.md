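# Methods

## Study design

Twelve conditions: {all skin, nonskin₁} × {20SS, 52 hpf, 72 hpf} plus
{periderm, basal, nonskin₂} × {52 hpf, 72 hpf}; two biological replicates
each except a single nonskin₂ replicate at 52 hpf — 23 samples. Each sample
carries a genes × B matrix of bootstrap count resamples (B = 1,000 by
default) from probabilistic quantification; gene counts are sums over
transcript isoforms (the reader offers a transcript→gene aggregation
option).

## Normalisation and transform

Size factors are median-of-ratios against the per-gene geometric-mean
reference, computed over genes positive in every sample and rescaled to
geometric mean 1, so normalisation is idempotent and removes pure library
scaling exactly. The log transform is log₂(x + 0.5); the 0.5 offset keeps
zeros finite while distorting counts near the expressed-gene threshold
(2.5 log₂ ≈ 5.2–5.7 linear depending on whether the offset is inverted) by
an amount immaterial at that magnitude. Approximate TPMs divide
length-normalised rates by their per-sample sum.

## Variance partitioning

For each sample, the variance of the B transformed, size-factor-normalised
bootstrap counts estimates the technical variance of a single observation;
a condition's technical variance v_tech is the unweighted mean over its
samples (equal weight per replicate, robust to unequal bootstrap depth).
The raw biological variance is v_bio_raw = max(0, s² − v_tech) with s² the
replicate variance of transformed values (floored because the decomposition
can go negative in finite samples; undefined for n = 1).

### Shrinkage

Raw variances with ν = n − 1 = 1 degree of freedom are extremely noisy, so
they are shrunk toward a mean–variance trend on the log scale:

v_bio = exp( w·log(v_bio_raw + ε₀) + (1 − w)·t(m) ) − ε₀,  w = ν/(ν + n₀)

with prior weight n₀ = 3 (so w = 1/4 at n = 2 and w = 0 at n = 1, where
the trend value is used outright) and stabiliser ε₀ = 10⁻³. The blend
target is t(m) = log r(m) − log κ/(1 − w), where r(m) is a lowess smooth
(frac = 0.4, no robustifying iterations) of v_bio_raw + ε₀ against the
condition mean m, pooled across all replicated conditions, and
κ = E[(χ²_ν/ν)^w] is a chi-square moment factor. Two deliberate choices
make the across-gene mean of v_bio track the true variance: the lowess
smooth targets the conditional *mean* of the skewed raw variances (robust
iterations would chase a trimmed mean, ≈ 40% low for χ²₁ data), and the κ
correction cancels the downward bias of geometric-style blending
(E[(χ²₁)¹ᐟ⁴] ≈ 0.82). Both factors follow from χ² theory, not from data.
A raw variance lying exactly on the blend target is left unchanged. With
fewer than 50 replicated gene–condition pairs the trend falls back to the
global mean raw variance.

The standard error of a condition mean is √((v_tech + v_bio)/n).

## Category rules

θ = log₂ 1.5 ≈ 0.585; ε = 0.02. All probabilities are under the fitted
independent normal models of the condition means.

- 20SS: 'S' iff P(μ_allskin − μ_nonskin₁ ≤ θ) < ε, else 'N'. The later
  timepoints' negligibility cutoff ε is reused here for symmetry.
- 52/72 hpf, in order: 'N' iff P(μ_P − μ_N ≤ θ ∧ μ_B − μ_N ≤ θ) ≥ ε;
  else 'G' iff P(|μ_P − μ_B| ≤ θ) ≥ ε; else 'P' iff P(μ_P > μ_B) > 0.5
  else 'B'. A tie at exactly 0.5 resolves to 'B' (deterministic output
  preferred over an unspecifiable knife edge).

The joint "neither above" event is a bivariate normal orthant probability:
D₁ = μ_P − μ_N and D₂ = μ_B − μ_N have Var(Dᵢ) = seᵢ² + se_N² and
Cov(D₁, D₂) = se_N² because they share the reference. Degenerate SEs reduce
to indicators, independence products (se_N = 0) or the tighter marginal
(se_P = se_B = 0). A seeded Monte Carlo oracle re-implements every rule by
sampling and is required to agree with the analytic path away from decision
boundaries. The algorithm does not enforce B↔P stability; empty exchange
flows (SBP/SPB/NBP/NPB) are an empirical outcome, reproduced on synthetic
data at low noise.

## Enrichment, filtering, ranking

Gene-set × flow-pattern enrichment uses the exact hypergeometric upper
tail over a configurable universe (default: all genes in the category
table); raw p-values are reported with the p ≤ 10⁻⁴ row/column retention
rule for heatmap export (−log₁₀ p cells), and a Benjamini–Hochberg column
is emitted alongside but never used for filtering. Whether memberships
were propagated to ancestor terms upstream is carried as metadata; the
test makes no ontology assumptions. Fold enrichment is observed fraction /
(background / universe). The expressed-gene filter keeps genes with
condition-mean log₂ expression ≥ 2.5 in at least one condition. The
ranking score is (A − N) + Σ|mᵢ − mean| where A and N average the three
all-skin and three nonskin₁ condition means and the deviations run over
the four basal/periderm conditions; ordering is by descending total with a
lexicographic gene-id tie-break, and heatmap export subtracts each gene's
12-condition mean (residuals sum to zero; on the linear scale they are
fold changes against the geometric mean).

## Clustering

Samples are observations, genes features; PCA is centered (gene-wise, the
standard feature-centering convention) and unscaled. Hierarchical
clustering runs on the first six component scores with complete linkage
under the Chebyshev distance; agglomeration ties break toward the lowest
cluster-index pair. Leaf order is optimised exactly by dynamic programming
over subtree end-leaf pairs (minimising the sum of adjacent-leaf
distances); a brute-force flip enumeration serves as the test oracle for
small trees. Newick export uses branch lengths equal to merge-height
differences.

## Synthetic data

The generator assigns each gene a flow from a configurable mixture
(default: ten flows without B↔P exchanges, 60% NNN), draws a baseline
log₂ level uniformly on [7, 13] (≈130–8,200 expected counts, typical of
deep poly-A bulk libraries), and constructs condition means so that the
zero-noise classification of the true means reproduces the assigned flow
exactly: "higher" tissues sit effect_size above baseline (default 4θ,
unambiguous by construction), all skin at 52/72 hpf is the mid-point of
the two layers, and nonskin₁ tracks nonskin₂. Replicate expected counts
are 2^(mean + 𝒩(0, dispersion²)) times a per-sample library factor drawn
uniformly from [0.5, 2.0] (dispersion default 0.25 on the log₂ scale);
bootstrap matrices multinomially resample each sample's rounded total, so
every bootstrap column conserves the total and the bootstrap mean tracks
the observed counts. Randomness is keyed by (seed, purpose, sample index);
identical configurations are byte-identical.

What the simulation does *not* emulate: negative-binomial quantifier
dispersion, gene length/GC effects, multi-mapping-driven bootstrap
inflation, correlated gene programs, or shot noise in the observed
expected counts themselves (replicates at zero dispersion are identical by
construction — consequently the replicate variance contains no technical
component, and subtracting v_tech biases v_bio down by ≈ v_tech, which is
negligible at the default expression levels). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Problem sizes and checks

The parameter-recovery runs use 2,000 genes with the full 23-sample,
1,000-bootstrap design (≈10 s); unit and property tests use 40–800 genes
with 5–400 bootstraps. The analytic-vs-Monte-Carlo probability check uses
a randomized 500-configuration panel at 10⁶ draws per configuration with a
3-standard-error criterion evaluated at the larger of the two estimates.
Hypergeometric tails are checked against exhaustive enumeration for
universes ≤ 12; leaf ordering against brute-force flip enumeration for
≤ 8 leaves.

## Known limitations

- Single-replicate conditions take their biological variance entirely from
  the pooled trend; genes deviating from the trend are mis-weighted there.
- The orthant probability relies on scipy's bivariate normal CDF
  (quasi-Monte-Carlo, ~10⁻⁸ accuracy), ample for ε = 0.02 decisions.
- The exact leaf-ordering DP is O(n⁴)-ish in leaves and intended for
  experiment-level trees (tens of leaves), not gene-level trees.
- With ε approaching 0.5, category 'N' dominates by construction; the
  Thresholds validator restricts ε to (0, 0.5).
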