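# skinflow

Gene expression "flow" analysis for two-layer embryonic skin transcriptomes.

The vertebrate embryonic skin is a bilayered epithelium: an outer, transient
periderm and an inner basal cell layer that later builds the stratified adult
epidermis. `skinflow` implements the downstream statistics for a FACS +
bulk RNA-seq survey of zebrafish embryonic skin across three developmental
timepoints (20-somite stage ≈ 19 hpf, 52 hpf and 72 hpf) and five sorted
tissues (all skin, nonskin₁, periderm, basal, nonskin₂), a 12-condition,
23-sample design with two biological replicates per condition (one for
nonskin₂ at 52 hpf).

## What it computes

- **Normal expression models.** Per gene *g* and condition *c*, log₂-scale
  expression is modelled as 𝒩(m₍g,c₎, v_tech + v_bio): the technical (assay)
  variance comes from per-sample bootstrap count resamples of the
  quantification, the biological variance from replicates, stabilised by
  empirical-Bayes shrinkage toward a smoothed mean–variance trend. The
  standard error of a condition mean is √((v_tech + v_bio)/n).
- **Category calls with a fold-change threshold.** With θ = log₂ 1.5 and
  ε = 0.02, a gene at 20SS is a skin gene ('S') when
  P(μ_skin − μ_nonskin ≤ θ) < ε. At 52/72 hpf the rules run in order:
  P(neither layer above nonskin₂ by θ) ≥ ε → 'N'onskin;
  else P(|μ_periderm − μ_basal| ≤ θ) ≥ ε → 'G'eneral skin; else
  'P'eriderm- or 'B'asal-preferred by whichever layer is more likely
  highest. The two layer-vs-reference events share μ_nonskin₂, so their
  joint probability is a bivariate normal orthant probability, not a
  product. A Monte Carlo oracle re-derives every call by sampling.
- **Flows.** Concatenating the categories across the three timepoints gives
  one of 2×4×4 = 32 flows (e.g. "SPP": skin gene at 20SS, then
  periderm-preferred at both later stages), with query patterns like
  `*BB` or `SSS` ('S' late = any of G/B/P).
- **Enrichment and ranking.** Hypergeometric gene-set enrichment of terms
  over flows/flow combinations (with the p ≤ 10⁻⁴ row/column retention rule
  for heatmap export), fold-enrichment arithmetic for external profile
  comparisons, an expressed-gene filter (log₂ mean ≥ 2.5, ≈ 5.7 linear),
  and a layer-specificity ranking score (A − N) + Σ|deviation| used to pick
  top candidate genes.
- **Experiment clustering.** Centered, unscaled PCA over samples,
  complete-linkage hierarchical clustering of the first six components under
  the Chebyshev distance, and exact optimal leaf ordering ("swiveling") that
  minimises the sum of adjacent-leaf distances.
- **Synthetic data.** A generator that emulates the full study design
  (truth flows → condition means → log-normal replicate noise → multinomial
  bootstrap tensors), so every stage is testable without any download.

## Worked example

```python
import skinflow as sf

cfg = sf.SimConfig(n_genes=500, n_bootstraps=200, seed=1)
run = sf.simulate_and_classify(cfg)
print("flow recovery:", run.recovery)
print(sf.flow_counts(run.result.calls, ["SPP", "*BB", "SSS", "NNN"]).to_string(index=False))
print("fold enrichment, 46% observed vs 573/31901 background:",
      round(sf.fold_enrichment(0.46, 573, 31901), 2))
```

prints

```
flow recovery: 1.0
pattern  count
    SPP     25
    *BB     30
    SSS     80
    NNN    300
fold enrichment, 46% observed vs 573/31901 background: 25.61
```

Every simulated gene's flow was recovered by the pipeline (`recovery` is
the fraction of genes whose called flow matches the simulation ground
truth). 25 genes were skin genes at 20SS and periderm-preferred at both
later timepoints ("SPP"); `*BB` counts genes basal-preferred at 52 and
72 hpf regardless of their 20SS category; `SSS` counts genes in some skin
category at every timepoint. The fold enrichment is the observed fraction
of a profile (46%) over a background fraction (573 of 31,901 genes),
≈ 26-fold above random expectation.

The same steps are available from a shell:

```sh
skinflow simulate --config sim.yaml --out-prefix sim
skinflow fit --counts sim.counts.tsv --bootstraps sim.bootstraps.h5 \
             --samples sim.samples.tsv --out model.tsv
skinflow classify --model model.tsv --out categories.tsv
skinflow flows --categories categories.tsv SPP '*BB' SSS
skinflow cluster --counts sim.counts.tsv --out-prefix clust
```

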