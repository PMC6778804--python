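"""Synthetic data emulating the 12-condition, 23-sample study design.

Each gene is assigned a ground-truth expression flow; condition means are
constructed so that zero-noise classification reproduces the assigned flow
exactly.  Replicate expected counts add log-normal biological variation and
a per-sample library size factor; each sample then carries B bootstrap
count vectors drawn by multinomial resampling of the sample's total count,
emulating the technical (assay) uncertainty of probabilistic quantification.

Real data differ in ways the simulator deliberately omits: counts are
negative-binomial-dispersed quantifier outputs with gene-length and
GC effects, and bootstrap uncertainty is inflated for genes sharing
sequence with other genes.  The generator captures only the structure the
downstream model assumes: normality on the log2 scale plus multinomial
counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import (
    ALL_FLOWS,
    CONDITIONS,
    LATER_TIMEPOINTS,
    REPLICATES,
    THETA,
    TIMEPOINTS,
    cond_label,
    sample_id,
)
from .io import BootstrapTensor, CountMatrix, SampleSheet

#: default ground-truth flow mixture: no B<->P exchange flows, nonskin-dominant
DEFAULT_TRUTH_MIX: dict[str, float] = {
    "NNN": 0.60,
    "NGG": 0.08,
    "SGG": 0.08,
    "SPP": 0.05,
    "SBB": 0.03,
    "NPP": 0.04,
    "NBB": 0.03,
    "SNN": 0.04,
    "NNG": 0.03,
    "NGN": 0.02,
}


@dataclass
class SimConfig:
    """Configuration of a simulated experiment.

    Parameters
    ----------
    n_genes : number of genes to simulate.
    dispersion : biological standard deviation on the log2 scale.
    effect_size : log2 separation between "higher" and "lower" tissues;
        defaults to four times the fold-change threshold so that true
        calls are unambiguous.
    base_log2_range : range of baseline true log2 expected counts,
        uniform per gene (default 128-8,200 counts, typical of deep
        poly-A bulk libraries).
    """

    n_genes: int
    conditions: tuple = CONDITIONS
    replicates_per_condition: dict = field(default_factory=lambda: dict(REPLICATES))
    n_bootstraps: int = 1000
    dispersion: float = 0.25
    library_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0
    truth_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MIX)
    )
    effect_size: float = 4 * THETA
    base_log2_range: tuple[float, float] = (7.0, 13.0)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_bootstraps < 2:
            raise ValueError("n_bootstraps must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        for flow in self.truth_mix:
            if flow not in ALL_FLOWS:
                raise ValueError(f"invalid flow label {flow!r} in truth_mix")
        total = sum(self.truth_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"truth_mix proportions sum to {total}, expected 1")
        for cond, n in self.replicates_per_condition.items():
            if n < 1:
                raise ValueError(f"replicates for {cond} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "library_size_range" in raw:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        if "base_log2_range" in raw:
            raw["base_log2_range"] = tuple(raw["base_log2_range"])
        if "conditions" in raw:
            raw["conditions"] = tuple(tuple(c) for c in raw["conditions"])
        if "replicates_per_condition" in raw:
            raw["replicates_per_condition"] = {
                tuple(k.split(":")): v
                for k, v in raw["replicates_per_condition"].items()
            }
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth: per-gene condition means, categories and flow."""

    means: pd.DataFrame  # genes x condition labels, true log2 means
    categories: pd.DataFrame  # genes x timepoints
    flows: pd.Series  # gene -> 3-character flow


def _allocate_flows(truth_mix: dict[str, float], n_genes: int) -> list[str]:
    """Deterministic largest-remainder allocation of genes to flows."""
    flows = sorted(truth_mix)
    exact = np.array([truth_mix[f] * n_genes for f in flows])
    base = np.floor(exact).astype(int)
    short = n_genes - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    out: list[str] = []
    for f, k in zip(flows, base):
        out.extend([f] * int(k))
    return out


def generate_truth(config: SimConfig) -> TruthTable:
    """Construct ground-truth condition means realising the truth mix.

    For each gene a baseline level ``b`` is drawn; "higher" tissues sit at
    ``b + effect_size``.  At 20SS an 'S' gene has all_skin above nonskin1;
    at 52/72 hpf category 'G' lifts both layers above nonskin2, 'P'/'B'
    lift one layer only, and 'N' leaves all tissues at baseline.  The
    mixed all_skin / nonskin1 conditions at 52/72 hpf track the layer
    means (all_skin is a physical mixture of the two layers).
    """
    flows = _allocate_flows(config.truth_mix, config.n_genes)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.base_log2_range
    base = rng.uniform(lo, hi, size=config.n_genes)
    e = config.effect_size

    means = pd.DataFrame(
        0.0, index=genes, columns=[cond_label(*c) for c in config.conditions]
    )
    cats = pd.DataFrame("", index=genes, columns=list(TIMEPOINTS))

    for g, gene in enumerate(genes):
        b = base[g]
        flow = flows[g]
        cats.loc[gene] = list(flow)
        # 20SS
        c20 = flow[0]
        means.at[gene, cond_label("all_skin", "20SS")] = b + (e if c20 == "S" else 0.0)
        means.at[gene, cond_label("nonskin1", "20SS")] = b
        for tp, cat in zip(LATER_TIMEPOINTS, flow[1:]):
            if cat == "N":
                mp = mb = b
            elif cat == "G":
                mp = mb = b + e
            elif cat == "P":
                mp, mb = b + e, b
            else:  # B
                mp, mb = b, b + e
            means.at[gene, cond_label("periderm", tp)] = mp
            means.at[gene, cond_label("basal", tp)] = mb
            means.at[gene, cond_label("nonskin2", tp)] = b
            means.at[gene, cond_label("all_skin", tp)] = 0.5 * (mp + mb)
            means.at[gene, cond_label("nonskin1", tp)] = b

    return TruthTable(means=means, categories=cats,
                      flows=pd.Series(flows, index=genes, name="flow"))


def simulate_counts(
    truth: TruthTable, config: SimConfig
) -> tuple[CountMatrix, BootstrapTensor, SampleSheet]:
    """Draw replicate expected counts and per-sample bootstrap tensors.

    Expected counts are ``2**(true mean + N(0, dispersion^2))`` scaled by a
    per-sample library factor; bootstraps multinomially resample each
    sample's total count over genes, so every bootstrap column conserves
    the sample total.  Randomness is keyed by (seed, purpose, sample), so
    identical configurations reproduce byte-identical output.
    """
    genes = list(truth.means.index)
    rows = []
    for cond in config.conditions:
        n_rep = config.replicates_per_condition[cond]
        for rep in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": sample_id(*cond, rep),
                    "tissue": cond[0],
                    "timepoint": cond[1],
                    "replicate": rep,
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))

    counts = pd.DataFrame(index=genes, columns=sheet.sample_ids, dtype=float)
    matrices: dict[str, np.ndarray] = {}
    lo, hi = config.library_size_range
    for s, row in enumerate(rows):
        sid = row["sample_id"]
        mu = truth.means[cond_label(row["tissue"], row["timepoint"])].to_numpy()
        lib_rng = np.random.default_rng([config.seed, 11, s])
        factor = lib_rng.uniform(lo, hi)
        bio_rng = np.random.default_rng([config.seed, 13, s])
        noise = (
            bio_rng.normal(0.0, config.dispersion, size=len(genes))
            if config.dispersion > 0
            else np.zeros(len(genes))
        )
        expected = np.exp2(mu + noise) * factor
        counts[sid] = expected
        total = int(round(expected.sum()))
        p = expected / expected.sum()
        boot_rng = np.random.default_rng([config.seed, 17, s])
        boots = boot_rng.multinomial(total, p, size=config.n_bootstraps)
        matrices[sid] = boots.T.astype(float)

    return (
        CountMatrix(counts),
        BootstrapTensor(genes=genes, matrices=matrices),
        sheet,
    )
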