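"""Gene-set enrichment over flows, expressed-gene filtering, layer ranking.

Enrichment of a gene set (e.g. a GO term) within the genes of a flow or
flow combination is tested with the hypergeometric upper tail over a gene
universe; fold enrichment is the observed in-pattern fraction divided by
the background fraction.  Raw p-values are reported (a Benjamini-Hochberg
column is emitted alongside but not used for filtering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .design import LATER_TIMEPOINTS, TIMEPOINTS, cond_label
from .io import GeneSetTable
from .model import ConditionModel

#: log2-scale expressed-gene threshold (~5.7 linear-scale counts)
EXPRESSED_THRESHOLD = 2.5


@dataclass
class EnrichmentResult:
    term: str
    pattern: str
    universe_size: int  # N
    term_size: int  # K
    pattern_size: int  # n
    overlap: int  # k
    p_value: float  # P(X >= k), exact tail
    fold: float  # (k/n) / (K/N); NaN for empty pattern
    empty_pattern: bool = False


def expressed_filter(
    model: ConditionModel, tau: float = EXPRESSED_THRESHOLD
) -> set[str]:
    """Genes with condition-mean log2 expression >= tau in any condition."""
    return set(model.mean.index[(model.mean >= tau).any(axis=1)])


def hypergeom_enrich(
    term_genes: set[str], pattern_genes: set[str], universe: set[str],
    term: str = "", pattern: str = "",
) -> EnrichmentResult:
    """Exact hypergeometric upper-tail enrichment of a term in a pattern."""
    if not term_genes <= universe:
        raise ValueError("term genes must be a subset of the universe")
    if not pattern_genes <= universe:
        raise ValueError("pattern genes must be a subset of the universe")
    N, K, n = len(universe), len(term_genes), len(pattern_genes)
    k = len(term_genes & pattern_genes)
    if n == 0:
        return EnrichmentResult(term, pattern, N, K, n, k, 1.0, float("nan"),
                                empty_pattern=True)
    p = float(hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else float("nan")
    return EnrichmentResult(term, pattern, N, K, n, k, min(p, 1.0), fold)


def fold_enrichment(
    observed_fraction: float, background_count: int, universe_size: int
) -> float:
    """Observed fraction over the background fraction of the universe."""
    if background_count == 0:
        raise ValueError("background count is zero; fold enrichment undefined")
    if background_count > universe_size:
        raise ValueError("background count exceeds universe size")
    if not 0 <= observed_fraction <= 1:
        raise ValueError("observed fraction must lie in [0, 1]")
    return observed_fraction / (background_count / universe_size)


def enrich_table(
    gene_sets: GeneSetTable,
    calls: pd.DataFrame,
    patterns: list[str],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of every term against every flow pattern.

    The universe defaults to all genes in the category table.  Adds a
    Benjamini-Hochberg adjusted column across the whole grid.
    """
    from .classify import flow_members

    if universe is None:
        universe = set(calls.index)
    rows = []
    for pattern in patterns:
        members = flow_members(calls, pattern) & universe
        for term, genes in gene_sets.sets.items():
            res = hypergeom_enrich(
                genes & universe, members, universe, term=term, pattern=pattern
            )
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    # Benjamini-Hochberg over the grid (reported, not used for filtering)
    p = out["p_value"].to_numpy()
    order = np.argsort(p)
    ranked = np.empty_like(p)
    m = len(p)
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    ranked[order] = np.minimum(adj, 1.0)
    out["p_bh"] = ranked
    return out


def enrich_heatmap(
    results: pd.DataFrame, p_cutoff: float = 1e-4
) -> pd.DataFrame:
    """Filter a term x pattern grid for export.

    Keeps every row and column containing at least one p-value <= cutoff;
    cells carry -log10 p.
    """
    grid = results.pivot(index="term", columns="pattern", values="p_value")
    keep_rows = (grid <= p_cutoff).any(axis=1)
    keep_cols = (grid <= p_cutoff).any(axis=0)
    filtered = grid.loc[keep_rows, keep_cols]
    return -np.log10(filtered)


# ---------------------------------------------------------------------------
# layer-specific gene ranking

#: conditions entering the skin-enrichment score
_A_CONDS = [cond_label("all_skin", tp) for tp in TIMEPOINTS]
_N_CONDS = [cond_label("nonskin1", tp) for tp in TIMEPOINTS]
#: conditions entering the layer-specificity score
_LAYER_CONDS = [
    cond_label(t, tp) for t in ("basal", "periderm") for tp in LATER_TIMEPOINTS
]


def rank_genes(
    model: ConditionModel, class_members: set[str] | None = None
) -> pd.DataFrame:
    """Score and rank genes by skin enrichment plus layer specificity.

    The skin score is A - N (mean over the three all-skin conditions minus
    mean over the three nonskin1 conditions); the layer score is the sum of
    absolute deviations of the four basal/periderm condition means from
    their own mean.  Genes are ordered by descending total with a
    deterministic tie-break on gene id.
    """
    for c in _A_CONDS + _N_CONDS + _LAYER_CONDS:
        if c not in model.mean.columns:
            raise ValueError(f"condition {c!r} missing from model")
    means = model.mean
    if class_members is not None:
        means = means.loc[means.index.intersection(sorted(class_members))]
    skin_score = means[_A_CONDS].mean(axis=1) - means[_N_CONDS].mean(axis=1)
    layer = means[_LAYER_CONDS]
    layer_score = (layer.sub(layer.mean(axis=1), axis=0)).abs().sum(axis=1)
    out = pd.DataFrame(
        {
            "skin_score": skin_score,
            "layer_score": layer_score,
            "total": skin_score + layer_score,
        }
    )
    # descending total, ascending gene id on ties
    if not out.empty:
        out = out.iloc[
            np.lexsort((out.index.to_numpy(), -out["total"].to_numpy()))
        ]
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "gene"
    return out


def top_k(ranks: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k rows of a ranking table (default 20, the display convention)."""
    return ranks.head(k)


def heatmap_rows(model: ConditionModel, genes: list[str]) -> pd.DataFrame:
    """Per-gene row mean and mean-subtracted condition values for export.

    On the log2 scale the residuals indicate fold changes relative to the
    gene's geometric mean across the 12 conditions; they sum to zero.
    """
    missing = [g for g in genes if g not in model.mean.index]
    if missing:
        raise KeyError(f"unknown gene id {missing[0]!r}")
    sub = model.mean.loc[genes]
    row_mean = sub.mean(axis=1)
    residuals = sub.sub(row_mean, axis=0)
    out = residuals.copy()
    out.insert(0, "row_mean", row_mean)
    return out
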