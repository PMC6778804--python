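"""Fold-change-threshold ordering probabilities and category/flow calls.

Under the fitted normal models, "A is significantly higher than B" is the
event ``mu_A - mu_B > theta`` with theta the log2 fold-change threshold
(1.5x by default).  At 20SS a gene is 'S' when the probability that all
skin is *not* significantly higher than nonskin1 is negligible (< eps).
At 52/72 hpf the rules are applied in order: a non-negligible probability
that neither layer exceeds nonskin2 gives 'N'; otherwise a non-negligible
probability that the layers are not significantly different gives 'G';
otherwise 'P' or 'B' according to which layer is more likely highest.

The two layer-vs-reference differences share the nonskin2 mean, so their
joint probability is a bivariate normal orthant probability with
covariance ``se_N**2``, not a product of marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .design import (
    ALL_FLOWS,
    CATEGORIES_LATER,
    EPSILON,
    LATER_TIMEPOINTS,
    THETA,
    cond_label,
)
from .model import ConditionModel


@dataclass
class Thresholds:
    """Decision thresholds for category calls."""

    theta: float = THETA  # log2 fold-change threshold (1.5x)
    epsilon: float = EPSILON  # negligibility probability
    mc_draws: int = 100_000  # Monte Carlo sample count for the oracle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")


def prob_exceeds(mA, seA, mB, seB, theta) -> float:
    """P(mu_A - mu_B > theta) under independent normal posteriors."""
    d = mA - mB
    s = math.hypot(seA, seB)
    if s == 0:
        return float(d > theta)
    return float(norm.sf((theta - d) / s))


def prob_not_different(mP, seP, mB, seB, theta) -> float:
    """P(|mu_P - mu_B| <= theta)."""
    d = mP - mB
    s = math.hypot(seP, seB)
    if s == 0:
        return float(abs(d) <= theta)
    return float(norm.cdf((theta - d) / s) - norm.cdf((-theta - d) / s))


def prob_neither_above(mP, seP, mB, seB, mN, seN, theta) -> float:
    """P(mu_P - mu_N <= theta and mu_B - mu_N <= theta).

    The differences D1 = mu_P - mu_N and D2 = mu_B - mu_N are jointly
    normal with Cov(D1, D2) = se_N^2 (the shared reference); degenerate
    cases reduce to indicators, products, or the tighter marginal.
    """
    vP, vB, vN = seP * seP, seB * seB, seN * seN
    d1, d2 = mP - mN, mB - mN
    var1, var2 = vP + vN, vB + vN
    if var1 == 0 and var2 == 0:
        return float(d1 <= theta and d2 <= theta)
    if var1 == 0:
        return float(d1 <= theta) * float(norm.cdf((theta - d2) / math.sqrt(var2)))
    if var2 == 0:
        return float(d2 <= theta) * float(norm.cdf((theta - d1) / math.sqrt(var1)))
    if vN == 0:
        return float(
            norm.cdf((theta - d1) / math.sqrt(var1))
            * norm.cdf((theta - d2) / math.sqrt(var2))
        )
    if vP == 0 and vB == 0:
        # comonotone: both events are lower bounds on the same mu_N
        return float(norm.cdf((theta - max(d1, d2)) / math.sqrt(vN)))
    cov = np.array([[var1, vN], [vN, var2]])
    return float(
        multivariate_normal(mean=[d1, d2], cov=cov).cdf([theta, theta])
    )


def _model_arrays(model: ConditionModel, tissue: str, timepoint: str):
    lbl = cond_label(tissue, timepoint)
    if lbl not in model.mean.columns:
        raise ValueError(f"condition {lbl!r} missing from model")
    return model.mean[lbl].to_numpy(), model.se[lbl].to_numpy()


def classify_20ss(model: ConditionModel, th: Thresholds | None = None) -> pd.Series:
    """'S' vs 'N' at 20SS: all skin significantly above nonskin1.

    A gene is 'S' when the probability that all skin is not significantly
    higher than nonskin1 is below eps.
    """
    th = th or Thresholds()
    mA, seA = _model_arrays(model, "all_skin", "20SS")
    mN, seN = _model_arrays(model, "nonskin1", "20SS")
    out = []
    for i in range(len(mA)):
        p_not_higher = 1.0 - prob_exceeds(mA[i], seA[i], mN[i], seN[i], th.theta)
        out.append("S" if p_not_higher < th.epsilon else "N")
    return pd.Series(out, index=model.genes, name="cat_20SS")


def classify_later(
    model: ConditionModel, timepoint: str, th: Thresholds | None = None
) -> pd.Series:
    """'N'/'G'/'B'/'P' at 52 or 72 hpf from layer ordering probabilities."""
    th = th or Thresholds()
    if timepoint not in LATER_TIMEPOINTS:
        raise ValueError(f"no layer-level classification at {timepoint!r}")
    mP, seP = _model_arrays(model, "periderm", timepoint)
    mB, seB = _model_arrays(model, "basal", timepoint)
    mN, seN = _model_arrays(model, "nonskin2", timepoint)
    out = []
    for i in range(len(mP)):
        out.append(
            _later_call(
                mP[i], seP[i], mB[i], seB[i], mN[i], seN[i], th.theta, th.epsilon
            )
        )
    return pd.Series(out, index=model.genes, name=f"cat_{timepoint}")


def _later_call(mP, seP, mB, seB, mN, seN, theta, epsilon) -> str:
    if prob_neither_above(mP, seP, mB, seB, mN, seN, theta) >= epsilon:
        return "N"
    if prob_not_different(mP, seP, mB, seB, theta) >= epsilon:
        return "G"
    # ties at exactly 0.5 resolve to 'B' for determinism
    return "P" if prob_exceeds(mP, seP, mB, seB, 0.0) > 0.5 else "B"


def assign_flows(
    cat20: pd.Series, cat52: pd.Series, cat72: pd.Series
) -> pd.DataFrame:
    """Combine per-timepoint categories into the 3-character flow label."""
    calls = pd.DataFrame(
        {"cat_20SS": cat20, "cat_52hpf": cat52, "cat_72hpf": cat72}
    )
    calls["flow"] = calls["cat_20SS"] + calls["cat_52hpf"] + calls["cat_72hpf"]
    calls.index.name = "gene"
    return calls


def classify_all(model: ConditionModel, th: Thresholds | None = None) -> pd.DataFrame:
    """Run all three timepoint classifications and assign flows."""
    th = th or Thresholds()
    return assign_flows(
        classify_20ss(model, th),
        classify_later(model, "52hpf", th),
        classify_later(model, "72hpf", th),
    )


# ---------------------------------------------------------------------------
# flow query patterns

_POS0 = {"N": ("N",), "S": ("S",), "*": ("N", "S")}
_POS12 = {
    "N": ("N",),
    "G": ("G",),
    "B": ("B",),
    "P": ("P",),
    "S": ("G", "B", "P"),  # "any skin"
    "*": CATEGORIES_LATER,
}


def expand_flow_query(pattern: str) -> set[str]:
    """Expand a 3-character flow pattern into its concrete flows.

    '*' matches every category at its timepoint; 'S' at 52/72 hpf means
    "any skin" (G, B or P).
    """
    if len(pattern) != 3:
        raise ValueError(f"flow pattern must have 3 characters, got {pattern!r}")
    if pattern[0] not in _POS0:
        raise ValueError(
            f"invalid character {pattern[0]!r} at position 1 of {pattern!r}"
        )
    for pos in (1, 2):
        if pattern[pos] not in _POS12:
            raise ValueError(
                f"invalid character {pattern[pos]!r} at position {pos + 1} "
                f"of {pattern!r}"
            )
    return {
        a + b + c
        for a in _POS0[pattern[0]]
        for b in _POS12[pattern[1]]
        for c in _POS12[pattern[2]]
    }


def flow_counts(calls: pd.DataFrame, patterns: list[str]) -> pd.DataFrame:
    """Count genes matching each flow pattern."""
    flows = calls["flow"]
    rows = []
    for pat in patterns:
        concrete = expand_flow_query(pat)
        rows.append({"pattern": pat, "count": int(flows.isin(concrete).sum())})
    return pd.DataFrame(rows)


def flow_members(calls: pd.DataFrame, pattern: str) -> set[str]:
    """Gene ids whose flow matches the pattern."""
    concrete = expand_flow_query(pattern)
    return set(calls.index[calls["flow"].isin(concrete)])


# ---------------------------------------------------------------------------
# Monte Carlo verification oracle


def mc_oracle_classify(
    model: ConditionModel, timepoint: str, th: Thresholds | None = None
) -> pd.Series:
    """Brute-force sampling analogue of :func:`classify_later`.

    Draws joint samples of (mu_P, mu_B, mu_N) from independent normals,
    estimates the three event probabilities empirically, and applies the
    same decision rules.
    """
    th = th or Thresholds()
    mP, seP = _model_arrays(model, "periderm", timepoint)
    mB, seB = _model_arrays(model, "basal", timepoint)
    mN, seN = _model_arrays(model, "nonskin2", timepoint)
    rng = np.random.default_rng(th.seed)
    out = []
    for i in range(len(mP)):
        p = rng.normal(mP[i], seP[i], size=th.mc_draws)
        b = rng.normal(mB[i], seB[i], size=th.mc_draws)
        nn = rng.normal(mN[i], seN[i], size=th.mc_draws)
        p_neither = np.mean((p - nn <= th.theta) & (b - nn <= th.theta))
        if p_neither >= th.epsilon:
            out.append("N")
            continue
        p_notdiff = np.mean(np.abs(p - b) <= th.theta)
        if p_notdiff >= th.epsilon:
            out.append("G")
            continue
        out.append("P" if np.mean(p > b) > 0.5 else "B")
    return pd.Series(out, index=model.genes, name=f"cat_{timepoint}")


def n_possible_flows() -> int:
    return len(ALL_FLOWS)
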