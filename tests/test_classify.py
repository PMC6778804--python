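"""Ordering probabilities, category rules, flows and the sampling oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from skinflow import (
    ALL_FLOWS,
    THETA,
    Thresholds,
    assign_flows,
    classify_all,
    expand_flow_query,
    flow_counts,
    mc_oracle_classify,
    prob_exceeds,
    prob_neither_above,
    prob_not_different,
)
from skinflow.classify import _later_call, classify_20ss, classify_later
from skinflow.model import ConditionModel


def toy_model(rows):
    """Build a ConditionModel from {cond_label: (mean, se)} per gene."""
    genes = [f"g{i}" for i in range(len(rows))]
    labels = sorted(rows[0])
    mean = pd.DataFrame(
        [[rows[i][c][0] for c in labels] for i in range(len(rows))],
        index=genes, columns=labels,
    )
    se = pd.DataFrame(
        [[rows[i][c][1] for c in labels] for i in range(len(rows))],
        index=genes, columns=labels,
    )
    zeros = mean * 0.0
    n = pd.Series(2, index=labels)
    return ConditionModel(mean=mean, v_tech=zeros, v_bio_raw=zeros,
                          v_bio=se**2 * 2, n=n, se=se)


class TestProbExceeds:
    def test_difference_at_threshold_is_half(self):
        assert np.isclose(prob_exceeds(1.0, 0.3, 1.0 - THETA, 0.4, THETA), 0.5)

    def test_degenerate_indicator(self):
        assert prob_exceeds(2 * THETA, 0.0, 0.0, 0.0, THETA) == 1.0
        assert prob_exceeds(0.5 * THETA, 0.0, 0.0, 0.0, THETA) == 0.0

    def test_normal_cdf_value(self):
        # (theta - d)/s = (0.585 - 1.585)/sqrt(0.5) = -1.41421
        p = prob_exceeds(1.585, 0.5, 0.0, 0.5, 0.585)
        assert np.isclose(p, norm.sf(-1.0 / np.sqrt(0.5)), atol=1e-12)
        assert np.isclose(p, 0.92135, atol=1e-4)


class TestProbNotDifferent:
    def test_symmetric_interval_at_equal_means(self):
        s = np.hypot(0.3, 0.4)
        expect = 2 * norm.cdf(THETA / s) - 1
        assert np.isclose(prob_not_different(1.0, 0.3, 1.0, 0.4, THETA), expect)

    def test_degenerate_inside_threshold(self):
        assert prob_not_different(1.0, 0.0, 1.2, 0.0, THETA) == 1.0
        assert prob_not_different(1.0, 0.0, 3.0, 0.0, THETA) == 0.0

    def test_normal_cdf_value(self):
        # Phi(-1.17) - Phi(-3.51) with d = 1.17, s = 0.5, theta = 0.585
        p = prob_not_different(1.17, 0.3, 0.0, 0.4, 0.585)
        assert np.isclose(p, norm.cdf(-1.17) - norm.cdf(-3.51), atol=1e-12)
        assert np.isclose(p, 0.1208, atol=1e-3)


class TestProbNeitherAbove:
    def test_zero_reference_se_gives_independence(self):
        p = prob_neither_above(0.2, 0.3, -0.1, 0.4, 0.0, 0.0, THETA)
        expect = norm.cdf((THETA - 0.2) / 0.3) * norm.cdf((THETA + 0.1) / 0.4)
        assert np.isclose(p, expect)

    def test_far_above_is_zero(self):
        p = prob_neither_above(10.0, 0.1, 10.0, 0.1, 0.0, 0.1, THETA)
        assert p < 1e-15

    def test_shared_reference_correlation_vs_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 10**6
        mP = mB = mN = 1.0
        p_draw = rng.normal(mP, 0.5, n)
        b_draw = rng.normal(mB, 0.5, n)
        n_draw = rng.normal(mN, 0.5, n)
        emp = np.mean((p_draw - n_draw <= 0.585) & (b_draw - n_draw <= 0.585))
        ana = prob_neither_above(mP, 0.5, mB, 0.5, mN, 0.5, 0.585)
        se = np.sqrt(emp * (1 - emp) / n)
        assert abs(ana - emp) <= 3 * se

    def test_correlation_matters(self):
        # equal means: joint "both below" exceeds the independence product
        joint = prob_neither_above(0.0, 0.5, 0.0, 0.5, 0.0, 0.5, THETA)
        indep = norm.cdf(THETA / np.hypot(0.5, 0.5)) ** 2
        assert joint > indep

    def test_degenerate_layers_comonotone(self):
        # seP = seB = 0: both events constrain the same mu_N
        p = prob_neither_above(1.0, 0.0, 0.5, 0.0, 0.0, 0.4, THETA)
        expect = norm.cdf((THETA - 1.0) / 0.4)
        assert np.isclose(p, expect)


class TestCategoryRules:
    def test_equal_means_called_nonskin_at_20ss(self):
        model = toy_model([
            {"all_skin:20SS": (2.0, 0.3), "nonskin1:20SS": (2.0, 0.3)}
        ])
        assert classify_20ss(model).iloc[0] == "N"

    def test_large_difference_called_skin(self):
        model = toy_model([
            {"all_skin:20SS": (10 * THETA, 0.1), "nonskin1:20SS": (0.0, 0.1)}
        ])
        assert classify_20ss(model).iloc[0] == "S"

    def test_difference_exactly_theta_is_nonskin(self):
        model = toy_model([
            {"all_skin:20SS": (THETA, 0.2), "nonskin1:20SS": (0.0, 0.2)}
        ])
        # P(not higher) = 0.5 >= eps
        assert classify_20ss(model).iloc[0] == "N"

    @pytest.mark.parametrize(
        "mP,mB,mN,se,expected",
        [
            (1.0, 1.0, 1.0, 0.1, "N"),
            (4.0, 4.0, 1.0, 0.2, "G"),  # both above, indistinguishable
            (5.0, 1.0, 1.0, 0.1, "P"),
            (1.0, 5.0, 1.0, 0.1, "B"),
        ],
    )
    def test_later_rules(self, mP, mB, mN, se, expected):
        th = Thresholds()
        assert _later_call(mP, se, mB, se, mN, se, th.theta, th.epsilon) == expected

    def test_missing_condition_errors(self, small_model):
        partial = ConditionModel(
            mean=small_model.mean.drop(columns=["periderm:52hpf"]),
            v_tech=small_model.v_tech,
            v_bio_raw=small_model.v_bio_raw,
            v_bio=small_model.v_bio,
            n=small_model.n,
            se=small_model.se,
        )
        with pytest.raises(ValueError, match="periderm"):
            classify_later(partial, "52hpf")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
        st.floats(0.05, 1.0), st.floats(-5, 5),
    )
    def test_translation_invariance(self, mP, mB, mN, se, shift):
        """Only differences enter: shifting all means keeps the category."""
        th = Thresholds()
        pN = prob_neither_above(mP, se, mB, se, mN, se, th.theta)
        pG = prob_not_different(mP, se, mB, se, th.theta)
        pPB = prob_exceeds(mP, se, mB, se, 0.0)
        # skip knife-edge cases where float jitter could flip the rule
        assume(abs(pN - th.epsilon) > 1e-6)
        assume(abs(pG - th.epsilon) > 1e-6)
        assume(abs(pPB - 0.5) > 1e-6)
        a = _later_call(mP, se, mB, se, mN, se, th.theta, th.epsilon)
        b = _later_call(
            mP + shift, se, mB + shift, se, mN + shift, se, th.theta, th.epsilon
        )
        assert a == b

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2),
        st.floats(0.05, 0.8), st.floats(0.1, 3),
    )
    def test_raising_periderm_never_turns_p_into_b(self, mP, mB, mN, se, bump):
        th = Thresholds()
        before = _later_call(mP, se, mB, se, mN, se, th.theta, th.epsilon)
        after = _later_call(mP + bump, se, mB, se, mN, se, th.theta, th.epsilon)
        if before == "P":
            assert after != "B"


class TestFlows:
    def test_concatenation(self):
        calls = assign_flows(
            pd.Series(["S", "N"], index=["a", "b"]),
            pd.Series(["P", "N"], index=["a", "b"]),
            pd.Series(["P", "N"], index=["a", "b"]),
        )
        assert list(calls["flow"]) == ["SPP", "NNN"]

    def test_32_possible_flows(self):
        assert len(ALL_FLOWS) == 32
        assert len(set(ALL_FLOWS)) == 32

    @pytest.mark.parametrize(
        "pattern,size",
        [("*BB", 2), ("SSS", 9), ("**S", 24), ("***", 32), ("SPP", 1)],
    )
    def test_query_expansion_sizes(self, pattern, size):
        assert len(expand_flow_query(pattern)) == size

    def test_star_bb_expansion(self):
        assert expand_flow_query("*BB") == {"NBB", "SBB"}

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            expand_flow_query("SXP")
        with pytest.raises(ValueError, match="position 1"):
            expand_flow_query("GPP")

    def test_partition_and_counts(self, small_run):
        calls = small_run.result.calls
        total = flow_counts(calls, list(ALL_FLOWS))["count"].sum()
        assert total == len(calls)
        # every gene has exactly one category per timepoint
        for col in ("cat_20SS", "cat_52hpf", "cat_72hpf"):
            assert calls[col].str.len().eq(1).all()


class TestMonteCarloOracle:
    def test_fixed_seed_reproducible(self, small_model):
        th = Thresholds(mc_draws=2000, seed=5)
        a = mc_oracle_classify(small_model, "52hpf", th)
        b = mc_oracle_classify(small_model, "52hpf", th)
        assert (a == b).all()

    def test_agrees_with_analytic_away_from_boundaries(self):
        """Random panel: oracle and analytic rules agree except where the
        analytic probabilities sit within 3 MC standard errors of the
        decision boundaries."""
        rng = np.random.default_rng(12)
        n_genes, draws = 200, 100_000
        th = Thresholds(mc_draws=draws, seed=99)
        rows = []
        for _ in range(n_genes):
            rows.append({
                "periderm:52hpf": (rng.normal(0, 2), rng.uniform(0.05, 0.8)),
                "basal:52hpf": (rng.normal(0, 2), rng.uniform(0.05, 0.8)),
                "nonskin2:52hpf": (rng.normal(0, 2), rng.uniform(0.05, 0.8)),
            })
        model = toy_model(rows)
        analytic = classify_later(model, "52hpf", th)
        oracle = mc_oracle_classify(model, "52hpf", th)
        mcse = lambda p: np.sqrt(max(p * (1 - p), 1e-12) / draws)
        for i, g in enumerate(model.genes):
            row_m = model.mean.iloc[i]
            row_s = model.se.iloc[i]
            pN = prob_neither_above(
                row_m["periderm:52hpf"], row_s["periderm:52hpf"],
                row_m["basal:52hpf"], row_s["basal:52hpf"],
                row_m["nonskin2:52hpf"], row_s["nonskin2:52hpf"], th.theta,
            )
            pG = prob_not_different(
                row_m["periderm:52hpf"], row_s["periderm:52hpf"],
                row_m["basal:52hpf"], row_s["basal:52hpf"], th.theta,
            )
            pPB = prob_exceeds(
                row_m["periderm:52hpf"], row_s["periderm:52hpf"],
                row_m["basal:52hpf"], row_s["basal:52hpf"], 0.0,
            )
            borderline = (
                abs(pN - th.epsilon) <= 3 * mcse(pN)
                or abs(pG - th.epsilon) <= 3 * mcse(pG)
                or abs(pPB - 0.5) <= 3 * mcse(pPB)
            )
            if not borderline:
                assert analytic[g] == oracle[g]

    def test_large_epsilon_forces_nonskin_in_both(self):
        model = toy_model([
            {"periderm:52hpf": (1.0, 0.3), "basal:52hpf": (0.8, 0.3),
             "nonskin2:52hpf": (0.0, 0.3)},
        ])
        th = Thresholds(epsilon=0.499, mc_draws=5000, seed=1)
        pN = prob_neither_above(1.0, 0.3, 0.8, 0.3, 0.0, 0.3, th.theta)
        if pN >= th.epsilon:
            assert classify_later(model, "52hpf", th).iloc[0] == "N"
            assert mc_oracle_classify(model, "52hpf", th).iloc[0] == "N"


def test_full_classification_on_simulated_run(small_run):
    calls = classify_all(small_run.result.model)
    assert calls["flow"].isin(ALL_FLOWS).all()
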