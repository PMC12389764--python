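"""Score fusion: quantification, normalisation, domain means, CRITIC
weighting, the comprehensive score, and the paired comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ergocab.fusion import (
    DOMAINS,
    EvaluationResult,
    MethodScores,
    NormalizationRange,
    compare_layouts,
    critic_weights,
    default_ranges,
    domain_means,
    model_structure,
    normalize_score,
    quantify_ratio,
    relative_reduction,
    total_score,
)


class TestQuantifyAndNormalize:
    @pytest.mark.parametrize(
        "total, in_scope, expected", [(5, 3, 0.4), (4, 4, 0.0), (4, 0, 1.0)]
    )
    def test_ratio_score(self, total, in_scope, expected):
        assert quantify_ratio(total, in_scope) == pytest.approx(expected)

    def test_empty_class_is_not_applicable(self):
        assert quantify_ratio(0, 0) is None

    def test_minmax_normalisation(self):
        lba = NormalizationRange("lba", 0.0, 6000.0)
        assert normalize_score(2300.0, lba) == pytest.approx(0.38333, abs=1e-5)
        assert normalize_score(0.0, lba) == 0.0
        assert normalize_score(6000.0, lba) == 1.0

    def test_out_of_range_clips_with_warning(self):
        rng = NormalizationRange("ca", 0.0, 80.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert normalize_score(95.0, rng) == 1.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="xmin"):
            NormalizationRange("bad", 5.0, 5.0)

    def test_default_ranges_cover_all_raw_scorers(self):
        ranges = default_ranges()
        assert ranges["lba"].xmax == 6000.0
        assert ranges["ca"].xmax == 80.0
        assert (ranges["owas"].xmin, ranges["owas"].xmax) == (1.0, 4.0)
        assert {"rula_upper", "rula_trunk", "rula_whole"} <= set(ranges)


class TestDomainMeans:
    def _scores(self, **kw):
        per_region = lambda v: {"upper": v, "trunk": v, "whole": v}
        defaults = dict(
            p1=0.2, p2=0.3, p3=0.1, p4=0.0, p5=0.5, p6=0.0, p7=0.0,
            p8=per_region(0.4), p9=0.6, p10=per_region(0.2),
            p11={"upper": 0.0, "lower": 0.3, "trunk": 0.0, "whole": 0.3},
        )
        defaults.update(kw)
        return MethodScores(**defaults)

    def test_fixed_groupings(self):
        dm = domain_means(self._scores())
        assert dm["MA1"] == pytest.approx(0.25)
        assert dm["MA2"] == pytest.approx(0.1)
        assert dm["MB1"] == pytest.approx(0.25)
        assert dm["MB2"] == 0.0
        assert dm["MC1"] == pytest.approx((0.4 + 0.2 + 0.0) / 3)
        assert dm["MC2"] == pytest.approx((0.6 + 0.3) / 2)
        assert dm["MC4"] == pytest.approx((0.4 + 0.2 + 0.3) / 3)

    def test_extremes(self):
        ones = {"upper": 1.0, "trunk": 1.0, "whole": 1.0}
        dm = domain_means(self._scores(p8=ones, p10=ones, p11={**ones, "lower": 1.0}))
        assert dm["MC4"] == 1.0

    def test_not_applicable_component_renormalises(self):
        dm = domain_means(self._scores(p2=None))
        assert dm["MA1"] == pytest.approx(0.2)  # mean over P1 alone
        assert any("P2" in entry for entry in dm.na_ledger)

    def test_fully_missing_domain_marked(self):
        dm = domain_means(self._scores(p6=None, p7=None))
        assert dm["MB2"] is None


class TestCritic:
    def test_two_domain_hand_computed_case(self):
        w = critic_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(w, [0.5, 0.5])
        # intermediate quantities of the same case, by hand: sigma = 0.5,
        # r = -1, conflict R = 2, information C = 1 each
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        sigma = x.std(axis=0)  # population form
        assert np.allclose(sigma, [0.5, 0.5])

    def test_identical_columns_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = critic_weights(np.array([[0.3, 0.3], [0.3, 0.3], [0.3, 0.3]]))
        assert np.allclose(w, [0.5, 0.5])

    @given(st.integers(0, 200))
    def test_weights_sum_to_one_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(rng.integers(2, 12), rng.integers(2, 6)))
        w = critic_weights(x)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(20, 4))
        w1 = critic_weights(x)
        w2 = critic_weights(x[rng.permutation(20)])
        assert np.allclose(w1, w2)

    def test_common_scaling_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(size=(15, 5))
        assert np.allclose(critic_weights(x), critic_weights(3.7 * x))

    def test_shape_requirements(self):
        with pytest.raises(ValueError, match="2 samples"):
            critic_weights(np.array([[1.0, 2.0]]))


class TestTotalScore:
    def test_weighted_mean(self):
        assert total_score(np.array([0.2, 0.4]), np.array([0.5, 0.5])) == pytest.approx(0.3)

    def test_constant_means_give_that_constant(self):
        w = np.array([0.2, 0.3, 0.5])
        assert total_score(np.full(3, 0.37), w) == pytest.approx(0.37)

    def test_monotone_in_any_mean(self):
        w = np.array([0.25, 0.75])
        assert total_score(np.array([0.3, 0.4]), w) < total_score(np.array([0.5, 0.4]), w)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            total_score(np.array([0.1, 0.2]), np.array([1.0]))

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(size=8)
        w = rng.uniform(size=8)
        w /= w.sum()
        expected = sum(mi * wi for mi, wi in zip(m, w))  # independent dot product
        assert abs(total_score(m, w) - expected) < 1e-12

    def test_relative_reduction_of_totals(self):
        assert relative_reduction(0.422, 0.277) == pytest.approx(34.36, abs=0.01)


class TestModelStructure:
    def test_eight_domains_eleven_leaf_methods(self):
        structure = model_structure()
        assert tuple(structure) == DOMAINS
        leaves = {leaf for methods in structure.values() for leaf in methods}
        assert leaves == {f"P{i}" for i in range(1, 12)}


def _result_from_table(df: pd.DataFrame) -> EvaluationResult:
    domains = tuple(c for c in df.columns if c not in ("participant_id", "M"))
    return EvaluationResult(
        sample_table=df,
        participant_table=df,
        weights={d: 1 / len(domains) for d in domains},
        domains=domains,
        m_total=float(df["M"].mean()),
        m_sd=float(df["M"].std(ddof=1)),
    )


class TestCompareLayouts:
    def _toy_pair(self):
        ids = [f"S{i}" for i in range(5)]
        a = pd.DataFrame(
            {
                "participant_id": ids,
                "MA1": [0.30, 0.32, 0.28, 0.35, 0.31],
                "M": [0.40, 0.42, 0.39, 0.44, 0.41],
            }
        )
        b = pd.DataFrame(
            {
                "participant_id": ids,
                "MA1": [0.20, 0.22, 0.21, 0.26, 0.19],
                "M": [0.30, 0.33, 0.31, 0.36, 0.29],
            }
        )
        return _result_from_table(a), _result_from_table(b)

    def test_bonferroni_level_for_nine_indicators(self):
        ra, rb = self._toy_pair()
        report = compare_layouts(ra, rb, n_indicators=9)
        assert report.alpha_corrected == pytest.approx(0.05 / 9)
        assert round(report.alpha_corrected, 4) == 0.0056

    def test_paired_t_matches_textbook_formula(self):
        ra, rb = self._toy_pair()
        report = compare_layouts(ra, rb)
        row = next(r for r in report.rows if r.indicator == "M")
        diff = np.array([0.40, 0.42, 0.39, 0.44, 0.41]) - np.array(
            [0.30, 0.33, 0.31, 0.36, 0.29]
        )
        t_hand = diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff)))
        assert row.t == pytest.approx(t_hand)
        assert row.df == 4

    def test_identical_cohorts_show_no_difference(self):
        ra, _ = self._toy_pair()
        report = compare_layouts(ra, ra)
        assert all(not r.significant for r in report.rows)
        assert all(r.t == 0.0 and r.p == 1.0 for r in report.rows)

    def test_mismatched_participants_rejected(self):
        ra, rb = self._toy_pair()
        rb.participant_table = rb.participant_table.assign(
            participant_id=["X0", "X1", "X2", "X3", "X4"]
        )
        with pytest.raises(ValueError, match="different participants"):
            compare_layouts(ra, rb)
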