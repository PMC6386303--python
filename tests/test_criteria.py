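"""Cutoff derivation, criteria scoring and the group-comparison statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from euslymph import (
    AgreementResult,
    ConfigError,
    ConsensusFeatures,
    DegenerateInputError,
    LesionRecord,
    assoc_test_2x2,
    clinical_round,
    new_criteria,
    old_criteria,
    score_criteria,
    select_features,
    wilcoxon_rank_sum,
    youden_cutoff,
)


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        res = youden_cutoff([30, 25, 10, 12], ["malignant"] * 2 + ["benign"] * 2)
        assert res.youden_cutoff_mm == pytest.approx(18.5)
        assert res.youden_j == pytest.approx(1.0)

    def test_identical_values_error(self):
        with pytest.raises(DegenerateInputError):
            youden_cutoff([5, 5, 5], ["malignant", "benign", "benign"])

    def test_single_class_error(self):
        with pytest.raises(DegenerateInputError):
            youden_cutoff([5, 6], ["benign", "benign"])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 30), st.booleans()), min_size=4, max_size=25
        )
    )
    def test_equals_brute_force(self, data):
        values = np.array([v for v, _ in data], dtype=float)
        labels = np.array([m for _, m in data])
        if labels.all() or not labels.any() or np.unique(values).size < 2:
            return
        res = youden_cutoff(values, labels)
        # brute force over every observed threshold (midpoints span them all)
        d = np.sort(np.unique(values))
        cands = (d[:-1] + d[1:]) / 2
        js = [
            (values[labels] > t).mean() + (values[~labels] <= t).mean() - 1
            for t in cands
        ]
        assert res.youden_j == pytest.approx(max(js), abs=1e-12)

    def test_tie_breaks_toward_higher_cutoff(self):
        # J is maximal on both sides of the middle value
        res = youden_cutoff([1, 2, 3, 4], [False, False, True, True])
        assert res.youden_cutoff_mm == pytest.approx(2.5)
        res2 = youden_cutoff([1, 2, 2, 3], [False, True, False, True])
        # J(1.5) = J(2.5) here; higher cutoff wins
        assert res2.youden_cutoff_mm == pytest.approx(2.5)

    def test_population_cutoff_recovered_on_large_cohort(self):
        """Sample Youden cutoff lands within 2 mm of the generator's
        population optimum (fine-grid oracle over the two size laws)."""
        from euslymph import CohortConfig, generate_cohort
        from euslymph.simulate import _lognorm_params

        recs, _ = generate_cohort(CohortConfig(n_lesions=10_000, seed=0))
        values = [r.long_axis_mm for r in recs]
        labels = [r.diagnosis for r in recs]
        res = youden_cutoff(values, labels)
        grid = np.linspace(3, 80, 20_000)
        mu_m, s_m = _lognorm_params(25.3, 11.3)
        mu_b, s_b = _lognorm_params(16.8, 8.1)
        J = stats.lognorm.sf(grid, s_m, scale=math.exp(mu_m)) - stats.lognorm.sf(
            grid, s_b, scale=math.exp(mu_b)
        )
        oracle = grid[J.argmax()]
        assert res.youden_cutoff_mm == pytest.approx(oracle, abs=2.0)


class TestClinicalRound:
    @pytest.mark.parametrize(
        "cutoff,expected", [(19.7, 20.0), (10.7, 10.0), (12.5, 15.0), (2.4, 0.0)]
    )
    def test_half_up_on_5mm_grid(self, cutoff, expected):
        assert clinical_round(cutoff) == expected

    def test_bad_grid_rejected(self):
        with pytest.raises(ConfigError):
            clinical_round(19.7, grid_mm=0)


def _agreements(kappas):
    return [
        AgreementResult(f, k, k - 0.1, k + 0.1, "fair", 68)
        for f, k in kappas.items()
    ]


class TestSelectFeatures:
    def test_reported_panel_selects_shape_only(self):
        ag = _agreements(
            {
                "shape": 0.44,
                "border": 0.22,
                "margin": -0.02,
                "echogenicity": 0.33,
                "homogeneity": 0.34,
                "hilum": 0.22,
            }
        )
        assert select_features(ag) == ["shape"]
        assert len(select_features(ag, threshold=0.0)) == 5  # all positive kappas

    def test_empty_input(self):
        assert select_features([]) == []


def _lesion(long_mm, short_mm):
    return LesionRecord("L1", "abdominal", long_mm, short_mm, "malignant")


def _consensus(shape=None, shape_ro=None, **cats):
    categories = dict(cats)
    if shape is not None:
        categories["shape"] = shape
    return ConsensusFeatures("L1", categories=categories, shape_round_or_oval=shape_ro)


class TestScoreCriteria:
    def test_new_criteria_examples(self):
        new = new_criteria()
        # oval, ratio 0.48: both size items true, shape item false
        r = score_criteria(_lesion(25, 12), _consensus("oval", True), new)
        assert r.score == 2
        # ratio exactly 0.5 is not > 0.5
        r = score_criteria(_lesion(22, 11), _consensus("round", True), new)
        assert r.score == 2
        # all-negative lesion
        r = score_criteria(_lesion(9, 5), _consensus("triangle", False), new)
        assert r.score == 0
        assert new.n_items == 3 and old_criteria().n_items == 4

    def test_old_criteria_items(self):
        old = old_criteria()
        cons = _consensus("round", True, border="clear", echogenicity="dark")
        r = score_criteria(_lesion(15, 9), cons, old)
        assert r.score == 4
        cons2 = _consensus("oval", True, border="fuzzy", echogenicity="dark")
        assert score_criteria(_lesion(15, 9), cons2, old).score == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        long_mm=st.floats(5, 60),
        ratio=st.floats(0.05, 1.0),
        grow=st.floats(0.0, 30),
    )
    def test_monotone_in_axis_growth(self, long_mm, ratio, grow):
        """Enlarging both axes proportionally never decreases the new score."""
        new = new_criteria()
        cons = _consensus("round", True)
        small = score_criteria(_lesion(long_mm, long_mm * ratio), cons, new)
        big = score_criteria(
            _lesion(long_mm + grow, (long_mm + grow) * ratio), cons, new
        )
        assert big.score >= small.score

    def test_criteria_serialization_round_trip(self):
        from euslymph.criteria import CriteriaDefinition

        for definition in (new_criteria(), old_criteria()):
            back = CriteriaDefinition.from_dict(definition.to_dict())
            assert back == definition


class TestWilcoxonRankSum:
    def test_identical_samples_null(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_exact_enumeration_small_samples(self):
        # all ranks separated: one-sided tail 1/20 -> two-sided 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_consistency_under_true_effect(self):
        rng = np.random.default_rng(0)
        x = rng.normal(25.3, 11.3, 5000)
        y = rng.normal(16.8, 8.1, 5000)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_rank_sum([], [1.0])


class TestAssocTest2x2:
    @pytest.mark.parametrize(
        "table,expected_p,expected_test,tol",
        [
            ([[27, 3], [32, 6]], 0.72, "fisher", 0.005),
            ([[0, 30], [5, 33]], 0.06, "fisher", 0.005),
            ([[19, 11], [9, 29]], 0.001, "chi-square", 0.0005),
        ],
    )
    def test_published_count_tables(self, table, expected_p, expected_test, tol):
        p, used = assoc_test_2x2(table)
        assert used == expected_test
        assert p == pytest.approx(expected_p, abs=tol)

    def test_zero_margin_degenerate(self):
        p, used = assoc_test_2x2([[0, 0], [5, 7]])
        assert (p, used) == (1.0, "degenerate")

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Fisher branch equals the exhaustive two-sided hypergeometric sum
        for small tables (total <= 40)."""
        rng = np.random.default_rng(10)
        checked = 0
        while checked < 60:
            a, b, c, d = rng.integers(0, 9, size=4)
            t = np.array([[a, b], [c, d]])
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            if not (expected < 5).any():
                continue
            p, used = assoc_test_2x2(t)
            assert used == "fisher"
            # enumeration oracle
            n1, n0 = a + b, c + d
            m1 = a + c
            rv = stats.hypergeom(n1 + n0, n1, m1)
            p_obs = rv.pmf(a)
            support = np.arange(max(0, m1 - n0), min(m1, n1) + 1)
            oracle = rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, abs=1e-9)
            checked += 1


def test_group_comparison_rows(study_cohort):
    from euslymph import build_feature_frame, consolidate_majority, group_comparison

    lesions, _, ratings = study_cohort
    frame = build_feature_frame(lesions, consolidate_majority(ratings))
    rows = {r["variable"]: r for r in group_comparison(frame)}
    assert rows["long_axis_mm"]["test"] == "wilcoxon-rank-sum"
    assert rows["long_axis_mm"]["p"] < 0.05  # sizes separate the classes
    assert 0 <= rows["shape=round"]["p"] <= 1
    assert rows["long_axis>20mm"]["malignant_count"] + rows["long_axis>20mm"]["benign_count"] == sum(
        (r.long_axis_mm > 20) for r in lesions
    )
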