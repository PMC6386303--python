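"""Fleiss kappa, bootstrap CI, Landis-Koch bands and majority consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from euslymph import (
    ConfigError,
    RatingTable,
    UndefinedKappaError,
    consolidate_majority,
    feature_agreement,
    fleiss_kappa,
    kappa_bootstrap_ci,
    landis_koch,
)
from conftest import binary_counts


class TestFleissKappa:
    def test_hand_calculation(self):
        # 3 lesions x 3 raters: P-bar = 7/9, Pe = 41/81, kappa = 22/40
        counts = np.array([[3, 0], [0, 3], [2, 1]])
        assert fleiss_kappa(counts) == pytest.approx(22 / 40)

    def test_perfect_agreement(self):
        counts = np.array([[5, 0], [0, 5], [5, 0]])
        assert fleiss_kappa(counts) == pytest.approx(1.0)

    def test_single_category_is_error_not_nan(self):
        with pytest.raises(UndefinedKappaError):
            fleiss_kappa(np.array([[5, 0], [5, 0]]))

    def test_matches_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n, K, R = rng.integers(2, 12), rng.integers(2, 5), rng.integers(2, 7)
            counts = rng.multinomial(R, np.ones(K) / K, size=n)
            try:
                ours = fleiss_kappa(counts)
            except UndefinedKappaError:
                continue
            assert ours == pytest.approx(sm_fleiss(counts, method="fleiss"), abs=1e-12)

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(5)
        counts = rng.multinomial(5, [0.4, 0.35, 0.25], size=10)
        base = fleiss_kappa(counts)
        for _ in range(10):
            perm_rows = rng.permutation(counts.shape[0])
            perm_cols = rng.permutation(counts.shape[1])
            assert fleiss_kappa(counts[perm_rows][:, perm_cols]) == pytest.approx(base)

    def test_unanimity_iff_kappa_one(self):
        unanimous = np.array([[0, 5], [5, 0], [0, 5]])
        assert fleiss_kappa(unanimous) == pytest.approx(1.0)
        not_unanimous = np.array([[0, 5], [5, 0], [4, 1]])
        assert fleiss_kappa(not_unanimous) < 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        rows=st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=4)
    )
    def test_small_binary_tables_match_direct_formula(self, rows):
        """Exhaustive-style oracle: direct formula evaluation, written
        independently with explicit loops."""
        R = 3
        counts = np.array([[k, R - k] for k in rows])
        pooled = counts.sum(axis=0) / (len(rows) * R)
        pe = sum(p * p for p in pooled)
        if 1 - pe < 1e-12:
            with pytest.raises(UndefinedKappaError):
                fleiss_kappa(counts)
            return
        p_i = [
            sum(c * (c - 1) for c in row) / (R * (R - 1)) for row in counts
        ]
        oracle = (sum(p_i) / len(p_i) - pe) / (1 - pe)
        assert fleiss_kappa(counts) == pytest.approx(oracle, abs=1e-12)


class TestBootstrapCI:
    def test_degenerate_perfect_agreement(self):
        counts = np.array([[5, 0]] * 3 + [[0, 5]] * 3)
        assert kappa_bootstrap_ci(counts, B=200, seed=0) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        counts = binary_counts(rng.random(60) < 0.5, 0.2, 5, rng)
        a = kappa_bootstrap_ci(counts, B=500, seed=31)
        b = kappa_bootstrap_ci(counts, B=500, seed=31)
        assert a == b

    def test_interval_brackets_estimate_with_slack(self):
        rng = np.random.default_rng(12)
        counts = binary_counts(rng.random(68) < 0.5, 0.25, 5, rng)
        k = fleiss_kappa(counts)
        lo, hi = kappa_bootstrap_ci(counts, B=1000, seed=2)
        assert lo - 0.01 <= k <= hi + 0.01

    def test_rejects_tiny_samples_and_small_B(self):
        counts = np.array([[3, 2], [2, 3]])
        with pytest.raises(ConfigError):
            kappa_bootstrap_ci(counts, B=100, seed=0)
        with pytest.raises(ConfigError):
            kappa_bootstrap_ci(np.array([[3, 2]] * 4), B=200, seed=0)

    def test_coverage_of_long_run_kappa(self):
        """95% percentile interval covers the model's long-run kappa in
        >= 90 of 100 seeded replications (eps=0.2, n=500, B=1000)."""
        eps, n, R = 0.2, 500, 5
        p = 0.5  # truth is Bernoulli(0.5), so the marginal stays 0.5
        target = 1 - eps * (1 - eps) / (p * (1 - p))
        hits = 0
        master = np.random.default_rng(2718)
        for _ in range(100):
            truth = master.random(n) < 0.5
            counts = binary_counts(truth, eps, R, master)
            lo, hi = kappa_bootstrap_ci(
                counts, B=1000, seed=int(master.integers(2**31))
            )
            hits += lo <= target <= hi
        assert hits >= 90


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.44, "moderate"),
            (0.33, "fair"),
            (0.34, "fair"),
            (0.22, "fair"),
            (-0.02, "less than chance"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.405, "moderate"),
            (0.75, "substantial"),
            (0.95, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_scale(self, kappa, label):
        assert landis_koch(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            landis_koch(1.5)


class TestConsolidateMajority:
    @staticmethod
    def _shape_table(votes):
        rows = [("L1", f"R{i+1}", "shape", v) for i, v in enumerate(votes)]
        # second lesion keeps the table multi-lesion
        rows += [("L2", f"R{i+1}", "shape", "polygonal") for i in range(5)]
        return RatingTable.from_rows(rows)

    def test_three_of_five_rule(self):
        table = self._shape_table(["round", "round", "round", "oval", "polygonal"])
        cons = {c.lesion_id: c for c in consolidate_majority(table)}
        assert cons["L1"].categories["shape"] == "round"
        assert cons["L1"].shape_round_or_oval is True

    def test_indeterminate_shape_still_binarizes(self):
        table = self._shape_table(["round", "oval", "oval", "triangle", "polygonal"])
        cons = {c.lesion_id: c for c in consolidate_majority(table)}
        assert cons["L1"].categories["shape"] == "indeterminate"
        assert cons["L1"].shape_round_or_oval is True  # 3 of 5 round-or-oval

    def test_binary_majority(self):
        rows = [
            ("L1", r, "border", c)
            for r, c in zip(
                ["R1", "R2", "R3", "R4", "R5"],
                ["clear", "clear", "fuzzy", "fuzzy", "clear"],
            )
        ]
        rows += [("L2", f"R{i+1}", "border", "fuzzy") for i in range(5)]
        cons = {c.lesion_id: c for c in consolidate_majority(RatingTable.from_rows(rows))}
        assert cons["L1"].categories["border"] == "clear"
        assert cons["L1"].votes["border"] == {"clear": 3, "fuzzy": 2}

    def test_min_votes_above_panel_rejected(self, tiny_ratings):
        with pytest.raises(ConfigError):
            consolidate_majority(tiny_ratings, min_votes=4)

    def test_incomplete_cells_excluded(self):
        rows = [("L1", r, "border", "clear") for r in ["R1", "R2", "R3", "R4"]]
        rows += [("L1", r, "hilum", "absent") for r in ["R1", "R2", "R3", "R4", "R5"]]
        cons = {c.lesion_id: c for c in consolidate_majority(RatingTable.from_rows(rows))}
        assert "border" not in cons["L1"].categories
        assert cons["L1"].categories["hilum"] == "absent"


def test_feature_agreement_end_to_end(study_cohort):
    _, _, ratings = study_cohort
    results = feature_agreement(ratings, B=300, seed=5)
    by_feature = {a.feature: a for a in results}
    assert set(by_feature) == {
        "shape", "border", "margin", "echogenicity", "homogeneity", "hilum"
    }
    for a in results:
        assert a.n_lesions_used == 68
        assert a.ci_low - 0.01 <= a.kappa <= a.ci_high + 0.01
        assert a.landis_label == landis_koch(a.kappa)
    assert by_feature["shape"].per_category is not None
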