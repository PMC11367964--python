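"""Agreement statistics against hand-evaluated and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from replanar import (ScoreTable, bland_altman, cohens_kappa,
                      concordance_summary, fleiss_kappa, pearson_regression,
                      percent_agreement)


class TestPercentAgreement:
    @pytest.mark.parametrize("n_agree,n,expected", [
        (27, 30, 90),   # three minor discordances in a 30-subject cohort
        (29, 30, 97),   # a single discordance
        (30, 30, 100),
        (15, 30, 50),
    ])
    def test_rounded_percentages(self, n_agree, n, expected):
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        b[:n - n_agree] = 1
        assert percent_agreement(a, b) == expected

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 4, 50)
        assert percent_agreement(a, b) == percent_agreement(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement([0, 1], [0])


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 2, 3, 0, 1])
        res = cohens_kappa(a, a.copy(), ci_method="none")
        assert res.kappa == 1.0
        assert res.percent_agreement == 100

    def test_hand_evaluated_two_by_two(self):
        """Confusion table [[35, 15], [25, 25]] (n=100): p_o = 0.6 and
        marginals (0.5, 0.5) x (0.6, 0.4) give p_e = 0.5, hence
        kappa = (0.6 - 0.5)/(1 - 0.5) = 0.2 by hand."""
        a = np.repeat([0, 0, 1, 1], [35, 15, 25, 25])
        b = np.repeat([0, 1, 0, 1], [35, 15, 25, 25])
        res = cohens_kappa(a, b, ci_method="none")
        assert res.kappa == pytest.approx(0.2, abs=1e-12)
        assert res.percent_agreement == 60

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 10_000)
        b = rng.integers(0, 4, 10_000)
        assert abs(cohens_kappa(a, b, ci_method="none").kappa) < 0.05

    def test_matches_statsmodels(self):
        """Cross-check against an independent implementation."""
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 60)
        b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 4, 60))
        table = np.zeros((4, 4))
        for i, j in zip(a, b):
            table[i, j] += 1
        expected = float(sm_kappa(table, return_results=False))
        assert cohens_kappa(a, b, ci_method="none").kappa == pytest.approx(
            expected, rel=1e-10)

    def test_degenerate_marginals_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cohens_kappa(np.zeros(10, int), np.zeros(10, int),
                               ci_method="none")
        assert res.kappa == 1.0

    def test_bootstrap_ci_seeded_and_contains_estimate(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 30)
        b = np.where(rng.random(30) < 0.8, a, rng.integers(0, 4, 30))
        r1 = cohens_kappa(a, b, n_boot=500, seed=11)
        r2 = cohens_kappa(a, b, n_boot=500, seed=11)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.kappa <= r1.ci_high


class TestFleissKappa:
    def test_unanimous_raters(self):
        table = np.tile(np.array([0, 1, 2, 3, 1, 2])[:, None], (1, 3))
        assert fleiss_kappa(table).kappa == 1.0

    def test_brute_force_oracle(self):
        """Direct evaluation of the defining sums on a small 3-rater table."""
        table = np.array([
            [0, 0, 1], [1, 1, 1], [2, 2, 3], [0, 1, 2],
            [3, 3, 3], [2, 2, 2], [1, 2, 1], [0, 0, 0]])
        n_sub, n_rat = table.shape
        cats = sorted(set(table.ravel().tolist()))
        # brute force: per-subject pairwise agreement and category shares
        p_i = []
        for row in table:
            agree = sum(1 for i in range(n_rat) for j in range(n_rat)
                        if i != j and row[i] == row[j])
            p_i.append(agree / (n_rat * (n_rat - 1)))
        p_j = [sum(1 for row in table for r in row if r == c)
               / (n_sub * n_rat) for c in cats]
        expected = (np.mean(p_i) - sum(p ** 2 for p in p_j)) \
            / (1 - sum(p ** 2 for p in p_j))
        assert fleiss_kappa(table).kappa == pytest.approx(expected, rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 4, 40)
        table = np.column_stack([
            np.where(rng.random(40) < 0.8, truth, rng.integers(0, 4, 40))
            for _ in range(3)])
        counts, _ = aggregate_raters(table)
        assert fleiss_kappa(table).kappa == pytest.approx(
            float(sm_fleiss(counts)), rel=1e-10)

    def test_uniform_random_near_zero(self):
        rng = np.random.default_rng(5)
        table = rng.integers(0, 4, size=(5000, 3))
        assert abs(fleiss_kappa(table).kappa) < 0.05

    def test_single_subject_ci_flagged(self):
        with pytest.warns(UserWarning, match="single subject"):
            res = fleiss_kappa(np.array([[1, 1, 2]]))
        assert np.isnan(res.ci_low) and np.isnan(res.ci_high)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 1.5, 2.0])
        res = bland_altman(x, x.copy())
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_constant_shift(self):
        x = np.array([1.0, 1.5, 2.0])
        res = bland_altman(x, x + 0.2)
        assert res.bias == pytest.approx(0.2)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.loa_low == pytest.approx(0.2)
        assert res.loa_high == pytest.approx(0.2)

    def test_hand_computed_three_pairs(self):
        """Pairs (1.0,1.1), (2.0,2.3), (3.0,3.2): d = {0.1, 0.3, 0.2}."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 2.3, 3.2])
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(0.2)
        assert res.sd == pytest.approx(0.1)
        assert res.loa_low == pytest.approx(0.2 - 1.96 * 0.1)
        assert res.loa_high == pytest.approx(0.2 + 1.96 * 0.1)
        np.testing.assert_allclose(res.means, [1.05, 2.15, 3.1])

    def test_loa_symmetric_about_bias(self):
        rng = np.random.default_rng(6)
        x = rng.random(25)
        y = x + rng.normal(0, 0.1, 25)
        res = bland_altman(x, y)
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low)


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = pearson_regression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        assert pearson_regression(x, -x).r == pytest.approx(-1.0)

    def test_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random(20)
        y = 1.5 * x + rng.normal(0, 0.1, 20)
        res = pearson_regression(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        r_direct = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(r_direct, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_regression(np.ones(5), np.arange(5.0))


def _score_frame(scores_by_reader_mod):
    rows = []
    for (reader, mod), scores in scores_by_reader_mod.items():
        for i, s in enumerate(scores):
            rows.append({"subject_id": f"S{i:02d}", "reader": reader,
                         "modality": mod, "score": s})
    return pd.DataFrame(rows)


class TestConcordanceSummary:
    def test_counts_partition_cohort(self):
        conv = [0, 1, 2, 3, 2, 1]
        repro = [0, 2, 2, 1, 2, 1]  # one minor (1->2), one major (3->1)
        table = ScoreTable(_score_frame({(1, "conventional"): conv,
                                         (1, "reprojected"): repro}))
        out = concordance_summary(table, ("conventional", "reprojected"))
        row = out.iloc[0]
        assert row["concordant"] == 4
        assert row["minor_discordant"] == 1
        assert row["major_discordant"] == 1
        assert row[["concordant", "minor_discordant",
                    "major_discordant"]].sum() == 6

    def test_identical_modalities(self):
        scores = [0, 1, 2, 3] * 5
        table = ScoreTable(_score_frame({(1, "conventional"): scores,
                                         (1, "reprojected"): scores}))
        row = concordance_summary(table).iloc[0]
        assert row["concordant"] == 20
        assert row["minor_discordant"] == row["major_discordant"] == 0
        assert row["percent_agreement"] == 100

    def test_single_unit_shift_is_minor(self):
        conv = [0] * 30
        repro = [0] * 30
        repro[7] = 1
        table = ScoreTable(_score_frame({(3, "conventional"): conv,
                                         (3, "reprojected"): repro}))
        row = concordance_summary(table).iloc[0]
        assert row["minor_discordant"] == 1
        assert row["percent_agreement"] == 97
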