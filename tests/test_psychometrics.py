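"""Internal consistency, discrimination, weights and staged refinement."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ppidqol as pq
from conftest import random_score_matrix


def alpha_covariance_oracle(scores: pd.DataFrame) -> float:
    """Independent route to alpha via the covariance matrix:
    k/(k-1) * (1 - trace(C) / sum(C))."""
    c = np.cov(np.asarray(scores, dtype=float), rowvar=False, ddof=1)
    k = c.shape[0]
    return k / (k - 1) * (1.0 - np.trace(c) / c.sum())


def tau_c_bruteforce(a, b) -> float:
    """O(n^2) concordance count for Stuart's tau-c on a 2-row table."""
    x = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    y = np.concatenate([a, b]).astype(float)
    n = x.size
    p = q = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                p += 1
            elif s < 0:
                q += 1
    m = min(2, np.unique(y).size)
    return (p - q) * 2 * m / (n**2 * (m - 1))


class TestCronbachAlpha:
    def test_matches_covariance_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = random_score_matrix(rng, rng.integers(5, 21), rng.integers(2, 7))
            if m.sum(axis=1).var(ddof=1) == 0:
                continue
            assert pq.cronbach_alpha(m) == pytest.approx(
                alpha_covariance_oracle(m), abs=1e-10
            )

    def test_identical_columns_give_alpha_one(self):
        col = np.array([0, 1, 2, 3, 1, 2], dtype=float)
        m = pd.DataFrame({f"i{j}": col for j in range(4)})
        assert pq.cronbach_alpha(m) == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_two_item_closed_form(self, rho):
        # for k=2 equal-variance items, alpha -> 2*rho/(1+rho)
        rng = np.random.default_rng(2024)
        n = 200_000
        cov = [[1, rho], [rho, 1]]
        m = pd.DataFrame(rng.multivariate_normal([0, 0], cov, size=n), columns=["a", "b"])
        assert pq.cronbach_alpha(m) == pytest.approx(2 * rho / (1 + rho), abs=0.02)

    def test_independent_items_give_alpha_near_zero(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.standard_normal((10_000, 5)))
        assert pq.cronbach_alpha(m) == pytest.approx(0.0, abs=0.05)

    def test_zero_total_variance_is_an_error(self):
        m = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [2.0, 2, 2, 2]})
        with pytest.raises(pq.DegenerateDataError, match="variance"):
            pq.cronbach_alpha(m)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        m = random_score_matrix(rng, 40, 5)
        expected = pingouin.cronbach_alpha(data=m)[0]
        assert pq.cronbach_alpha(m) == pytest.approx(expected, abs=1e-10)


class TestItemTotalCorrelations:
    def test_two_item_matrix_reduces_to_pairwise_pearson(self):
        rng = np.random.default_rng(3)
        m = random_score_matrix(rng, 50, 2)
        r = pq.item_total_correlations(m)
        expected = np.corrcoef(m.iloc[:, 0], m.iloc[:, 1])[0, 1]
        assert r.iloc[0] == pytest.approx(expected)
        assert r.iloc[1] == pytest.approx(expected)

    def test_item_equal_to_sum_of_rest_gives_one(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.standard_normal((30, 3)), columns=["a", "b", "c"])
        m["total_copy"] = m.sum(axis=1)
        assert pq.item_total_correlations(m)["total_copy"] == pytest.approx(1.0)

    def test_independent_item_near_zero(self):
        rng = np.random.default_rng(6)
        shared = rng.standard_normal(20_000)
        m = pd.DataFrame(
            {
                "a": shared + rng.standard_normal(20_000),
                "b": shared + rng.standard_normal(20_000),
                "noise": rng.standard_normal(20_000),
            }
        )
        assert pq.item_total_correlations(m)["noise"] == pytest.approx(0.0, abs=0.03)

    def test_zero_variance_item_flagged_nan(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [0.0, 0, 0, 0], "c": [2.0, 1, 4, 3]})
        with pytest.warns(UserWarning, match="zero variance"):
            r = pq.item_total_correlations(m)
        assert np.isnan(r["b"])


class TestInterItemMatrix:
    def test_identical_and_anticorrelated_columns(self):
        x = np.array([0.0, 1, 2, 3, 2])
        m = pd.DataFrame({"a": x, "b": x, "c": 3 - x})
        corr = pq.inter_item_matrix(m)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.standard_normal((20_000, 3)), columns=list("abc"))
        corr = pq.inter_item_matrix(m)
        off = corr.values[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.03


class TestChi2Discrimination:
    def test_identical_distributions_give_zero(self):
        responses = [0, 1, 2, 3] * 10
        group = (["ppid"] * 4 + ["non-ppid"] * 4) * 5
        res = pq.chi2_discrimination(responses, group)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.retain()

    def test_perfect_separation_2x2(self):
        # [[10, 0], [0, 10]]: expected counts all 5; Pearson chi2 = 20, df 1
        responses = [0] * 10 + [1] * 10
        group = ["ppid"] * 10 + ["non-ppid"] * 10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pq.chi2_discrimination(responses, group)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1
        assert res.p_value < 0.001
        assert res.retain()

    def test_matches_bruteforce_expected_counts_on_table_set(self):
        rng = np.random.default_rng(12)
        for rows in (2, 3, 4):
            for cols in (2, 3, 4, 5):
                table = rng.integers(3, 30, size=(rows, cols))
                responses = np.repeat(
                    np.tile(np.arange(cols), rows), table.ravel()
                )
                group = np.repeat(np.arange(rows), table.sum(axis=1))
                res = pq.chi2_discrimination(group, responses)
                expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
                stat = ((table - expected) ** 2 / expected).sum()
                assert res.statistic == pytest.approx(stat, rel=1e-10)
                assert res.df == (rows - 1) * (cols - 1)

    def test_single_category_flagged_undefined(self):
        res = pq.chi2_discrimination([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert res.undefined
        assert not res.retain()

    def test_low_expected_counts_warn_without_collapsing(self):
        responses = [0] * 18 + [1, 2] + [0] * 17 + [1, 1, 2]
        group = ["ppid"] * 20 + ["non-ppid"] * 20
        with pytest.warns(UserWarning, match="expected counts"):
            res = pq.chi2_discrimination(responses, group)
        assert res.low_expected
        assert res.df == 2  # 3 response categories kept

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(77)
        probs = [0.55, 0.25, 0.13, 0.07]
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.choice(4, size=150, p=probs)
            b = rng.choice(4, size=150, p=probs)
            res = pq.chi2_discrimination(
                np.concatenate([a, b]), ["p"] * 150 + ["n"] * 150
            )
            rejections += res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)


class TestDomainWeights:
    def test_simple_median(self):
        w = pq.compute_domain_weights(
            {d: [5, 5, 4, 3, 5] for d in pq.DOMAINS}
        )
        assert all(w[d] == 5 for d in pq.DOMAINS)

    def test_even_n_midpoint_rounds_half_up(self):
        w = pq.compute_domain_weights({d: [3, 5] for d in pq.DOMAINS})
        assert w["health"] == 4
        w2 = pq.compute_domain_weights({d: [4, 5] for d in pq.DOMAINS})
        assert w2["health"] == 5  # midpoint 4.5 rounds up

    def test_reproduces_published_weight_profile(self):
        # rating vectors whose medians equal the published PPID-owner values
        ratings = {
            "demeanour": [5, 5, 5, 4, 5],
            "appearance": [4, 3, 5, 4, 4],
            "condition": [4, 3, 5, 4, 4],
            "health": [5, 5, 5, 5, 4],
            "appetite": [5, 4, 5, 5, 4],
            "ingestion": [5, 4, 5, 5, 4],
            "management": [5, 4, 5, 5, 4],
        }
        w = pq.compute_domain_weights(ratings)
        assert w.as_dict() == {
            "demeanour": 5,
            "appearance": 4,
            "condition": 4,
            "health": 5,
            "appetite": 5,
            "ingestion": 5,
            "management": 5,
        }

    def test_empty_ratings_error(self):
        ratings = {d: [3] for d in pq.DOMAINS}
        ratings["health"] = []
        with pytest.raises(pq.DegenerateDataError, match="health"):
            pq.compute_domain_weights(ratings)

    def test_out_of_scale_rating_rejected(self):
        ratings = {d: [3] for d in pq.DOMAINS}
        ratings["health"] = [6]
        with pytest.raises(ValueError, match="1..5"):
            pq.compute_domain_weights(ratings)


class TestRefinement:
    def _planted_run(self, seed=0):
        bank = pq.planted_bank()
        cohort = pq.simulate_cohort(pq.planted_bank_params(), seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bank, pq.refine_items(bank, cohort.score_matrix(bank), cohort.group)

    def test_planted_nondiscriminating_items_dropped_in_stage_one(self):
        _, report = self._planted_run()
        stage1_drops = {
            s.items[0]
            for s in report.steps
            if s.action == "drop-nondiscriminating"
        }
        assert {"pl11", "pl12"} <= stage1_drops

    def test_planted_redundant_pair_merged(self):
        _, report = self._planted_run()
        merges = [s for s in report.steps if s.action == "merge-redundant"]
        assert any(set(s.items) == {"pl1", "pl2"} for s in merges)
        assert all(s.statistic["r"] > 0.6 for s in merges)

    def test_planted_noise_item_pruned_with_alpha_increase(self):
        _, report = self._planted_run()
        prunes = [s for s in report.steps if s.action == "drop-low-item-total"]
        assert any(s.items == ("pl10",) for s in prunes)
        for s in prunes:
            assert s.alpha_after > s.alpha_before

    def test_prune_choice_matches_bruteforce_alpha_recomputation(self):
        bank = pq.planted_bank()
        cohort = pq.simulate_cohort(pq.planted_bank_params(), seed=1)
        scores = cohort.score_matrix(bank)
        ppid = scores.loc[cohort.group == "ppid"]
        # brute force: among items with corrected r < 0.30, the removal with
        # the best alpha must be the one the pipeline takes first
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = pq.refine_items(bank, scores, cohort.group)
        first_prune = next(
            s for s in report.steps if s.action == "drop-low-item-total"
        )
        survivors = [
            s.items[0] for s in report.steps if s.action == "retain"
        ]
        merged = [c for c in report.retained if "+" in c]
        frame = ppid[[c for c in survivors if c not in ("pl1", "pl2")]].copy()
        for m in merged:
            a, b = m.split("+")
            frame[m] = ppid[[a, b]].max(axis=1)
        r_it = pq.item_total_correlations(frame)
        candidates = [c for c in frame.columns if r_it[c] < 0.30]
        best = max(
            candidates,
            key=lambda c: pq.cronbach_alpha(frame.drop(columns=[c])),
        )
        assert first_prune.items == (best,)

    def test_alpha_trajectory_never_decreases_during_pruning(self):
        for seed in range(5):
            _, report = self._planted_run(seed)
            prune_alphas = [
                (s.alpha_before, s.alpha_after)
                for s in report.steps
                if s.action == "drop-low-item-total"
            ]
            for before, after in prune_alphas:
                assert after >= before

    def test_every_item_has_exactly_one_terminal_disposition(self):
        bank, report = self._planted_run()
        disp = report.dispositions()
        assert set(disp) == set(bank.item_ids)

    def test_final_alpha_meets_adequacy_on_planted_bank(self):
        _, report = self._planted_run()
        assert report.final_alpha > 0.70
        assert report.alpha_adequate

    def test_default_cohort_recovers_published_ledger_shape(
        self, survey37, default_cohort
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = pq.refine_items(
                survey37, default_cohort.score_matrix(survey37), default_cohort.group
            )
        assert len(report.retained) == 24
        assert "svy1+svy2" in report.retained
        disp = report.dispositions()
        for item in ("svy3", "svy4", "svy5", "svy6", "svy7", "svy22", "svy23"):
            assert disp[item] == "drop-nondiscriminating"
        for item in ("svy13", "svy14", "svy24", "svy29", "svy30"):
            assert disp[item] == "drop-low-item-total"

    def test_thresholds_are_configuration_not_constants(self, planted12):
        cohort = pq.simulate_cohort(pq.planted_bank_params(), seed=2)
        scores = cohort.score_matrix(planted12)
        config = pq.RefinementConfig(p_drop=0.5, r_merge=0.99, r_prune=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = pq.refine_items(planted12, scores, cohort.group, config)
        # with a lenient chi-squared filter and a near-impossible merge
        # threshold, the redundant pair must survive unmerged
        assert not any(s.action == "merge-redundant" for s in report.steps)
        assert {"pl1", "pl2"} <= set(report.retained)

    def test_refinement_to_fewer_than_two_items_errors(self, planted12):
        cohort = pq.simulate_cohort(pq.planted_bank_params(), seed=3)
        scores = cohort.score_matrix(planted12)
        rng = np.random.default_rng(0)
        shuffled = scores.copy()
        for c in shuffled.columns:  # destroy all group structure
            shuffled[c] = rng.permutation(shuffled[c].values)
        with pytest.raises((pq.DegenerateDataError, ValueError)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pq.refine_items(planted12, shuffled, cohort.group)

    def test_report_serializes_and_summarizes(self):
        _, report = self._planted_run()
        d = report.to_dict()
        assert d["retained"] and isinstance(d["final_alpha"], float)
        text = report.summary()
        assert "final alpha" in text and "merge-redundant" in text


def test_tau_c_helper_consistency():
    # the brute-force oracle used elsewhere agrees with scipy on a toy case
    a, b = [5, 5, 5], [1, 1, 1]
    assert abs(tau_c_bruteforce(a, b)) == pytest.approx(1.0)
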