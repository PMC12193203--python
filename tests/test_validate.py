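import numpy as np
import pandas as pd
import pytest

from msidiff.synthetic import simulate_ihc, simulate_survival
from msidiff.validate import (
    best_cutoff,
    compare_ihc,
    drug_response_correlation,
    h_score,
    km_estimate,
    logrank,
    paired_t,
    percent_positive_pixels,
    responder_roc,
)


def _areas(rows):
    return pd.DataFrame(rows, columns=["bin0", "bin1", "bin2", "bin3"])


class TestHScore:
    def test_saturated_staining_is_300(self):
        assert h_score(_areas([[0, 0, 0, 1.0]])) == 300.0

    def test_mixed_fractions(self):
        # 20% bin3 + 30% bin2 + 50% bin0 -> 100*(0.6 + 0.2*3) = 120
        assert h_score(_areas([[0.5, 0.0, 0.3, 0.2]])) == pytest.approx(120.0)

    def test_unstained_is_zero(self):
        assert h_score(_areas([[1.0, 0, 0, 0]])) == 0.0

    def test_tissue_value_is_mean_over_areas(self):
        table = _areas([[0, 0, 0, 1.0], [1.0, 0, 0, 0]])
        assert h_score(table) == 150.0

    def test_invalid_fractions_error(self):
        with pytest.raises(ValueError, match="sum"):
            h_score(_areas([[0.5, 0.2, 0.1, 0.1]]))


class TestPercentPositive:
    def test_fraction_of_pixels(self):
        table = pd.DataFrame({"compartment": "stroma", "positive": [3], "total": [12]})
        assert percent_positive_pixels(table, "stroma") == 25.0

    @pytest.mark.parametrize("positive, expected", [(12, 100.0), (0, 0.0)])
    def test_extremes(self, positive, expected):
        table = pd.DataFrame({"compartment": "stroma", "positive": [positive], "total": [12]})
        assert percent_positive_pixels(table, "stroma") == expected

    def test_empty_filter_errors(self):
        table = pd.DataFrame({"compartment": "stroma", "positive": [1], "total": [2]})
        with pytest.raises(ValueError, match="epithelial"):
            percent_positive_pixels(table, "epithelial")


class TestPairedT:
    def test_hand_computed_statistic(self):
        # differences 1, 2, 3: mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        t, df, p = paired_t([0, 0, 0], [1, 2, 3])
        np.testing.assert_allclose(t, 3.4641, atol=1e-4)
        assert df == 2

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1, 2, 3], [2, 3, 4])

    def test_sign_flip_negates_t(self):
        t1, _, p1 = paired_t([0, 0, 0, 0], [1, 3, 2, 5])
        t2, _, p2 = paired_t([1, 3, 2, 5], [0, 0, 0, 0])
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)


class TestCompareIhc:
    def test_planted_shift_recovered_exactly_when_noiseless(self):
        table = simulate_ihc(n_pairs=4, effect=50.0, within_sd=0.0, seed=0)
        epi = table[table["compartment"] == "epithelial"].copy()
        epi["h"] = h_score(epi, per_area=True)
        wide = epi.pivot_table(index=["patient_id", "area_id"], columns="timepoint",
                               values="h")
        np.testing.assert_allclose(wide["relapse"] - wide["diagnosis"], 50.0)

    def test_modes_agree_on_balanced_noisy_data(self):
        table = simulate_ihc(n_pairs=6, effect=60.0, within_sd=10.0, seed=1)
        per_area = compare_ihc(table, value="h_score", mode="per_area")
        per_tissue = compare_ihc(table, value="h_score", mode="per_tissue")
        assert per_area["mean_difference"] == pytest.approx(60.0, abs=15.0)
        assert per_tissue["mean_difference"] == pytest.approx(60.0, abs=15.0)
        assert per_area["p_value"] < 0.01

    def test_stroma_percent_positive(self):
        table = simulate_ihc(n_pairs=4, effect=60.0, within_sd=5.0, seed=2)
        res = compare_ihc(table, value="percent_positive", compartment="stroma")
        assert res["mean_relapse"] > res["mean_diagnosis"]


def _records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        km = km_estimate(_records([1.0, 2.0, 3.0], [1, 1, 1]))
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km["at_risk"], [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(_records([1.0, 2.0, 3.0], [0, 0, 0]))
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_censoring_reduces_later_at_risk_only(self):
        km = km_estimate(_records([1.0, 2.0, 3.0], [1, 0, 1]))
        # survival drops at t=1 and t=3; the censoring at t=2 only shrinks
        # the t=3 risk set
        np.testing.assert_allclose(km["survival"], [2 / 3, 2 / 3, 0.0])
        np.testing.assert_allclose(km["at_risk"], [3, 2, 1])

    def test_nonpositive_time_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            km_estimate(_records([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_null(self):
        a = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        res = logrank(a, a.copy())
        np.testing.assert_allclose(res.chi_square, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.hazard_ratio, 1.0)

    def test_group_swap_inverts_hazard_ratio(self, rng):
        a = _records(rng.exponential(10, 40), np.ones(40, int))
        b = _records(rng.exponential(5, 40), np.ones(40, int))
        r1 = logrank(a, b)
        r2 = logrank(b, a)
        np.testing.assert_allclose(r1.hazard_ratio * r2.hazard_ratio, 1.0, rtol=1e-9)
        np.testing.assert_allclose(r1.chi_square, r2.chi_square, rtol=1e-9)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines.statistics import logrank_test

        a = _records(np.round(rng.exponential(10, 60), 0) + 1, rng.integers(0, 2, 60))
        b = _records(np.round(rng.exponential(6, 50), 0) + 1, rng.integers(0, 2, 50))
        mine = logrank(a, b)
        ref = logrank_test(a["time"], b["time"], a["event"], b["event"])
        np.testing.assert_allclose(mine.chi_square, ref.test_statistic, rtol=1e-6)
        np.testing.assert_allclose(mine.p_value, ref.p_value, rtol=1e-6)

    def test_no_events_errors(self):
        a = _records([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank(a, a.copy())


class TestBestCutoff:
    def test_selects_separating_cutoff(self):
        records = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "time": [10.0, 11.0, 1.0, 2.0],
                "event": [1, 1, 1, 1],
                "marker": [1.0, 2.0, 3.0, 4.0],
            }
        )
        res = best_cutoff(records, quantile_bounds=(0.0, 1.0), min_group_frac=0.25,
                          n_permutations=0)
        assert 2.0 < res.cutoff <= 3.0
        assert res.n_high == 2 and res.n_low == 2
        assert res.hazard_ratio > 1.0

    def test_multi_probe_marker_is_mean_across_probes(self, rng):
        base = simulate_survival(n=40, true_hr=2.0, seed=5)
        probe_rows = []
        for probe, shift in (("pr1", -1.0), ("pr2", 1.0)):
            sub = base.copy()
            sub["probe_id"] = probe
            sub["marker"] = base["marker"] + shift
            probe_rows.append(sub)
        multi = pd.concat(probe_rows, ignore_index=True)
        res_multi = best_cutoff(multi, n_permutations=0)
        res_mean = best_cutoff(base, n_permutations=0)  # mean of shifts cancels
        np.testing.assert_allclose(res_multi.cutoff, res_mean.cutoff)
        np.testing.assert_allclose(res_multi.p_value, res_mean.p_value)

    def test_adjusted_p_exceeds_naive_under_null(self, rng):
        naive, adjusted = [], []
        for rep in range(15):
            cohort = simulate_survival(n=40, true_hr=1.0, seed=100 + rep)
            cohort["marker"] = rng.permutation(cohort["marker"].to_numpy())
            res = best_cutoff(cohort, n_permutations=99, seed=rep)
            naive.append(res.p_value)
            adjusted.append(res.p_adjusted)
        assert np.mean(adjusted) > np.mean(naive)

    def test_too_few_subjects_errors(self):
        records = pd.DataFrame(
            {"subject_id": ["a"], "time": [1.0], "event": [1], "marker": [1.0]}
        )
        with pytest.raises(ValueError, match="too few"):
            best_cutoff(records)


class TestResponderRoc:
    def test_perfectly_separating_marker(self):
        res, p = responder_roc([5.0, 6.0, 1.0, 2.0], [False, False, True, True])
        assert res.auc == 1.0
        assert res.direction == "higher_in_non_responders"

    def test_worked_auc_example(self):
        res, _ = responder_roc([5, 6, 7, 1, 2, 6],
                               [False, False, False, True, True, True])
        np.testing.assert_allclose(res.auc, 7.5 / 9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both"):
            responder_roc([1.0, 2.0], [True, True])


class TestDrugResponseCorrelation:
    def test_exact_linear_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = drug_response_correlation(x, 2 * x, "pearson")
        np.testing.assert_allclose(r, 1.0)

    def test_reversed_order_spearman(self):
        r, _ = drug_response_correlation([1, 2, 3, 4], [8, 6, 4, 2], "spearman")
        np.testing.assert_allclose(r, -1.0)

    def test_hand_ranked_spearman(self):
        r, p = drug_response_correlation([1, 2, 3], [2, 1, 3], "spearman")
        np.testing.assert_allclose(r, 0.5)
        np.testing.assert_allclose(p, 1.0)  # all 6 rank permutations have |rho| >= 0.5

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            drug_response_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            drug_response_correlation([1.0, 2.0], [1.0, 2.0])
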