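import numpy as np
import pandas as pd
import pytest

from hmcresponse.survival import (cohort_responsiveness, cox_fit,
                                  day_correlation, dose_trend, km_estimate,
                                  logrank_test, median_split,
                                  patient_dhmg_count)
from hmcresponse.io import CountMatrix, SampleSheet
from hmcresponse.synthetic import SimulationConfig, generate_hmc_cohort


class TestKmEstimate:
    def test_hand_example_with_censoring(self):
        km = km_estimate([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(km["survival"],
                                   [2 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_all_censored_flat(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_all_events_distinct_times(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_non_increasing(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rng.exponential(10, 50), rng.integers(0, 2, 50))
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0], [1])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km["time"]).to_numpy()
        np.testing.assert_allclose(km["survival"], ref, atol=1e-10)


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        chi2, _ = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(2.8824, abs=1e-3)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 20)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 20)
        chi1, _ = logrank_test(ta, ea, tb, eb)
        chi2, _ = logrank_test(np.sqrt(ta), ea, np.sqrt(tb), eb)
        assert chi1 == pytest.approx(chi2, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(3)
        for _ in range(100):
            na, nb = rng.integers(5, 25, 2)
            ta = rng.exponential(5, na).round(2)
            tb = rng.exponential(9, nb).round(2)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxFit:
    def test_closed_form_three_records(self):
        res = cox_fit([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1, 0, 1]}))
        assert res.table.loc["x", "coef"] == pytest.approx(-np.log(2) / 2,
                                                           abs=1e-6)

    def test_covariate_rescaling(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 30)
        e = np.ones(30, dtype=int)
        x = rng.normal(size=30)
        r1 = cox_fit(t, e, pd.DataFrame({"x": x}))
        r2 = cox_fit(t, e, pd.DataFrame({"x": 2 * x}))
        assert r2.table.loc["x", "coef"] == pytest.approx(
            r1.table.loc["x", "coef"] / 2, abs=1e-8)

    def test_null_coverage(self):
        rng = np.random.default_rng(5)
        inside = 0
        n_rep = 50
        for _ in range(n_rep):
            t = rng.exponential(5, 200)
            e = (rng.uniform(size=200) < 0.8).astype(int)
            x = rng.normal(size=200)
            res = cox_fit(t, e, pd.DataFrame({"x": x}))
            if abs(res.table.loc["x", "coef"]) < 2 * res.table.loc["x", "se"]:
                inside += 1
        assert inside >= 0.9 * n_rep

    def test_matches_lifelines_breslow(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(6)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.exp(-0.5 * x1), n)   # continuous: no ties,
        e = (rng.uniform(size=n) < 0.8).astype(int)  # Breslow == Efron
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        mine = cox_fit(t, e, df[["x1", "x2"]])
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(mine.table["coef"],
                                   cph.params_[["x1", "x2"]], atol=1e-5)

    def test_perfect_separation_detected(self):
        # covariate perfectly ordered with event times -> monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="divergence|separation"):
            cox_fit(t, e, pd.DataFrame({"x": x}))


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(pd.Series([1.0, 2, 3, 4],
                                        index=list("abcd")))
        assert labels.loc[["a", "b"]].tolist() == ["low", "low"]
        assert labels.loc[["c", "d"]].tolist() == ["high", "high"]

    def test_ties_go_low(self):
        labels = median_split(pd.Series([1.0, 2, 2, 9], index=list("abcd")))
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_odd_n(self):
        labels = median_split(pd.Series([1.0, 2, 3], index=list("abc")))
        assert labels.tolist() == ["low", "low", "high"]

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            median_split(pd.Series([2.0, 2.0], index=["a", "b"]))


class TestResponsivenessStats:
    def test_identical_days_zero_dhmgs(self):
        rng = np.random.default_rng(7)
        mat = rng.negative_binomial(10, 0.05, size=(300, 2))
        cols = ["P1_BM_D0", "P1_PB_D0", "P1_BM_D5", "P1_PB_D5"]
        values = pd.DataFrame(np.hstack([mat, mat]), columns=cols,
                              index=[f"g{i}" for i in range(300)])
        sheet = SampleSheet(pd.DataFrame([
            dict(sample_id=c, patient_id="P1", tissue=c.split("_")[1],
                 day=int(c.split("_D")[1]), dose_mg_m2=50.0, response="CR",
                 os_time=100.0, os_event=0, age=50.0, sex="F")
            for c in cols]))
        counts = CountMatrix(values)
        assert patient_dhmg_count(counts, sheet, "P1") == 0
        assert day_correlation(counts, sheet, "P1") == pytest.approx(1.0)

    def test_missing_day_named(self, hmc_cohort):
        counts, sheet, _ = hmc_cohort
        day0_only = sheet.data[sheet.data["day"] == 0]
        sub_sheet = SampleSheet(day0_only.copy())
        sub = counts.subset_samples(sub_sheet.sample_ids)
        with pytest.raises(ValueError, match="P000"):
            patient_dhmg_count(sub, sub_sheet, "P000")

    def test_spearman_matches_rank_then_pearson(self):
        rng = np.random.default_rng(8)
        from scipy.stats import rankdata
        for _ in range(50):
            x, y = rng.normal(size=(2, 60))
            rx, ry = rankdata(x), rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            from scipy.stats import spearmanr
            assert spearmanr(x, y).statistic == pytest.approx(expected,
                                                              abs=1e-12)

    def test_rank_reversal_gives_minus_one(self, hmc_cohort):
        counts, sheet, _ = hmc_cohort
        patient = sheet.patients[0]
        day0 = sheet.samples_for(patient, tissue="BM", day=0)
        sub = counts.values[day0[0]]
        flipped = pd.DataFrame({
            day0[0]: sub.to_numpy(),
            "fake_d5": sub.max() - sub.to_numpy() + 1})
        from scipy.stats import spearmanr
        rho = spearmanr(flipped.iloc[:, 0], flipped.iloc[:, 1]).statistic
        assert rho == pytest.approx(-1.0)


class TestDoseTrend:
    def test_identical_patients_p_one(self):
        table = pd.DataFrame({
            "value": [5.0, 5.0, 5.0, 5.0],
            "dose_mg_m2": [37.5, 37.5, 75.0, 75.0]},
            index=["p1", "p2", "p3", "p4"])
        out = dose_trend(table)
        assert out["pairwise_p"]["37.5_vs_75"] == 1.0

    def test_single_dose_rejected(self):
        table = pd.DataFrame({"value": [1.0, 2.0],
                              "dose_mg_m2": [50.0, 50.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="dose groups"):
            dose_trend(table)

    def test_planted_dose_effect_monotone(self):
        cfg = SimulationConfig(n_patients=30, n_genes=1000, seed=21)
        hmc, sheet, _ = generate_hmc_cohort(cfg)
        table = cohort_responsiveness(hmc, sheet, stat="dhmg")
        out = dose_trend(table)
        meds = [out["median_by_dose"][d] for d in ("37.5", "50", "75")]
        assert meds[0] < meds[2]
        assert out["monotone_increasing"]
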