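"""Diagnostic (AUC) and prognostic (Cox / KM / log-rank / HR) validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reporternet import synthetic, validation
from reporternet.datasets import ExpressionDataset, SurvivalTable


def pairwise_auc(scores, labels):
    """Enumeration oracle: concordant pairs + half ties over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    num = 0.0
    n = 0
    for i, j in itertools.product(np.flatnonzero(labels), np.flatnonzero(~labels)):
        n += 1
        if scores[i] > scores[j]:
            num += 1.0
        elif scores[i] == scores[j]:
            num += 0.5
    return num / n


class TestAUC:
    def test_hand_example(self):
        # cases {3,1}, controls {2,0}: 3 of 4 pairs concordant
        assert validation.auc([3, 1, 2, 0], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert validation.auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert validation.auc([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            validation.auc([1, 2], [1, 1])

    def test_matches_enumeration_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 6, n).astype(float)  # integer scores force ties
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert validation.auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels)
            )

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=20))
    def test_invariant_under_monotone_transform(self, raw):
        # round so the transform stays strictly monotone in float arithmetic
        scores = np.round(np.asarray(raw), 2)
        labels = np.arange(scores.size) % 2 == 0
        a1 = validation.auc(scores, labels)
        a2 = validation.auc(np.exp(scores / 2.0), labels)
        assert a1 == pytest.approx(a2)


class TestScreenDiagnostic:
    def test_planted_shift_flagged(self):
        for seed in range(3):
            ds, _ = synthetic.generate_expression(
                20, 100, 30, 0.0, 0.0, 0.5, seed=seed, name="val"
            )
            vals = ds.values.copy()
            vals.loc["G0001", ds.case_samples] += 1.0  # 2 sd at noise_sd=0.5
            shifted = ExpressionDataset(vals, ds.labels, "val")
            table = validation.screen_diagnostic(shifted, set(ds.genes))
            assert table.loc["G0001", "auc"] >= 0.9
            assert table.loc["G0001", "diagnostic_flag"]
            null_aucs = table.drop("G0001")["auc"]
            assert (~table.drop("G0001")["diagnostic_flag"]).mean() > 0.9
            assert null_aucs.median() < 0.65

    def test_down_markers_orientation_maximized(self, rng):
        genes = ["g1"]
        vals = pd.DataFrame(
            [np.r_[rng.normal(-2, 0.3, 50), rng.normal(2, 0.3, 20)]],
            index=genes,
            columns=[f"s{i}" for i in range(70)],
        )
        labels = pd.Series(["case"] * 50 + ["control"] * 20, index=vals.columns)
        table = validation.screen_diagnostic(ExpressionDataset(vals, labels), {"g1"})
        assert table.loc["g1", "auc"] > 0.95
        assert table.loc["g1", "orientation"] == "-"

    def test_unattainable_threshold_flags_nothing(self, small_bundle):
        table = validation.screen_diagnostic(
            small_bundle.validation, set(small_bundle.validation.genes), threshold=1.01
        )
        assert not table["diagnostic_flag"].any()

    def test_no_measured_candidates_errors(self, small_bundle):
        with pytest.raises(ValueError):
            validation.screen_diagnostic(small_bundle.validation, {"absent"})


class TestCox:
    @staticmethod
    def _grid_loglik(x, t, e, beta):
        ll = 0.0
        for i in range(len(t)):
            if e[i]:
                ll += beta * x[i] - np.log(np.exp(beta * x[t >= t[i]]).sum())
        return ll

    def test_newton_matches_grid_search_oracle(self, rng):
        x = rng.standard_normal(120)
        t = rng.exponential(1000 * np.exp(-x))
        e = (rng.uniform(0, 1, 120) < 0.7).astype(int)
        beta = validation.fit_univariate_cox(x, t, e)
        grid = np.linspace(beta - 0.5, beta + 0.5, 2001)
        lls = [self._grid_loglik(x, t, e, b) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - beta) < 1e-3

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        x = rng.standard_normal(100)
        t = rng.exponential(500 * np.exp(-0.8 * x))
        e = np.ones(100, int)  # no ties, no censoring: Breslow == Efron
        beta = validation.fit_univariate_cox(x, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e")
        assert beta == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_covariate_negation_flips_sign(self, rng):
        x = rng.standard_normal(80)
        t = rng.exponential(100 * np.exp(-x))
        e = np.ones(80, int)
        b1 = validation.fit_univariate_cox(x, t, e)
        b2 = validation.fit_univariate_cox(-x, t, e)
        assert b1 == pytest.approx(-b2, abs=1e-8)

    def test_recovers_planted_coefficient(self):
        """beta_hat within +/-0.2 of beta=1 in >= 90% of replicates at n=300."""
        ok = 0
        n_rep = 25
        for seed in range(n_rep):
            ds, _ = synthetic.generate_expression(5, 150, 150, 0.0, 0.0, 0.5, seed=seed)
            surv = synthetic.generate_survival(
                ds, {"G0001": 1.0}, 1 / 1000, 2000, seed=1000 + seed
            )
            x = ds.values.loc["G0001"].to_numpy()
            x = (x - x.mean()) / x.std(ddof=1)
            beta = validation.fit_univariate_cox(
                x, surv.time.to_numpy(), surv.event.to_numpy()
            )
            ok += 0.8 <= beta <= 1.2
        assert ok / n_rep >= 0.9

    def test_null_covariate_centered_at_zero(self, rng):
        betas = []
        for _ in range(30):
            x = rng.standard_normal(100)
            t = rng.exponential(100, 100)
            e = np.ones(100, int)
            betas.append(validation.fit_univariate_cox(x, t, e))
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 0.1
        assert 0.2 < (betas > 0).mean() < 0.8

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="no events"):
            validation.fit_univariate_cox([1, 2, 3], [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="constant"):
            validation.fit_univariate_cox([1, 1, 1], [1, 2, 3], [1, 1, 1])


class TestRiskSplit:
    def test_even_split(self):
        pi = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        groups = validation.split_risk_groups(pi)
        assert set(groups[groups == "high"].index) == {"c", "d"}

    def test_all_equal_goes_low(self):
        pi = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        assert (validation.split_risk_groups(pi) == "low").all()

    def test_odd_sizes_differ_by_one(self, rng):
        pi = pd.Series(rng.standard_normal(11))
        counts = validation.split_risk_groups(pi).value_counts()
        assert abs(counts["high"] - counts["low"]) == 1


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        surv = SurvivalTable(
            pd.Series([5.0, 8.0, 2.0], index=list("abc")),
            pd.Series([0, 0, 0], index=list("abc")),
        )
        km = validation.kaplan_meier(surv)
        assert (km["survival"] == 1.0).all()

    def test_all_events_empirical_survival(self):
        surv = SurvivalTable(
            pd.Series([1.0, 2.0, 3.0], index=list("abc")),
            pd.Series([1, 1, 1], index=list("abc")),
        )
        km = validation.kaplan_meier(surv).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_matches_hand_product_limit_with_censoring(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        surv = SurvivalTable(
            pd.Series(times, index=[f"s{i}" for i in range(10)]),
            pd.Series(events, index=[f"s{i}" for i in range(10)]),
        )
        km = validation.kaplan_meier(surv).set_index("time")["survival"]
        # hand product-limit: t=1 (10 at risk, 1 death) -> 9/10; t=2 (9,1) ->
        # 9/10*8/9; t=3 (7,1) -> *6/7; t=5 (5,2) -> *3/5; t=7 (2,1) -> *1/2
        assert km.loc[1.0] == pytest.approx(0.9)
        assert km.loc[2.0] == pytest.approx(0.8)
        assert km.loc[3.0] == pytest.approx(0.8 * 6 / 7)
        assert km.loc[5.0] == pytest.approx(0.8 * 6 / 7 * 3 / 5)
        assert km.loc[7.0] == pytest.approx(0.8 * 6 / 7 * 3 / 5 * 0.5)


def test_km_plot_written(tmp_path):
    idx = [f"s{i}" for i in range(8)]
    high = SurvivalTable(pd.Series([1.0, 2, 3, 4], index=idx[:4]),
                         pd.Series([1, 1, 1, 0], index=idx[:4]))
    low = SurvivalTable(pd.Series([5.0, 6, 7, 8], index=idx[4:]),
                        pd.Series([1, 0, 1, 0], index=idx[4:]))
    out = tmp_path / "km.png"
    validation.plot_kaplan_meier(high, low, out, title="toy")
    assert out.stat().st_size > 0


class TestLogrank:
    def test_hand_accumulation_example(self):
        res = validation.logrank([1, 2], [1, 1], [3, 4], [1, 0])
        assert res.o1 == 2 and res.o2 == 1
        assert res.e1 == pytest.approx(5 / 6)
        assert res.e2 == pytest.approx(13 / 6)
        assert res.hr == pytest.approx(5.2)

    def test_event_conservation(self, rng):
        t1 = rng.exponential(10, 30)
        t2 = rng.exponential(15, 25)
        e1 = (rng.uniform(size=30) < 0.7).astype(int)
        e2 = (rng.uniform(size=25) < 0.7).astype(int)
        res = validation.logrank(t1, e1, t2, e2)
        assert res.o1 + res.o2 == pytest.approx(e1.sum() + e2.sum())
        assert res.e1 + res.e2 == pytest.approx(e1.sum() + e2.sum())

    def test_exchangeable_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 0]
        res = validation.logrank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)

    def test_group_relabeling_swaps_and_inverts(self, rng):
        t1 = rng.exponential(10, 20)
        t2 = rng.exponential(20, 20)
        e = np.ones(20, int)
        a = validation.logrank(t1, e, t2, e)
        b = validation.logrank(t2, e, t1, e)
        assert a.o1 == b.o2
        assert a.e1 == pytest.approx(b.e2, rel=1e-12)
        assert a.hr == pytest.approx(1.0 / b.hr)
        assert a.p == pytest.approx(b.p)

    def test_matches_lifelines_statistic(self, rng):
        from lifelines.statistics import logrank_test

        t1 = rng.exponential(10, 40)
        t2 = rng.exponential(18, 35)
        e1 = (rng.uniform(size=40) < 0.8).astype(int)
        e2 = (rng.uniform(size=35) < 0.8).astype(int)
        res = validation.logrank(t1, e1, t2, e2)
        ref = logrank_test(t1, t2, e1, e2)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_hr_consistent_with_cox_estimate(self, rng):
        """O/E hazard ratio tracks exp(two-group Cox beta) within 15%."""
        n = 260
        grp = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = rng.exponential(1000 * np.exp(-0.8 * grp))
        c = rng.uniform(0, 2000, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        assert event.sum() >= 100
        res = validation.logrank(time[grp == 1], event[grp == 1],
                                 time[grp == 0], event[grp == 0])
        beta = validation.fit_univariate_cox(grp, time, event)
        assert res.hr == pytest.approx(np.exp(beta), rel=0.15)

    def test_null_p_uniform(self):
        """Log-rank p-values are uniform under exchangeable survival."""
        from scipy import stats

        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            t = rng.exponential(10, 40)
            e = (rng.uniform(size=40) < 0.8).astype(int)
            half = rng.permutation(40) < 20
            pvals.append(validation.logrank(t[half], e[half], t[~half], e[~half]).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScreenPrognostic:
    def test_planted_gene_flagged_with_high_hr(self):
        flagged = 0
        n_rep = 10
        for seed in range(n_rep):
            ds, _ = synthetic.generate_expression(10, 150, 150, 0.0, 0.0, 0.5, seed=seed)
            surv = synthetic.generate_survival(
                ds, {"G0001": 1.0}, 1 / 1000, 2000, seed=500 + seed
            )
            table = validation.screen_prognostic(ds, surv, {"G0001"})
            row = table.loc["G0001"]
            flagged += bool(row["prognostic_flag"] and row["hr"] > 1)
        assert flagged / n_rep >= 0.9

    def test_null_type_one_error_calibrated(self):
        ds, _ = synthetic.generate_expression(400, 150, 150, 0.0, 0.0, 0.5, seed=3)
        surv = synthetic.generate_survival(ds, {}, 1 / 1000, 2000, seed=4)
        table = validation.screen_prognostic(ds, surv, set(ds.genes))
        rate = table["prognostic_flag"].mean()
        assert abs(rate - 0.05) < 0.03

    def test_absent_candidate_yields_na_row(self, small_bundle):
        table = validation.screen_prognostic(
            small_bundle.validation, small_bundle.survival, {"G0001", "missing_gene"}
        )
        assert np.isnan(table.loc["missing_gene", "beta"])
        assert not table.loc["missing_gene", "prognostic_flag"]

    def test_event_conservation_every_row(self, small_bundle):
        genes = list(small_bundle.validation.genes[:10])
        table = validation.screen_prognostic(
            small_bundle.validation, small_bundle.survival, genes
        )
        total = small_bundle.survival.event.sum()
        fitted = table.dropna(subset=["beta"])
        assert np.allclose(fitted["o1"] + fitted["o2"], total)
        assert np.allclose(fitted["e1"] + fitted["e2"], total)
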