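"""Episode splitting, Cox fitting, AIC comparison, KM and odds ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from camokit import (
    EXP2_CUTPOINTS,
    TrialOutcome,
    ValidationError,
    compare_aic,
    distance_quartile_strata,
    episodes_to_frame,
    fit_cox,
    hits_timeouts_table,
    km_estimate,
    odds_ratio,
    split_episodes,
)
from camokit.errors import ModelSpecError


def outcome(play="p0", idx=1, cond="50", time=3.0, event=1, dist=100.0, **kw):
    return TrialOutcome(
        play_id=play,
        trial_index=idx,
        condition=cond,
        time=time,
        event=event,
        distance=dist,
        **kw,
    )


class TestSplitEpisodes:
    def test_hit_spanning_all_phases(self):
        eps = split_episodes([outcome(time=3.0)], (1.5, 2.5))
        got = [(e.tstart, e.tstop, e.event, e.period_index) for e in eps]
        assert got == [(0.0, 1.5, 0, 0), (1.5, 2.5, 0, 1), (2.5, 3.0, 1, 2)]

    def test_hit_before_first_cut_single_episode(self):
        eps = split_episodes([outcome(time=1.0)], (1.5, 2.5))
        assert [(e.tstart, e.tstop, e.event) for e in eps] == [(0.0, 1.0, 1)]

    def test_timeout_under_six_phase_cuts(self):
        eps = split_episodes([outcome(time=15.0, event=0)], EXP2_CUTPOINTS)
        assert len(eps) == 6
        assert all(e.event == 0 for e in eps)
        assert [e.period_index for e in eps] == list(range(6))

    def test_exposure_and_events_conserved_exactly(self, rng):
        outs = [
            outcome(
                play=f"p{i % 7}",
                idx=i,
                time=float(t),
                event=int(ev),
            )
            for i, (t, ev) in enumerate(
                zip(
                    np.round(rng.uniform(0.05, 15.0, 200), 4),
                    rng.integers(0, 2, 200),
                )
            )
        ]
        for o in outs:
            if o.event == 0:
                o.time = 15.0
        eps = split_episodes(outs, (0.6, 1.2, 1.4, 2.0, 10.5))
        exposure = sum(e.tstop - e.tstart for e in eps)
        assert exposure == pytest.approx(sum(o.time for o in outs), abs=1e-9)
        assert sum(e.event for e in eps) == sum(o.event for o in outs)
        # episodes of one outcome tile (0, time] without gaps
        frame = episodes_to_frame(eps)
        for (pid, idx), g in frame.groupby(["play_id", "trial_index"]):
            g = g.sort_values("tstart")
            assert g.iloc[0]["tstart"] == 0.0
            assert np.allclose(g["tstop"].to_numpy()[:-1], g["tstart"].to_numpy()[1:])

    def test_non_monotone_cuts_raise(self):
        with pytest.raises(ValidationError):
            split_episodes([outcome()], (2.5, 1.5))


def brute_force_breslow(df, covs):
    """Independent oracle: direct maximization of the written-out Breslow
    partial likelihood with a generic optimizer."""
    X = df[covs].to_numpy(float)
    ts = df["tstart"].to_numpy(float)
    te = df["tstop"].to_numpy(float)
    ev = df["event"].to_numpy(int)

    def nll(beta):
        eta = X @ beta
        ll = 0.0
        for i in np.flatnonzero(ev):
            risk = (ts < te[i]) & (te[i] <= te)
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
        return -ll

    res = minimize(
        nll,
        np.zeros(len(covs)),
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-13, maxiter=20000),
    )
    return res.x, -res.fun


class TestFitCox:
    def small_df(self):
        return pd.DataFrame(
            dict(
                play_id=[f"p{i}" for i in range(6)],
                tstart=[0.0, 0.0, 0.0, 0.0, 1.0, 0.5],
                tstop=[1.2, 2.4, 3.1, 0.9, 2.0, 4.0],
                event=[1, 1, 0, 1, 1, 1],
                x1=[0.5, -1.0, 0.2, 1.5, -0.3, 0.8],
                x2=[1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            )
        )

    def test_matches_brute_force_oracle(self):
        df = self.small_df()
        fit = fit_cox(df, ["x1", "x2"])
        beta, ll = brute_force_breslow(df, ["x1", "x2"])
        assert fit.coefficients["x1"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.coefficients["x2"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(ll, abs=1e-8)
        assert fit.aic == pytest.approx(-2 * ll + 4, abs=1e-6)

    def test_null_covariate_pinned_at_zero(self):
        df = self.small_df()
        df["z"] = 0.0
        fit = fit_cox(df, ["z"])
        null_ll = fit_cox(df.assign(one=1.0), ["one"]).log_partial_likelihood
        assert fit.coefficients["z"] == 0.0
        assert fit.robust_se["z"] == math.inf
        assert fit.log_partial_likelihood == pytest.approx(null_ll, abs=1e-9)
        assert "z" in fit.pinned

    def test_two_group_simulation_recovers_hr2(self):
        r = np.random.default_rng(99)
        n = 2000
        g = np.repeat([0.0, 1.0], n // 2)
        t = r.exponential(1.0 / (0.5 * 2.0**g))
        df = pd.DataFrame(
            dict(
                play_id=np.arange(n).astype(str),
                tstart=0.0,
                tstop=t,
                event=1,
                g=g,
            )
        )
        fit = fit_cox(df, ["g"], concordance=False)
        assert (
            abs(fit.coefficients["g"] - math.log(2.0))
            <= 1.96 * fit.robust_se["g"]
        )

    def test_matches_lifelines_on_episode_data(self, rng):
        from lifelines import CoxTimeVaryingFitter

        n = 300
        df = pd.DataFrame(
            dict(
                id=np.arange(n),
                play_id=np.repeat(np.arange(n // 3), 3).astype(str),
                tstart=0.0,
                x=rng.standard_normal(n),
                g=rng.integers(0, 2, n).astype(float),
            )
        )
        t = rng.exponential(1.0 / (0.3 * np.exp(0.5 * df.x - 0.6 * df.g)))
        df["tstop"] = np.minimum(t, 10.0)
        df["event"] = (t < 10.0).astype(int)
        fit = fit_cox(df, ["x", "g"], concordance=False)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            df[["id", "tstart", "tstop", "event", "x", "g"]],
            id_col="id",
            event_col="event",
            start_col="tstart",
            stop_col="tstop",
        )
        for term in ("x", "g"):
            assert fit.coefficients[term] == pytest.approx(
                ctv.params_[term], abs=1e-6
            )
            assert fit.naive_se[term] == pytest.approx(
                ctv.standard_errors_[term], rel=1e-4
            )

    def test_concordance_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        n = 200
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.3 * np.exp(0.6 * x)))
        df = pd.DataFrame(
            dict(
                play_id=np.arange(n).astype(str),
                tstart=0.0,
                tstop=np.minimum(t, 5.0),
                event=(t < 5.0).astype(int),
                x=x,
            )
        )
        fit = fit_cox(df, ["x"])
        eta = x * fit.coefficients["x"]
        assert fit.concordance == pytest.approx(
            concordance_index(df["tstop"], -eta, df["event"]), abs=1e-12
        )

    def test_stratified_fit_recovers_effect(self, rng):
        """Strata with very different baselines do not bias the shared
        coefficient when the model is stratified."""
        n = 3000
        stratum = rng.integers(0, 4, n)
        base = np.array([0.1, 0.4, 1.0, 3.0])[stratum]
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (base * np.exp(0.5 * x)))
        df = pd.DataFrame(
            dict(
                play_id=np.arange(n).astype(str),
                tstart=0.0,
                tstop=np.minimum(t, 20.0),
                event=(t < 20.0).astype(int),
                x=x,
                s=stratum.astype(str),
            )
        )
        fit = fit_cox(df, ["x"], strata="s", concordance=False)
        assert abs(fit.coefficients["x"] - 0.5) <= 2.5 * fit.robust_se["x"]

    def test_cluster_robust_se_exceeds_naive_under_frailty(self, rng):
        n = 2000
        cl = np.repeat(np.arange(n // 10), 10)
        frail = np.exp(0.8 * rng.standard_normal(n // 10))[cl]
        g = (np.arange(n) % 10 < 5).astype(float)  # varies within cluster
        z = rng.standard_normal(n // 10)[cl]  # cluster-constant covariate
        t = rng.exponential(1.0 / (0.3 * frail * np.exp(0.3 * g + 0.3 * z)))
        df = pd.DataFrame(
            dict(
                play_id=cl.astype(str),
                tstart=0.0,
                tstop=np.minimum(t, 15.0),
                event=(t < 15.0).astype(int),
                g=g,
                z=z,
            )
        )
        fit = fit_cox(df, ["g", "z"], concordance=False)
        assert fit.robust_se["z"] > fit.naive_se["z"]

    def test_rank_deficient_design_raises(self):
        df = self.small_df()
        df["x3"] = 2.0 * df["x1"]
        with pytest.raises(ModelSpecError):
            fit_cox(df, ["x1", "x3"])

    def test_no_events_raises(self):
        df = self.small_df()
        df["event"] = 0
        with pytest.raises(ValidationError):
            fit_cox(df, ["x1"])


class TestCompareAic:
    def test_identical_fits_give_zero(self):
        df = TestFitCox().small_df()
        f1 = fit_cox(df, ["x1"])
        f2 = fit_cox(df, ["x1"])
        assert compare_aic(f1, f2) == 0.0

    def test_different_data_raises(self):
        df = TestFitCox().small_df()
        f1 = fit_cox(df, ["x1"])
        f2 = fit_cox(df.assign(tstop=df.tstop + 0.1), ["x1"])
        with pytest.raises(ValidationError):
            compare_aic(f1, f2)

    def test_pure_noise_term_costs_about_two(self):
        """Adding a noise covariate changes AIC by 2 - chi2(1) on average;
        over 100 simulations the mean lands in [0, 2]."""
        r = np.random.default_rng(17)
        deltas = []
        for _ in range(100):
            n = 120
            t = r.exponential(1.0, n)
            df = pd.DataFrame(
                dict(
                    play_id=np.arange(n).astype(str),
                    tstart=0.0,
                    tstop=t,
                    event=1,
                    noise=r.standard_normal(n),
                )
            )
            full = fit_cox(df, ["noise"], concordance=False)
            null = fit_cox(df.assign(zero=0.0), ["zero"], concordance=False)
            deltas.append(compare_aic(full, null))
        assert 0.0 <= np.mean(deltas) <= 2.0

    def test_strong_effect_favors_full_model(self):
        r = np.random.default_rng(23)
        wins = 0
        reps = 50
        for _ in range(reps):
            n = 400
            g = r.integers(0, 2, n).astype(float)
            t = r.exponential(1.0 / np.exp(0.7 * g))
            df = pd.DataFrame(
                dict(
                    play_id=np.arange(n).astype(str),
                    tstart=0.0,
                    tstop=t,
                    event=1,
                    g=g,
                )
            )
            full = fit_cox(df, ["g"], concordance=False)
            null = fit_cox(df.assign(zero=0.0), ["zero"], concordance=False)
            wins += compare_aic(full, null) < 0
        assert wins >= 0.95 * reps


class TestKaplanMeier:
    def test_no_censoring_matches_one_minus_ecdf(self):
        times = [1.0, 2.0, 3.0, 4.0]
        outs = [outcome(idx=i, time=t) for i, t in enumerate(times)]
        km = km_estimate(outs, "50")
        for t, frac in [(0.0, 1.0), (1.5, 0.75), (2.5, 0.5), (4.0, 0.0)]:
            idx = np.searchsorted(km.times, t, side="right") - 1
            assert km.survival[idx] == pytest.approx(frac)

    def test_all_censored_flat_at_one(self):
        outs = [outcome(idx=i, time=15.0, event=0) for i in range(5)]
        km = km_estimate(outs, "50")
        assert np.allclose(km.survival, 1.0)
        assert list(km.censor_times) == [15.0] * 5

    def test_hand_computed_product_limit(self):
        """times 1, 2+, 3, 4, 5 (one censored): S = 4/5, 8/15, 4/15, 0."""
        data = [(1.0, 1), (2.0, 0), (3.0, 1), (4.0, 1), (5.0, 1)]
        outs = [outcome(idx=i, time=t, event=e) for i, (t, e) in enumerate(data)]
        km = km_estimate(outs, "50")
        expect = {1.0: 4 / 5, 3.0: 8 / 15, 4.0: 4 / 15, 5.0: 0.0}
        for t, s in expect.items():
            idx = np.searchsorted(km.times, t, side="right") - 1
            assert km.survival[idx] == pytest.approx(s)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            km_estimate([outcome()], "75")


class TestOddsRatio:
    def test_worked_example(self):
        res = odds_ratio([[90, 10], [80, 20]])
        assert res.or_value == pytest.approx(2 / 4.5)
        lo, hi = res.ci95
        assert lo < res.or_value < hi
        assert res.p < 0.06

    def test_identical_rows_unity(self):
        res = odds_ratio([[50, 50], [50, 50]])
        assert res.or_value == 1.0
        assert res.chi2 == pytest.approx(0.0)

    def test_row_swap_inverts(self):
        a = odds_ratio([[90, 10], [80, 20]])
        b = odds_ratio([[80, 20], [90, 10]])
        assert a.or_value == pytest.approx(1.0 / b.or_value)

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio([[90, 0], [80, 20]])
        assert res.haldane
        assert math.isfinite(res.or_value) and res.or_value > 0

    def test_negative_counts_raise(self):
        with pytest.raises(ValidationError):
            odds_ratio([[1, -2], [3, 4]])

    def test_table_builder(self):
        outs = [outcome(idx=i, cond="25", event=1) for i in range(3)] + [
            outcome(idx=i, cond="25", event=0, time=15.0) for i in range(2)
        ] + [outcome(idx=i, cond="50", event=1) for i in range(4)]
        tab = hits_timeouts_table(outs, "50", "25")
        assert tab.tolist() == [[4, 0], [3, 2]]


class TestDistanceQuartiles:
    def test_uniform_1_to_100_balanced(self):
        outs = [outcome(idx=i, dist=float(d)) for i, d in enumerate(range(1, 101))]
        lab = distance_quartile_strata(outs)
        counts = pd.Series([o.distance_stratum for o in lab]).value_counts()
        assert counts.to_dict() == {"Q1": 25, "Q2": 25, "Q3": 25, "Q4": 25}

    def test_monotone_relabel_invariance(self, rng):
        d = rng.uniform(10, 500, 80)
        outs1 = [outcome(idx=i, dist=float(x)) for i, x in enumerate(d)]
        outs2 = [outcome(idx=i, dist=float(x**2)) for i, x in enumerate(d)]
        s1 = [o.distance_stratum for o in distance_quartile_strata(outs1)]
        s2 = [o.distance_stratum for o in distance_quartile_strata(outs2)]
        assert s1 == s2

    def test_four_levels_always(self, rng):
        d = rng.uniform(0, 1, 37)
        outs = [outcome(idx=i, dist=float(x)) for i, x in enumerate(d)]
        strata = {o.distance_stratum for o in distance_quartile_strata(outs)}
        assert strata == {"Q1", "Q2", "Q3", "Q4"}

    def test_degenerate_distances_raise(self):
        outs = [outcome(idx=i, dist=5.0) for i in range(10)]
        with pytest.raises(ValidationError):
            distance_quartile_strata(outs)
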