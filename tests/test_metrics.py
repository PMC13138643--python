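"""Evaluation layer vs brute-force oracles and algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crlandmark import (
    aalen_johansen_cif,
    bootstrap_ci,
    brier_cr,
    calibration,
    censoring_km,
    pseudo_obs_cif,
    subgroup_eval,
    timedep_auprc,
    timedep_auroc,
)
from crlandmark.metrics import _case_control_weights


def _censored_instance(n=40, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.exponential(3, n)
    e = rng.integers(0, 3, n)
    s = rng.normal(size=n)
    return t, e, s


class TestAUROC:
    def test_equals_bruteforce_pair_enumeration(self):
        t, e, s = _censored_instance()
        h = 2.0
        G = censoring_km(t, e)
        case, ctrl, w = _case_control_weights(t, e, h, G)
        num = 0.0
        for i in np.flatnonzero(case):
            for j in np.flatnonzero(ctrl):
                c = 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
                num += w[i] * w[j] * c
        brute = num / (w[case].sum() * w[ctrl].sum())
        assert abs(timedep_auroc(t, e, s, h).auc - brute) < 1e-10

    def test_perfect_and_constant_scores(self):
        t = np.array([0.5, 0.8, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 2, 0, 0])
        perfect = np.array([9.0, 8.0, 1.0, 2.0, 1.0, 0.5])
        assert timedep_auroc(t, e, perfect, 2.0).auc == 1.0
        assert timedep_auroc(t, e, np.ones(6), 2.0).auc == 0.5

    def test_deaths_before_horizon_are_controls(self):
        t = np.array([0.5, 1.0, 3.0, 3.5])
        e = np.array([1, 2, 0, 0])
        # the death at t=1 is a control: a score ranking it below the case
        # gives a perfect AUROC
        s = np.array([2.0, 1.0, 0.5, 0.4])
        assert timedep_auroc(t, e, s, 2.0).auc == 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        t, e, s = _censored_instance(seed=seed)
        try:
            a1 = timedep_auroc(t, e, s, 2.0).auc
        except ValueError:
            return  # degenerate draw without cases or controls
        a2 = timedep_auroc(t, e, np.exp(2 * s) + 1, 2.0).auc
        assert abs(a1 - a2) < 1e-12

    def test_matches_sksurv_without_competing_events(self):
        from sksurv.metrics import cumulative_dynamic_auc

        rng = np.random.default_rng(4)
        n = 300
        t = rng.exponential(3, n)
        e = rng.integers(0, 2, n)  # no competing events
        s = -t + rng.normal(0, 1, n)
        h = 2.0
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("event", "?"), ("time", "<f8")])
        ours = timedep_auroc(t, e, s, h).auc
        theirs = cumulative_dynamic_auc(y, y, s, [h])[1]
        assert abs(ours - theirs) < 1e-8

    def test_errors_when_no_cases(self):
        with pytest.raises(ValueError, match="cases"):
            timedep_auroc([5.0, 6.0], [0, 0], [0.1, 0.2], 1.0)


class TestAUPRC:
    def test_equals_bruteforce_threshold_sweep(self):
        t, e, s = _censored_instance()
        h = 2.0
        G = censoring_km(t, e)
        case, ctrl, w = _case_control_weights(t, e, h, G)
        prec, rec = [], []
        for c in np.unique(s)[::-1]:
            tp = w[case & (s >= c)].sum()
            fp = w[ctrl & (s >= c)].sum()
            rec.append(tp / w[case].sum())
            prec.append(tp / (tp + fp) if tp + fp > 0 else 1.0)
        rec, prec = np.array(rec), np.array(prec)
        brute = np.sum(prec * np.diff(np.concatenate([[0.0], rec])))
        assert abs(timedep_auprc(t, e, s, h).auc - brute) < 1e-10

    def test_perfect_and_baseline(self):
        t = np.array([0.5, 0.8, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 2, 0])
        assert timedep_auprc(t, e, np.array([9, 8, 1, 2, 1.0]), 2.0).auc == 1.0
        G = censoring_km(t, e)
        case, ctrl, w = _case_control_weights(t, e, 2.0, G)
        prevalence = w[case].sum() / (w[case].sum() + w[ctrl].sum())
        assert abs(timedep_auprc(t, e, np.ones(5), 2.0).auc - prevalence) < 1e-12


class TestBrier:
    def test_no_censoring_equals_mse(self):
        rng = np.random.default_rng(1)
        n = 50
        t = rng.exponential(2, n)
        e = rng.integers(1, 3, n)  # nobody censored
        p = rng.uniform(size=n)
        h = 1.5
        mse = np.mean((((t <= h) & (e == 1)).astype(float) - p) ** 2)
        assert abs(brier_cr(t, e, p, h) - mse) < 1e-12
        ind = ((t <= h) & (e == 1)).astype(float)
        assert brier_cr(t, e, ind, h) == 0.0

    def test_censored_toy_vs_hand_weighted_sum(self):
        t, e, _ = _censored_instance(n=20, seed=3)
        p = np.linspace(0.05, 0.95, 20)
        h = 2.0
        G = censoring_km(t, e)
        total = 0.0
        for i in range(20):
            y = 1.0 if (t[i] <= h and e[i] == 1) else 0.0
            if t[i] <= h and e[i] != 0:
                w = 1.0 / G.left_limit(t[i])
            elif t[i] > h:
                w = 1.0 / G(h)
            else:
                w = 0.0
            total += w * (y - p[i]) ** 2
        assert abs(brier_cr(t, e, p, h) - total / 20) < 1e-12

    def test_constant_prediction_minimized_at_ipcw_prevalence(self):
        t, e, _ = _censored_instance(n=120, seed=9)
        h = 2.0
        G = censoring_km(t, e)
        case, ctrl, w = _case_control_weights(t, e, h, G)
        prev = w[case].sum() / w.sum()
        grid = np.linspace(0.01, 0.99, 99)
        scores = [brier_cr(t, e, np.full(120, p), h) for p in grid]
        assert abs(grid[int(np.argmin(scores))] - prev) < 0.02


class TestPseudoObservations:
    def test_no_censoring_equals_indicators_exactly(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2, 30)
        e = rng.integers(1, 3, 30)
        po = pseudo_obs_cif(t, e, 1.5)
        assert np.array_equal(po, ((t <= 1.5) & (e == 1)).astype(float))

    def test_mean_identity_always_holds(self):
        t, e, _ = _censored_instance(n=35, seed=5)
        po = pseudo_obs_cif(t, e, 2.0)
        aj = aalen_johansen_cif(t, e, 2.0)
        assert abs(po.mean() - aj) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_matches_naive_leave_one_out(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        t = np.round(rng.exponential(2, n), 1) + 0.1  # induce ties
        e = rng.integers(0, 3, n)
        h = 1.5
        F = aalen_johansen_cif(t, e, h)
        naive = np.empty(n)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            naive[i] = n * F - (n - 1) * aalen_johansen_cif(t[mask], e[mask], h)
        assert np.abs(pseudo_obs_cif(t, e, h) - naive).max() < 1e-10

    def test_aalen_johansen_matches_lifelines(self):
        from lifelines import AalenJohansenFitter

        t, e, _ = _censored_instance(n=60, seed=6)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, e, event_of_interest=1)
        h = 2.0
        theirs = float(ajf.cumulative_density_.iloc[
            np.searchsorted(ajf.cumulative_density_.index.to_numpy(), h,
                            side="right") - 1, 0])
        assert abs(aalen_johansen_cif(t, e, h) - theirs) < 1e-10


class TestCalibration:
    def test_perfect_predictions_give_unit_slope(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(2, 200)
        e = rng.integers(1, 3, 200)
        h = 1.5
        y = ((t <= h) & (e == 1)).astype(float)
        rep = calibration(t, e, y, h, groups=4)
        assert abs(rep.slope - 1.0) < 1e-10
        assert rep.n_groups == 4

    def test_degenerate_predictions_error(self):
        t, e, _ = _censored_instance(n=30, seed=8)
        with pytest.raises(ValueError, match="zero variance"):
            calibration(t, e, np.full(30, 0.2), 2.0)


class TestBootstrap:
    def test_seeded_and_degenerate(self):
        t = np.tile([1.0, 2.0], 30)
        e = np.tile([1, 0], 30)
        s = np.tile([0.9, 0.1], 30)
        metric = lambda tt, ee, ss: timedep_auroc(tt, ee, ss, 1.5).auc
        ci1 = bootstrap_ci(metric, t, e, s, B=100, seed=3)
        ci2 = bootstrap_ci(metric, t, e, s, B=100, seed=3)
        assert ci1 == ci2
        assert ci1 == (1.0, 1.0)  # constant data -> degenerate interval

    def test_coverage_close_to_level(self):
        # scaled-down coverage check of the AUROC percentile interval
        rng = np.random.default_rng(10)
        n, reps, B = 120, 40, 150
        t0 = rng.exponential(3, 40_000)
        e0 = np.where(rng.uniform(size=40_000) < 0.8, 1, 0)
        s0 = -t0 + rng.normal(0, 2.0, 40_000)
        truth = timedep_auroc(t0, e0, s0, 2.0).auc  # population value
        metric = lambda tt, ee, ss: timedep_auroc(tt, ee, ss, 2.0).auc
        hit = 0
        for r in range(reps):
            idx = rng.integers(0, 40_000, n)
            lo, hi = bootstrap_ci(metric, t0[idx], e0[idx], s0[idx],
                                  B=B, level=0.9, seed=r)
            hit += lo <= truth <= hi
        se = np.sqrt(0.9 * 0.1 / reps)
        assert abs(hit / reps - 0.9) < 3 * se + 0.02


class TestSubgroups:
    def test_single_level_equals_overall(self):
        t, e, s = _censored_instance(n=60, seed=11)
        tab = subgroup_eval(t, e, s, np.repeat("all", 60), 2.0)
        assert len(tab) == 1
        assert np.isclose(tab["auroc"][0], timedep_auroc(t, e, s, 2.0).auc)

    def test_pooled_brier_is_weighted_mean_when_G_shared(self):
        t, e, s = _censored_instance(n=80, seed=12)
        p = 1 / (1 + np.exp(-s))
        g = np.where(np.arange(80) < 50, "a", "b")
        G = censoring_km(t, e)  # shared censoring estimate across strata
        h = 2.0
        overall = brier_cr(t, e, p, h, G=G)
        parts = [brier_cr(t[g == lv], e[g == lv], p[g == lv], h, G=G)
                 * (g == lv).sum() for lv in ("a", "b")]
        assert abs(overall - sum(parts) / 80) < 1e-12

    def test_per_stratum_auroc_matches_direct_computation(self):
        t, e, s = _censored_instance(n=80, seed=13)
        g = np.where(s > 0, "hi", "lo")
        tab = subgroup_eval(t, e, s, g, 2.0).set_index("group")
        for lv in ("hi", "lo"):
            m = g == lv
            direct = timedep_auroc(t[m], e[m], s[m], 2.0).auc
            assert np.isclose(tab.loc[lv, "auroc"], direct)
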