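"""Outcome rule exactness, landmark windows, splits, missingness policy."""

import numpy as np
import pandas as pd
import pytest

from crlandmark import (
    RawCohort,
    SimulationConfig,
    build_landmark,
    derive_esrd_outcome,
    fit_missingness_policy,
    simulate_cohort,
    split_cohort,
)
from crlandmark.landmark import LandmarkDataset
from crlandmark.simulate import DAYS_PER_YEAR

IDX = pd.Timestamp("2010-01-01")


def _cohort(labs=None, dx=None, death=None, extra_visit_days=400, n_extra=0):
    """Hand-built single-subject cohort (+ optional filler subjects)."""
    ids = [0] + [100 + k for k in range(n_extra)]
    patients = pd.DataFrame({
        "id": ids,
        "sex": "M",
        "race": "white",
        "ethnicity": "not_hispanic",
        "birth_date": IDX - pd.Timedelta(days=int(60 * DAYS_PER_YEAR)),
        "index_date": IDX,
        "death_date": [death] + [pd.NaT] * n_extra,
    })
    lab_rows = [(0, IDX + pd.Timedelta(days=d), name, v)
                for d, name, v in (labs or [])]
    lab_rows += [(0, IDX + pd.Timedelta(days=extra_visit_days), "sbp", 130.0)]
    for k in range(n_extra):
        lab_rows.append((100 + k, IDX + pd.Timedelta(days=900), "sbp", 120.0))
    labs_df = pd.DataFrame(lab_rows, columns=["id", "date", "name", "value"])
    dx_rows = [(0, IDX + pd.Timedelta(days=d), "esrd") for d in (dx or [])]
    dx_df = pd.DataFrame(dx_rows, columns=["id", "date", "code_group"])
    meds = pd.DataFrame(columns=["id", "date", "class", "days_supply"])
    return RawCohort(patients, labs_df, meds, dx_df)


class TestOutcomeRule:
    def test_consecutive_low_egfr_pair_fires_at_first_measure(self):
        c = _cohort(labs=[(0, "egfr", 14.0), (50, "egfr", 13.0)])
        out = derive_esrd_outcome(c).set_index("id")
        assert out.loc[0, "cause"] == 1
        # event time is the first measure of the pair (day 0 -> clipped > 0)
        assert out.loc[0, "event_time"] < 2 / DAYS_PER_YEAR

    def test_intervening_normal_value_resets_rule(self):
        c = _cohort(labs=[(0, "egfr", 14.0), (20, "egfr", 16.0),
                          (70, "egfr", 14.0)])
        out = derive_esrd_outcome(c).set_index("id")
        assert out.loc[0, "cause"] == 0

    def test_adjacent_pair_under_45_days_does_not_qualify(self):
        c = _cohort(labs=[(0, "egfr", 14.0), (30, "egfr", 13.0)])
        assert derive_esrd_outcome(c).set_index("id").loc[0, "cause"] == 0

    @pytest.mark.parametrize("days, expect_cause", [
        ((100, 480), 0),   # 380 days apart: outside the 45-365 window
        ((100, 300), 1),   # 200 days apart: qualifies
        ((100, 120), 0),   # 20 days apart: too close
        ((100, 130, 300), 1),  # a later entry completes a qualifying pair
    ])
    def test_coded_entry_spacing_window(self, days, expect_cause):
        c = _cohort(dx=list(days))
        out = derive_esrd_outcome(c).set_index("id")
        assert out.loc[0, "cause"] == expect_cause
        if expect_cause == 1:
            assert np.isclose(out.loc[0, "event_time"],
                              100 / DAYS_PER_YEAR, atol=1e-9)

    def test_death_without_esrd_is_cause_2(self):
        c = _cohort(death=IDX + pd.Timedelta(days=700))
        out = derive_esrd_outcome(c).set_index("id")
        assert out.loc[0, "cause"] == 2
        assert np.isclose(out.loc[0, "event_time"], 700 / DAYS_PER_YEAR)

    def test_censored_at_last_visit(self):
        c = _cohort(extra_visit_days=800)
        out = derive_esrd_outcome(c).set_index("id")
        assert out.loc[0, "cause"] == 0
        assert np.isclose(out.loc[0, "event_time"], 800 / DAYS_PER_YEAR)

    def test_simulated_cohort_roundtrip(self):
        cohort = simulate_cohort(SimulationConfig(
            300, (0.5, -0.5, 0.3), (0.2, 0.1, -0.1), censor_rate=0.05, seed=9))
        out = derive_esrd_outcome(cohort)
        merged = out.merge(cohort.truth[["id", "time", "event"]], on="id")
        assert (merged["cause"] == merged["event"]).mean() > 0.98
        ev = merged[merged["event"] > 0]
        assert (ev["event_time"] - ev["time"]).abs().max() < 0.2


def _scripted_landmark_cohort():
    """10 subjects with scripted event times {0.5, 2, 6, 12, ...} years."""
    times = [0.5, 2.0, 6.0, 12.0, 0.8, 4.0, 9.0, 15.0, 1.5, 20.0]
    causes = [1, 1, 1, 1, 2, 2, 2, 0, 0, 0]
    outcomes = pd.DataFrame({"id": range(10), "event_time": times,
                             "cause": causes})
    patients = pd.DataFrame({
        "id": range(10), "sex": "M", "race": "white",
        "ethnicity": "not_hispanic",
        "birth_date": IDX - pd.Timedelta(days=21915),
        "index_date": IDX, "death_date": pd.NaT,
    })
    labs = pd.DataFrame([
        (i, IDX + pd.Timedelta(days=30), "sbp", 120.0 + i) for i in range(10)
    ], columns=["id", "date", "name", "value"])
    meds = pd.DataFrame(columns=["id", "date", "class", "days_supply"])
    dx = pd.DataFrame(columns=["id", "date", "code_group"])
    return RawCohort(patients, labs, meds, dx), outcomes


class TestBuildLandmark:
    def test_membership_matches_hand_enumeration(self):
        cohort, outcomes = _scripted_landmark_cohort()
        # event_time > s: LM1 drops {0.5, 0.8}; LM5 keeps {6,12,9,15,20};
        # LM10 keeps {12, 15, 20}
        assert set(build_landmark(cohort, outcomes, 1.0).frame["id"]) == \
            {1, 2, 3, 5, 6, 7, 8, 9}
        assert set(build_landmark(cohort, outcomes, 5.0).frame["id"]) == \
            {2, 3, 6, 7, 9}
        assert set(build_landmark(cohort, outcomes, 10.0).frame["id"]) == \
            {3, 7, 9}

    def test_residual_time_consistency_across_landmarks(self):
        cohort, outcomes = _scripted_landmark_cohort()
        lm1 = build_landmark(cohort, outcomes, 1.0).frame.set_index("id")
        lm5 = build_landmark(cohort, outcomes, 5.0).frame.set_index("id")
        shared = lm5.index
        assert np.allclose(lm5.loc[shared, "residual_time"],
                           lm1.loc[shared, "residual_time"] - 4.0)

    def test_last_value_in_window_wins_and_lookback_enforced(self):
        cohort, outcomes = _scripted_landmark_cohort()
        s = 5.0
        extra = pd.DataFrame([
            # s - 1.5y and s - 0.2y: the later one wins
            (3, IDX + pd.Timedelta(days=round(3.5 * 365.25)), "hba1c", 7.0),
            (3, IDX + pd.Timedelta(days=round(4.8 * 365.25)), "hba1c", 9.0),
            # outside the 2-year lookback: ignored
            (7, IDX + pd.Timedelta(days=round(2.5 * 365.25)), "hba1c", 6.0),
        ], columns=["id", "date", "name", "value"])
        cohort.labs = pd.concat([cohort.labs, extra], ignore_index=True)
        ds = build_landmark(cohort, outcomes, s)
        frame = ds.frame.set_index("id")
        assert frame.loc[3, "hba1c"] == 9.0
        assert np.isnan(frame.loc[7, "hba1c"])

    def test_medication_window_and_supply_rounding(self):
        cohort, outcomes = _scripted_landmark_cohort()
        s = 5.0
        lm_day = round(s * 365.25)
        cohort.meds = pd.DataFrame([
            # filled 70 days before the landmark with a 7-day supply: even
            # rounded up to 30 days the exposure ends 40 days before the
            # landmark, outside the 30-day window
            (3, IDX + pd.Timedelta(days=lm_day - 70), "acei", 7),
            # filled 45 days before with a 7-day supply: the 30-day rounded
            # exposure reaches 15 days before the landmark -> in the window
            (6, IDX + pd.Timedelta(days=lm_day - 45), "acei", 7),
            # filled inside the window
            (7, IDX + pd.Timedelta(days=lm_day - 10), "acei", 90),
        ], columns=["id", "date", "class", "days_supply"])
        ds = build_landmark(cohort, outcomes, s)
        frame = ds.frame.set_index("id")
        assert frame.loc[3, "acei"] == 0.0
        assert frame.loc[6, "acei"] == 1.0
        assert frame.loc[7, "acei"] == 1.0

    def test_empty_risk_set_errors(self):
        cohort, outcomes = _scripted_landmark_cohort()
        with pytest.raises(ValueError, match="25"):
            build_landmark(cohort, outcomes, 25.0)


class TestSplit:
    def test_70_30_and_determinism(self):
        frame = pd.DataFrame({"id": range(10), "residual_time": 1.0,
                              "cause": 1, "f": 0.0})
        ds = LandmarkDataset(1.0, frame, ["f"])
        s1 = split_cohort(ds, 0.7, seed=5)
        s2 = split_cohort(ds, 0.7, seed=5)
        assert (s1.frame["split"] == "train").sum() == 7
        assert (s1.frame["split"] == s2.frame["split"]).all()

    def test_later_landmark_inherits_labels(self):
        cohort, outcomes = _scripted_landmark_cohort()
        lm1 = split_cohort(build_landmark(cohort, outcomes, 1.0), 0.7, seed=1)
        labels = lm1.frame.set_index("id")["split"]
        lm5 = split_cohort(build_landmark(cohort, outcomes, 5.0),
                           inherit=labels)
        joined = lm5.frame.set_index("id")["split"]
        assert (labels.loc[joined.index] == joined).all()

    def test_resplit_requires_override(self):
        frame = pd.DataFrame({"id": range(4), "residual_time": 1.0,
                              "cause": 1, "f": 0.0})
        ds = split_cohort(LandmarkDataset(1.0, frame, ["f"]), 0.5, seed=1)
        with pytest.raises(ValueError, match="override"):
            split_cohort(ds, 0.5, seed=2)
        split_cohort(ds, 0.5, seed=2, override=True)


class TestMissingnessPolicy:
    def _dataset(self, n=600, miss=0.85, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 20, n)
        frame = pd.DataFrame({
            "id": range(n), "residual_time": rng.exponential(2, n) + 0.1,
            "cause": rng.integers(0, 3, n),
            "clean": rng.normal(size=n),
            "heavy": np.where(rng.uniform(size=n) < miss, np.nan, x),
            "flag": rng.integers(0, 2, n).astype(float),
        })
        return LandmarkDataset(1.0, frame, ["clean", "heavy", "flag"])

    def test_clean_feature_passes_through_standardized(self):
        ds = self._dataset()
        schema = fit_missingness_policy(ds, seed=1)
        out = schema.transform(ds)
        assert schema.specs["clean"].kind == "continuous"
        assert abs(out.frame["clean"].mean()) < 1e-10
        assert np.isclose(out.frame["clean"].std(ddof=0), 1.0)

    def test_heavy_missingness_binned_with_missing_category(self):
        ds = self._dataset()
        schema = fit_missingness_policy(ds, bin_edges={"heavy": (30.0, 300.0)},
                                        seed=1)
        out = schema.transform(ds)
        spec = schema.specs["heavy"]
        assert spec.kind == "binned" and spec.has_missing_category
        cols = {"heavy_30to300", "heavy_ge300", "heavy_missing"}
        assert cols <= set(out.feature_cols)
        miss = ds.frame["heavy"].isna()
        assert (out.frame.loc[miss, "heavy_missing"] == 1.0).all()
        assert (out.frame.loc[~miss, "heavy_missing"] == 0.0).all()

    def test_policy_fitted_on_train_applied_frozen_to_test(self):
        ds = self._dataset()
        ds = split_cohort(ds, 0.7, seed=3)
        schema = fit_missingness_policy(ds.train, seed=1)
        te = schema.transform(ds.test)
        spec = schema.specs["clean"]
        tr_mean = ds.train.frame["clean"].mean()
        assert np.isclose(spec.mean, tr_mean)
        # test standardization uses the train statistics, not its own
        assert abs(te.frame["clean"].mean()) > 1e-6

    def test_imputation_beats_mean_imputation_on_gaussian_mcar(self):
        rng = np.random.default_rng(4)
        n = 800
        z = rng.multivariate_normal([0, 0], [[1, 0.85], [0.85, 1]], size=n)
        mask = rng.uniform(size=n) < 0.3
        x0 = np.where(mask, np.nan, z[:, 0])
        frame = pd.DataFrame({"id": range(n), "residual_time": 1.0,
                              "cause": 1, "x0": x0, "x1": z[:, 1]})
        ds = LandmarkDataset(1.0, frame, ["x0", "x1"])
        schema = fit_missingness_policy(ds, seed=2)
        out = schema.transform(ds)
        spec = schema.specs["x0"]
        imputed = out.frame.loc[mask, "x0"].to_numpy() * spec.sd + spec.mean
        rmse = np.sqrt(np.mean((imputed - z[mask, 0]) ** 2))
        mean_rmse = np.sqrt(np.mean((np.nanmean(x0) - z[mask, 0]) ** 2))
        assert rmse < mean_rmse  # conditional regressions beat the marginal

    def test_all_missing_feature_dropped_with_warning(self):
        ds = self._dataset()
        ds.frame["void"] = np.nan
        ds.feature_cols.append("void")
        with pytest.warns(UserWarning, match="void"):
            schema = fit_missingness_policy(ds, seed=1)
        assert "void" not in schema.columns
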