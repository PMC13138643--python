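"""Landmark dataset construction: windowed snapshots, missingness policy, splits.

At a landmark time ``s`` (years after the index date) the risk set is every
subject still event-free at ``s``; covariates are snapshotted with
half-open lookback windows (s - w, s]:

* biomarkers/labs: 2-year lookback, last in-window value wins;
* medications: 30-day lookback; a drug is flagged if any dispensation's
  exposure interval touches the window, with supplies under 30 days rounded
  up to 30 days;
* conditions (coded diagnoses): full history up to ``s``.

The missingness policy is fitted on the training split only and applied
frozen everywhere: continuous features with more than 40% missingness are
binned at clinical cutoffs with an explicit missing category; features at
or below 40% get a single chained-equations imputation replicate and are
then centered/scaled by training statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import spawn_rng
from .simulate import DAYS_PER_YEAR, RawCohort

logger = logging.getLogger(__name__)

BIOMARKER_LOOKBACK_YEARS = 2.0
MEDICATION_LOOKBACK_DAYS = 30
MIN_SUPPLY_DAYS = 30
MISSINGNESS_BIN_THRESHOLD = 0.40


@dataclass
class LandmarkDataset:
    """Snapshot feature matrix and residual outcomes at one landmark time."""

    s: float
    frame: pd.DataFrame  # id, residual_time, cause, [split], features...
    feature_cols: list
    schema: "FeatureSchema | None" = None

    @property
    def X(self):
        return self.frame[self.feature_cols]

    @property
    def time(self):
        return self.frame["residual_time"].to_numpy(dtype=float)

    @property
    def cause(self):
        return self.frame["cause"].to_numpy(dtype=int)

    def subset(self, mask):
        return LandmarkDataset(self.s, self.frame[mask].reset_index(drop=True),
                               list(self.feature_cols), self.schema)

    @property
    def train(self):
        self._require_split()
        return self.subset((self.frame["split"] == "train").to_numpy())

    @property
    def test(self):
        self._require_split()
        return self.subset((self.frame["split"] == "test").to_numpy())

    def _require_split(self):
        if "split" not in self.frame.columns:
            raise ValueError("dataset has no split labels; call split_cohort first")


def build_landmark(cohort: RawCohort, outcomes: pd.DataFrame, s: float,
                   lab_features=None, med_features=None, dx_features=None,
                   biomarker_lookback=BIOMARKER_LOOKBACK_YEARS,
                   med_lookback_days=MEDICATION_LOOKBACK_DAYS,
                   demographics=True) -> LandmarkDataset:
    """Assemble the landmark-``s`` dataset (risk set + covariate snapshot)."""
    at_risk = outcomes[outcomes["event_time"] > s]
    if at_risk.empty:
        raise ValueError(f"empty risk set at landmark {s}")
    ids = at_risk["id"].to_numpy()
    patients = cohort.patients.set_index("id").loc[ids]
    lm_date = patients["index_date"] + pd.to_timedelta(
        round(s * DAYS_PER_YEAR), "D"
    )

    frame = pd.DataFrame({
        "id": ids,
        "residual_time": at_risk["event_time"].to_numpy() - s,
        "cause": at_risk["cause"].to_numpy(),
    })
    feature_cols = []

    if demographics:
        age = (lm_date - patients["birth_date"]).dt.days / DAYS_PER_YEAR
        frame["age"] = age.to_numpy()
        frame["male"] = (patients["sex"] == "M").astype(float).to_numpy()
        frame["black_race"] = (patients["race"] == "black").astype(float).to_numpy()
        frame["hispanic"] = (
            patients["ethnicity"] == "hispanic"
        ).astype(float).to_numpy()
        feature_cols += ["age", "male", "black_race", "hispanic"]

    # ---- labs: last value in (s - lookback, s] -------------------------
    labs = cohort.labs.merge(
        patients[["index_date"]], left_on="id", right_index=True
    )
    labs = labs.merge(
        lm_date.rename("lm_date"), left_on="id", right_index=True
    )
    w0 = labs["lm_date"] - pd.to_timedelta(round(biomarker_lookback * DAYS_PER_YEAR), "D")
    in_window = (labs["date"] > w0) & (labs["date"] <= labs["lm_date"])
    lw = labs[in_window].sort_values("date")
    lab_names = lab_features or sorted(cohort.labs["name"].unique())
    snap = (
        lw[lw["name"].isin(lab_names)]
        .groupby(["id", "name"])["value"].last().unstack()
    )
    for name in lab_names:
        col = snap[name] if name in snap.columns else pd.Series(dtype=float)
        frame[name] = frame["id"].map(col)
        feature_cols.append(name)

    # ---- medications: exposure touches (s - 30d, s] --------------------
    med_names = med_features
    if med_names is None:
        med_names = sorted(cohort.meds["class"].unique()) if len(cohort.meds) else []
    if med_names:
        meds = cohort.meds.merge(lm_date.rename("lm_date"), left_on="id", right_index=True)
        supply = np.maximum(
            meds["days_supply"].to_numpy(dtype=float), MIN_SUPPLY_DAYS
        )
        end = meds["date"] + pd.to_timedelta(supply, "D")
        w0 = meds["lm_date"] - pd.Timedelta(days=med_lookback_days)
        touches = (meds["date"] <= meds["lm_date"]) & (end > w0)
        mw = meds[touches]
        for cls in med_names:
            flagged = set(mw.loc[mw["class"] == cls, "id"])
            frame[cls] = frame["id"].isin(flagged).astype(float)
            feature_cols.append(cls)

    # ---- diagnoses: any history up to s --------------------------------
    dx_names = dx_features
    if dx_names is None:
        dx_names = (
            sorted(cohort.diagnoses["code_group"].unique())
            if len(cohort.diagnoses) else []
        )
        dx_names = [d for d in dx_names if d != "esrd"]  # outcome, not feature
    if dx_names:
        dx = cohort.diagnoses.merge(
            lm_date.rename("lm_date"), left_on="id", right_index=True
        )
        dx = dx[dx["date"] <= dx["lm_date"]]
        for grp in dx_names:
            flagged = set(dx.loc[dx["code_group"] == grp, "id"])
            frame[f"hx_{grp}"] = frame["id"].isin(flagged).astype(float)
            feature_cols.append(f"hx_{grp}")

    return LandmarkDataset(float(s), frame, feature_cols)


def split_cohort(dataset: LandmarkDataset, fraction=0.7, seed=0,
                 inherit: pd.Series | None = None, override=False) -> LandmarkDataset:
    """Assign (or inherit) persistent train/test labels by subject id.

    The split is drawn once — at the first landmark — and later landmarks
    inherit the same labels via ``inherit`` (a Series id -> label).
    """
    if "split" in dataset.frame.columns and not override:
        raise ValueError("dataset already split; pass override=True to re-split")
    frame = dataset.frame.copy()
    if inherit is not None:
        frame["split"] = frame["id"].map(inherit)
        missing = frame["split"].isna()
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} subject(s) lack an inherited split label"
            )
    else:
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        rng = spawn_rng(seed, "split")
        ids = frame["id"].to_numpy()
        n_train = int(round(fraction * len(ids)))
        perm = rng.permutation(len(ids))
        lab = np.empty(len(ids), dtype=object)
        lab[perm[:n_train]] = "train"
        lab[perm[n_train:]] = "test"
        frame["split"] = lab
    return LandmarkDataset(dataset.s, frame, list(dataset.feature_cols), dataset.schema)


# ---------------------------------------------------------------------------
# missingness policy / feature schema
# ---------------------------------------------------------------------------


@dataclass
class FeatureSpec:
    name: str
    kind: str  # 'continuous' | 'binned' | 'binary'
    missing_frac: float = 0.0
    bin_edges: tuple | None = None
    has_missing_category: bool = False
    mean: float | None = None
    sd: float | None = None
    out_columns: tuple = ()


@dataclass
class FeatureSchema:
    """Frozen train-fitted transform: binning, imputation, standardization."""

    specs: dict = field(default_factory=dict)
    _imputer: object = None
    _impute_cols: list = field(default_factory=list)

    @property
    def columns(self):
        out = []
        for spec in self.specs.values():
            out.extend(spec.out_columns)
        return out

    def transform(self, dataset: LandmarkDataset) -> LandmarkDataset:
        """Apply the frozen policy to any landmark dataset (train/test/target)."""
        frame = dataset.frame.copy()
        out_cols = []
        for name, spec in self.specs.items():
            if spec.kind == "dropped":
                continue
            x = frame[name]
            if spec.kind == "binary":
                frame[name] = x.fillna(0.0).astype(float)
                out_cols.append(name)
            elif spec.kind == "binned":
                cats = _bin_categories(spec.bin_edges)
                codes = _bin_codes(x, spec.bin_edges)
                for k, cat in enumerate(cats):
                    if k == 0:
                        continue  # reference category
                    frame[f"{name}_{cat}"] = (codes == k).astype(float)
                    out_cols.append(f"{name}_{cat}")
                if spec.has_missing_category:
                    frame[f"{name}_missing"] = x.isna().astype(float)
                    out_cols.append(f"{name}_missing")
            elif spec.kind == "continuous":
                out_cols.append(name)
        if self._impute_cols:
            block = frame[self._impute_cols].to_numpy(dtype=float)
            imputed = self._imputer.transform(block)
            frame[self._impute_cols] = imputed
        for name, spec in self.specs.items():
            if spec.kind == "continuous":
                frame[name] = (frame[name] - spec.mean) / spec.sd
        return LandmarkDataset(dataset.s, frame, out_cols, self)


def _bin_categories(edges):
    cats = [f"lt{edges[0]:g}"]
    for a, b in zip(edges[:-1], edges[1:]):
        cats.append(f"{a:g}to{b:g}")
    cats.append(f"ge{edges[-1]:g}")
    return cats


def _bin_codes(x, edges):
    codes = np.searchsorted(np.asarray(edges, dtype=float), x.to_numpy(dtype=float),
                            side="right")
    return np.where(x.isna().to_numpy(), -1, codes)


def fit_missingness_policy(train: LandmarkDataset, bin_edges=None,
                           threshold=MISSINGNESS_BIN_THRESHOLD,
                           n_iter=5, seed=0) -> FeatureSchema:
    """Fit the train-only missingness policy and return the frozen schema.

    ``bin_edges`` maps feature name -> clinical cutoffs used when the
    feature exceeds the missingness threshold (default: its observed
    training terciles).  Low-missingness continuous features share a single
    chained-equations imputation replicate (round-robin conditional
    regressions with a fixed iteration count and seed), then standardize.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    bin_edges = bin_edges or {}
    frame = train.frame
    schema = FeatureSchema()
    impute_cols = []
    for name in train.feature_cols:
        x = frame[name]
        miss = float(x.isna().mean())
        vals = x.dropna().unique()
        if miss >= 1.0 or len(vals) == 0:
            warnings.warn(f"feature {name!r} is entirely missing; dropped")
            schema.specs[name] = FeatureSpec(name, "dropped", miss)
            continue
        if set(np.unique(vals)) <= {0.0, 1.0}:
            spec = FeatureSpec(name, "binary", miss, out_columns=(name,))
        elif miss > threshold:
            edges = tuple(
                bin_edges.get(name)
                or np.unique(np.quantile(x.dropna(), [1 / 3, 2 / 3])).tolist()
            )
            cats = _bin_categories(edges)[1:]
            cols = tuple(f"{name}_{c}" for c in cats) + (f"{name}_missing",)
            spec = FeatureSpec(name, "binned", miss, bin_edges=edges,
                               has_missing_category=True, out_columns=cols)
        else:
            spec = FeatureSpec(name, "continuous", miss, out_columns=(name,))
            impute_cols.append(name)
        schema.specs[name] = spec

    if impute_cols:
        imputer = IterativeImputer(
            max_iter=n_iter, random_state=int(seed) % (2**31), sample_posterior=False,
            keep_empty_features=True,
        )
        block = frame[impute_cols].to_numpy(dtype=float)
        imputed = imputer.fit_transform(block)
        schema._imputer = imputer
        schema._impute_cols = impute_cols
        for k, name in enumerate(impute_cols):
            col = imputed[:, k]
            sd = float(np.std(col))
            schema.specs[name].mean = float(np.mean(col))
            schema.specs[name].sd = sd if sd > 0 else 1.0
    return schema
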