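"""Stage-one univariable predictor screening.

Each candidate feature enters an adjusted logistic regression (candidate +
adjusters, e.g. age/sex/race) for the binary outcome "cause-1 event within
the screening horizon".  Subjects are included when they either have the
potential to be followed through the horizon (T >= h) or experienced any
event before it; censored-before-horizon subjects are excluded.  A feature
is retained when |logOR| > threshold and the Wald P < alpha.  Multi-level
binned features are retained when ANY level passes.  No multiplicity
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .landmark import LandmarkDataset


@dataclass
class ScreeningResult:
    table: pd.DataFrame  # feature, level_col, log_or, p_value, retained
    retained: list  # column names passing the rule (adjusters always included)
    threshold: float
    alpha: float

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _screening_outcome(time, cause, horizon):
    include = (time >= horizon) | (cause != 0)
    y = ((cause == 1) & (time <= horizon)).astype(float)
    return include, y


def screen_features(train: LandmarkDataset, adjusters, horizon=10.0,
                    threshold=0.1, alpha=0.05,
                    level_groups: dict | None = None) -> ScreeningResult:
    """Adjusted univariable logistic screening on the training split.

    ``level_groups`` maps a base feature name to its indicator columns so a
    binned feature is tested jointly (retained if any level passes).
    """
    frame = train.frame
    for adj in adjusters:
        if adj not in frame.columns:
            raise ValueError(f"adjuster column {adj!r} not present")
    include, y = _screening_outcome(train.time, train.cause, horizon)
    y = y[include]
    A = frame.loc[include, adjusters].to_numpy(dtype=float)

    level_groups = level_groups or {}
    col_to_group = {}
    for base, cols in level_groups.items():
        for c in cols:
            col_to_group[c] = base

    candidates = [c for c in train.feature_cols if c not in adjusters]
    rows = []
    for col in candidates:
        x = frame.loc[include, col].to_numpy(dtype=float)
        design = sm.add_constant(np.column_stack([x, A]), has_constant="add")
        log_or, p = np.nan, np.nan
        # collinearity guard: candidate with no variation beyond the adjusters
        Ac = sm.add_constant(A, has_constant="add")
        resid = x - Ac @ np.linalg.lstsq(Ac, x, rcond=None)[0]
        if np.ptp(x) == 0 or np.std(resid) < 1e-10 * max(np.std(x), 1e-12):
            log_or, p = 0.0, 1.0
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
                log_or, p = fit.params[1], fit.pvalues[1]
                if not np.isfinite(log_or) or abs(log_or) > 50:
                    raise ValueError("separation")
            except Exception:
                warnings.warn(
                    f"screening fit failed for {col!r} (possible separation); "
                    "retained by default"
                )
                log_or, p = np.inf, 0.0
        passed = bool(abs(log_or) > threshold and p < alpha)
        rows.append({
            "feature": col_to_group.get(col, col),
            "column": col,
            "log_or": log_or,
            "p_value": p,
            "retained": passed,
        })
    table = pd.DataFrame(rows)
    # multi-level features: any passing level retains the whole group
    group_pass = table.groupby("feature")["retained"].transform("any")
    table["retained"] = group_pass
    retained = list(adjusters) + table.loc[table["retained"], "column"].tolist()
    return ScreeningResult(table, retained, threshold, alpha)
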