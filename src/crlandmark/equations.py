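"""Benchmark risk equations (KFRE-style linear-predictor scores) + recalibration.

An equation is a versioned JSON config, not code, so coefficients can be
audited and swapped: each input carries a scale divisor, an optional log
transform, a centering constant and a coefficient; the predicted risk at
horizon ``h`` is

    risk(h | x) = 1 - S0(h) ** exp( sum_j c_j * (g_j(x_j) - center_j) ),

with ``g_j(x) = log(x / scale_j)`` or ``x / scale_j``.  A missing input with
a declared default (the urine albumin-to-creatinine ratio defaults to
7.5 mg/g, a median healthy value, when unmeasured in the landmark window)
is substituted before the transform; a missing non-defaultable input is an
error.  The 4-variable KFRE ships with its published coefficients; the
RECODe kidney-failure stand-in is synthetic (see its JSON description) and
exists so the benchmark workflow runs end-to-end on synthetic cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .landmark import LandmarkDataset
from .transport import _offset_breslow_cox, _offset_breslow_fg


@dataclass
class RiskEquationSpec:
    """A linear-predictor risk equation loaded from a JSON config."""

    name: str
    inputs: list  # dicts: name, scale, log, center, coefficient, [default]
    baseline_survival: dict  # {horizon (years, str or float): S0}
    description: str = ""
    synthetic: bool = False

    @classmethod
    def from_json(cls, path_or_dict, non_north_american=False):
        if isinstance(path_or_dict, dict):
            d = path_or_dict
        else:
            with open(path_or_dict) as fh:
                d = json.load(fh)
        base = d["baseline_survival"]
        if non_north_american:
            alt = d.get("baseline_survival_non_north_american")
            if alt is None:
                raise ValueError(f"{d['name']} has no non-North-American baselines")
            base = alt
        return cls(
            name=d["name"],
            inputs=d["inputs"],
            baseline_survival={float(k): float(v) for k, v in base.items()},
            description=d.get("description", ""),
            synthetic=bool(d.get("synthetic", False)),
        )

    @classmethod
    def load_builtin(cls, name, **kwargs):
        """Load a shipped equation: 'kfre4' or 'recode_esrd_synthetic'."""
        with resources.files("crlandmark.data").joinpath(f"{name}.json").open() as fh:
            return cls.from_json(json.load(fh), **kwargs)

    @property
    def required_inputs(self):
        return [i["name"] for i in self.inputs]

    def linear_predictor(self, frame: pd.DataFrame):
        lp = np.zeros(len(frame))
        for spec in self.inputs:
            name = spec["name"]
            if name in frame.columns:
                x = frame[name].to_numpy(dtype=float)
            else:
                x = np.full(len(frame), np.nan)
            if "default" in spec:
                x = np.where(np.isnan(x), float(spec["default"]), x)
            elif np.isnan(x).any():
                raise ValueError(
                    f"equation {self.name!r}: input {name!r} is missing and has "
                    "no default"
                )
            g = x / float(spec.get("scale", 1.0))
            if spec.get("log", False):
                g = np.log(g)
            lp += float(spec["coefficient"]) * (g - float(spec.get("center", 0.0)))
        return lp

    def predict_risk(self, frame: pd.DataFrame, h):
        if float(h) not in self.baseline_survival:
            raise ValueError(
                f"equation {self.name!r} has no baseline anchor at horizon {h}; "
                f"available: {sorted(self.baseline_survival)} (or recalibrate)"
            )
        s0 = self.baseline_survival[float(h)]
        risk = 1.0 - s0 ** np.exp(self.linear_predictor(frame))
        return np.clip(risk, 0.0, 1.0)


def compute_equation_risk(spec: RiskEquationSpec,
                          snapshot: LandmarkDataset | pd.DataFrame, h):
    """Evaluate an equation on a landmark snapshot at horizon h (years)."""
    frame = snapshot.frame if isinstance(snapshot, LandmarkDataset) else snapshot
    return spec.predict_risk(frame, h)


class EquationResults:
    """Adapter giving a risk equation the fitted-model prediction surface,
    so it can flow through the recalibration machinery unchanged."""

    def __init__(self, spec: RiskEquationSpec):
        self.spec = spec
        self.feature_names = spec.required_inputs
        self.params = np.array([float(i["coefficient"]) for i in spec.inputs])
        self.center_ = np.zeros(len(spec.inputs))

    def _conform(self, X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("risk equations require a named DataFrame")
        return X

    def linear_predictor(self, frame):
        return self.spec.linear_predictor(frame)


def recalibrate_equation(spec: RiskEquationSpec,
                         target: LandmarkDataset, engine="fine-gray"):
    """Recalibrate an equation's baseline in a target cohort.

    The equation's linear predictor is a fixed offset (coefficient 1); the
    target baseline hazard is estimated under the chosen engine and anchored
    at the target mean of the linear predictor.  Returns an object with
    ``predict_cif(frame, h)``.
    """
    frame = target.frame
    lp = spec.linear_predictor(frame)
    lp_c = lp - lp.mean()
    if engine == "fine-gray":
        baseline = _offset_breslow_fg(target.time, target.cause, lp_c)
    elif engine == "cox":
        baseline = _offset_breslow_cox(target.time, target.cause, lp_c)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return _RecalibratedEquation(spec, baseline, float(lp.mean()), engine)


class _RecalibratedEquation:
    def __init__(self, spec, baseline, lp_mean, engine):
        self.spec = spec
        self.baseline_cumhaz_ = baseline
        self.lp_mean = lp_mean
        self.engine = engine

    def linear_predictor(self, frame):
        return self.spec.linear_predictor(frame) - self.lp_mean

    def predict_cif(self, frame, horizons):
        if isinstance(frame, LandmarkDataset):
            frame = frame.frame
        scalar = np.isscalar(horizons)
        horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
        lp = self.linear_predictor(frame)
        lam = np.atleast_1d(self.baseline_cumhaz_(horizons))
        F = 1.0 - np.exp(-np.outer(np.exp(lp), lam))
        return F[:, 0] if scalar else F
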