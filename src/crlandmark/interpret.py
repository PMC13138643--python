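"""Model explanation and operating-threshold selection.

Shapley attributions are estimated by Monte-Carlo permutation sampling with
a marginal background: for each sampled permutation the features are
switched one at a time from a background draw to the explained subject's
values, and the successive prediction differences are the marginal
contributions.  The target function defaults to the predicted cumulative
incidence at a horizon (risk scale); a linear-predictor-scale option exists,
for which the attribution of an independent feature j converges to
beta_j * (x_j - E[x_j]) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import spawn_rng


@dataclass
class ShapReport:
    horizon: float | None
    values: pd.DataFrame  # (subjects x features) attributions
    base_value: float  # expected prediction over the background
    n_samples: int
    seed: int

    @property
    def ranking(self) -> pd.Series:
        """Global importance: mean |attribution| per feature, descending."""
        return self.values.abs().mean(axis=0).sort_values(ascending=False)


def shap_values(model, data: pd.DataFrame, h=None, n_samples=128, seed=0,
                background: pd.DataFrame | None = None,
                target="risk") -> ShapReport:
    """Monte-Carlo permutation Shapley values of a fitted model's predictions.

    Parameters
    ----------
    model : object with ``predict_cif`` / ``linear_predictor``
    data : DataFrame of subjects to explain (model feature columns).
    h : horizon (years), required for the risk-scale target.
    n_samples : permutations per subject (>= 32).
    background : marginal background sample; defaults to ``data`` itself.
    target : 'risk' (predicted CIF at h) or 'linear' (linear predictor).
    """
    if n_samples < 32:
        raise ValueError("n_samples must be >= 32")
    names = list(model.feature_names)
    X = data[names].to_numpy(dtype=float)
    bg = (background[names] if background is not None else data[names]).to_numpy(
        dtype=float
    )
    if bg.shape[0] < 2:
        raise ValueError("background must contain more than one row")
    if target == "risk":
        if h is None:
            raise ValueError("a horizon h is required for the risk-scale target")
        f = lambda M: np.asarray(model.predict_cif(pd.DataFrame(M, columns=names), h))
    elif target == "linear":
        f = lambda M: np.asarray(
            model.linear_predictor(pd.DataFrame(M, columns=names))
        )
    else:
        raise ValueError(f"unknown target {target!r}")

    rng = spawn_rng(seed, "shap")
    n, p = X.shape
    phi = np.zeros((n, p))
    base = float(f(bg).mean())
    # balanced background: full permuted passes over the background rows so
    # the background-mean sampling error vanishes at multiples of its size
    n_bg = bg.shape[0]
    reps = int(np.ceil(n_samples / n_bg))
    bg_order = np.concatenate([rng.permutation(n_bg) for _ in range(reps)])
    for k in range(n_samples):
        perm = rng.permutation(p)
        cur = np.tile(bg[bg_order[k]], (n, 1))
        prev = f(cur)
        for j in perm:
            cur[:, j] = X[:, j]
            nxt = f(cur)
            phi[:, j] += nxt - prev
            prev = nxt
    phi /= n_samples
    values = pd.DataFrame(phi, columns=names, index=data.index)
    return ShapReport(h, values, base, n_samples, seed)


def compare_coefficients(models: dict) -> tuple:
    """Tidy coefficient comparison across fitted models sharing a schema.

    ``models`` maps label -> results object (``params``, ``bse``,
    ``feature_names``).  Returns (long table, pairwise Lin concordance
    correlation matrix).
    """
    labels = list(models)
    names0 = list(models[labels[0]].feature_names)
    rows = []
    for lab in labels:
        m = models[lab]
        if list(m.feature_names) != names0:
            raise ValueError(f"model {lab!r} has a different feature schema")
        bse = getattr(m, "bse", np.full(len(names0), np.nan))
        for j, name in enumerate(names0):
            rows.append({"feature": name, "model": lab,
                         "beta": float(m.params[j]), "se": float(bse[j])})
    table = pd.DataFrame(rows)

    def ccc(a, b):
        a, b = np.asarray(a), np.asarray(b)
        cov = np.cov(a, b, ddof=0)
        return 2 * cov[0, 1] / (cov[0, 0] + cov[1, 1] + (a.mean() - b.mean()) ** 2)

    conc = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            c = ccc(models[la].params, models[lb].params)
            conc.loc[la, lb] = conc.loc[lb, la] = c
    return table, conc


@dataclass
class ThresholdChoice:
    method: str
    threshold: float
    sensitivity: float
    specificity: float


def select_threshold(roc, method="youden") -> ThresholdChoice:
    """Operating threshold from a time-dependent ROC curve.

    'youden' maximizes TPR - FPR; 'top_left' minimizes the Euclidean
    distance to the perfect corner (FPR, TPR) = (0, 1).  Ties resolve to the
    lower threshold (higher sensitivity).
    """
    thr, tpr, fpr = roc.thresholds, roc.tpr, roc.fpr
    if thr.size < 2:
        raise ValueError("degenerate ROC (single point)")
    if method == "youden":
        crit = tpr - fpr
        best = np.flatnonzero(crit >= crit.max() - 1e-12)
    elif method == "top_left":
        dist = np.sqrt(fpr**2 + (1 - tpr) ** 2)
        best = np.flatnonzero(dist <= dist.min() + 1e-12)
    else:
        raise ValueError(f"unknown method {method!r}")
    k = best[np.argmin(thr[best])]  # lower threshold = higher sensitivity
    return ThresholdChoice(method, float(thr[k]), float(tpr[k]), float(1 - fpr[k]))
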