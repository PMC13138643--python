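"""Fine-Gray subdistribution hazard regression with IPCW risk-set weights.

The estimator maximizes the weighted partial likelihood in which subjects
with a competing (cause-2) event remain in the cause-1 risk set after their
event time with Kaplan-Meier censoring weights

    w_j(t) = G(t-) / G(min(T_j, t)-) ,

where ``G`` is the Kaplan-Meier estimate of the censoring survival function.
All score/information quantities are computed in O(n) per covariate via a
forward-backward scan: a backward (suffix) accumulation over the
conventional risk set {j : T_j >= t} plus a forward (prefix) accumulation
over weighted cause-2 contributions {j : cause_j = 2, T_j < t}.

The module follows the statsmodels pattern: a :class:`FineGray` model object
built from data; ``fit()`` returns a :class:`FineGrayResults` carrying
coefficient estimates, model-based Wald standard errors, the Breslow-type
baseline cumulative subdistribution hazard anchored at the covariate mean,
and a ``summary()`` table.  The MCP-penalized path lives in
:mod:`crlandmark.mcp` and is reachable as ``FineGray.fit_regularized``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import StepFunction

_BETA_BOUND = 20.0


class CensoringDistribution:
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Censoring (cause 0) is treated as the event; causes 1 and 2 are treated
    as censored-for-G.  Provides right-continuous evaluation ``G(t)`` and the
    left limit ``G(t-)`` used by the weight convention.
    """

    def __init__(self, step: StepFunction):
        self._step = step

    @classmethod
    def fit(cls, time, event) -> "CensoringDistribution":
        # product-limit estimator computed directly (cross-checked against
        # lifelines' KaplanMeierFitter in the test suite); censoring events
        # at tied times are taken after cause-1/2 events, the usual
        # at-risk convention
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.size == 0:
            raise ValueError("no records")
        n = time.size
        u, inv = np.unique(time, return_inverse=True)
        d = np.bincount(inv, weights=(event == 0).astype(float), minlength=u.size)
        nobs = np.bincount(inv, minlength=u.size)
        at_risk = n - np.concatenate([[0], np.cumsum(nobs)[:-1]])
        surv = np.cumprod(1.0 - d / at_risk)
        return cls(StepFunction(u, surv, baseline=1.0))

    def __call__(self, t):
        return self._step(t)

    def left_limit(self, t):
        return self._step.left_limit(t)


def censoring_km(time, event) -> CensoringDistribution:
    """Functional alias for :meth:`CensoringDistribution.fit`."""
    return CensoringDistribution.fit(time, event)


# ---------------------------------------------------------------------------
# scan machinery
# ---------------------------------------------------------------------------


class _FGData:
    """Pre-sorted arrays and censoring-weight ingredients for the scan."""

    def __init__(self, time, event, X, censoring=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite (impute or bin first)")
        if np.any(time <= 0):
            raise ValueError("times must be positive")
        if not np.isin(event, [0, 1, 2]).all():
            raise ValueError("event codes must be 0 (censored), 1 or 2")
        order = np.argsort(time, kind="stable")
        self.order = order
        self.t = time[order]
        self.d = event[order]
        self.X = X[order]
        self.n, self.p = X.shape
        self.G = censoring or CensoringDistribution.fit(time, event)
        # G(T_j-) for every subject (used in cause-2 prefix weights)
        self.Gm_T = np.asarray(self.G.left_limit(self.t), dtype=float)
        self.ev = np.flatnonzero(self.d == 1)  # cause-1 positions (sorted order)
        if self.ev.size:
            s = self.t[self.ev]
            # first sorted index with t >= s  (== index into prefix t < s)
            self.a = np.searchsorted(self.t, s, side="left")
            self.Gm_s = np.asarray(self.G.left_limit(s), dtype=float)
        self.is2 = self.d == 2

    def weights_matrix(self):
        """Dense w_j(t_k) for each cause-1 event time; O(n^2), reference only."""
        s = self.t[self.ev]
        W = np.zeros((self.ev.size, self.n))
        for k, sk in enumerate(s):
            at_risk = self.t >= sk
            W[k, at_risk] = 1.0
            late2 = self.is2 & (self.t < sk)
            W[k, late2] = self.Gm_s[k] / self.Gm_T[late2]
        return W


def _suffix_cumsum(a, axis=0):
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


def fg_loglik_score_hessian(data: _FGData, beta, want=("loglik", "score", "hessian")):
    """Weighted FG partial log-likelihood, score and Hessian via the scan.

    Returns a dict with the requested entries.  Cost O(n p) for the score and
    O(n p^2) for the Hessian; memory O(n p).
    """
    beta = np.asarray(beta, dtype=float)
    t, d, X, ev, a = data.t, data.d, data.X, data.ev, data.a
    if ev.size == 0:
        raise ValueError("no cause-1 events")
    eta = X @ beta
    eta = eta - eta.max()  # stabilize; partial likelihood is shift-invariant
    r = np.exp(eta)
    c = np.where(data.is2, r / data.Gm_T, 0.0)

    # denominators
    suf_r = np.concatenate([_suffix_cumsum(r), [0.0]])
    pre_c = np.concatenate([[0.0], np.cumsum(c)])
    D = suf_r[a] + data.Gm_s * pre_c[a]
    out = {}
    if "loglik" in want:
        out["loglik"] = float(np.sum(eta[ev]) - np.sum(np.log(D)))
    if "score" in want or "hessian" in want:
        rX = r[:, None] * X
        cX = c[:, None] * X
        suf_rX = np.vstack([_suffix_cumsum(rX), np.zeros(data.p)])
        pre_cX = np.vstack([np.zeros(data.p), np.cumsum(cX, axis=0)])
        N = suf_rX[a] + data.Gm_s[:, None] * pre_cX[a]  # (K, p)
        xbar = N / D[:, None]
        out["score"] = X[ev].sum(axis=0) - xbar.sum(axis=0)
    if "hessian" in want:
        H = np.zeros((data.p, data.p))
        for j in range(data.p):
            rXXj = rX * X[:, [j]]
            cXXj = cX * X[:, [j]]
            suf = np.vstack([_suffix_cumsum(rXXj), np.zeros(data.p)])
            pre = np.vstack([np.zeros(data.p), np.cumsum(cXXj, axis=0)])
            Mj = suf[a] + data.Gm_s[:, None] * pre[a]  # (K, p)
            H[j] = (Mj / D[:, None] - xbar * xbar[:, [j]]).sum(axis=0)
        out["hessian"] = -H
    return out


def fg_coordinate_score_info(data: _FGData, eta, j):
    """Score U_j and information I_j for coordinate j at linear predictor eta.

    O(n) given eta; used by the MCP coordinate-descent solver.
    """
    ev, a = data.ev, data.a
    r = np.exp(eta - eta.max())
    c = np.where(data.is2, r / data.Gm_T, 0.0)
    xj = data.X[:, j]
    suf_r = np.concatenate([_suffix_cumsum(r), [0.0]])
    pre_c = np.concatenate([[0.0], np.cumsum(c)])
    D = suf_r[a] + data.Gm_s * pre_c[a]
    suf_rx = np.concatenate([_suffix_cumsum(r * xj), [0.0]])
    pre_cx = np.concatenate([[0.0], np.cumsum(c * xj)])
    Nj = suf_rx[a] + data.Gm_s * pre_cx[a]
    suf_rxx = np.concatenate([_suffix_cumsum(r * xj * xj), [0.0]])
    pre_cxx = np.concatenate([[0.0], np.cumsum(c * xj * xj)])
    Mj = suf_rxx[a] + data.Gm_s * pre_cxx[a]
    xbar = Nj / D
    U = xj[ev].sum() - xbar.sum()
    I = (Mj / D - xbar**2).sum()
    return U, I


def fg_loglik_score_hessian_naive(data: _FGData, beta):
    """Direct O(n^2) double-loop reference implementation (validation only)."""
    beta = np.asarray(beta, dtype=float)
    X = data.X
    eta = X @ beta
    r = np.exp(eta - eta.max())
    W = data.weights_matrix()
    ll, score, H = 0.0, np.zeros(data.p), np.zeros((data.p, data.p))
    for k, i in enumerate(data.ev):
        w = W[k] * r
        D = w.sum()
        xbar = (w[:, None] * X).sum(axis=0) / D
        ll += (eta[i] - eta.max()) - np.log(D)
        score += X[i] - xbar
        M = (w[:, None, None] * X[:, :, None] * X[:, None, :]).sum(axis=0) / D
        H -= M - np.outer(xbar, xbar)
    return {"loglik": float(ll), "score": score, "hessian": H}


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class FineGray:
    """Fine-Gray subdistribution hazard model for competing-risks data.

    Parameters
    ----------
    time : array-like
        Time from the (landmark) origin to event or censoring, > 0.
    event : array-like
        0 censored, 1 event of interest, 2 competing event.
    exog : array-like or DataFrame
        Covariate matrix; column names taken from a DataFrame.
    censoring : CensoringDistribution, optional
        Pre-fitted censoring KM (e.g., from a training split); estimated from
        the data when omitted.
    """

    def __init__(self, time, event, exog, feature_names=None, censoring=None):
        if isinstance(exog, pd.DataFrame):
            feature_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.feature_names = feature_names or [f"x{j}" for j in range(exog.shape[1])]
        self.center_ = exog.mean(axis=0)
        self._data = _FGData(time, event, exog - self.center_, censoring=censoring)
        self.n, self.p = self._data.n, self._data.p

    @classmethod
    def from_dataframe(cls, df, duration_col="time", event_col="event", covariates=None,
                       censoring=None):
        covariates = covariates or [
            c for c in df.columns if c not in (duration_col, event_col, "id")
        ]
        return cls(df[duration_col], df[event_col], df[covariates], censoring=censoring)

    @property
    def censoring(self) -> CensoringDistribution:
        return self._data.G

    # -- likelihood surface -------------------------------------------------
    def loglike(self, beta):
        return fg_loglik_score_hessian(self._data, beta, want=("loglik",))["loglik"]

    def score(self, beta):
        return fg_loglik_score_hessian(self._data, beta, want=("score",))["score"]

    def hessian(self, beta):
        return fg_loglik_score_hessian(self._data, beta, want=("hessian",))["hessian"]

    # -- estimation ----------------------------------------------------------
    def fit(self, start=None, tol=1e-8, maxiter=50) -> "FineGrayResults":
        """Newton-Raphson to gradient max-norm ``tol`` with step-halving."""
        if self._data.ev.size == 0:
            raise ValueError("cannot fit: no cause-1 events in the data")
        if np.linalg.matrix_rank(self._data.X) < self.p:
            raise ValueError("design matrix is rank deficient")
        beta = np.zeros(self.p) if start is None else np.asarray(start, dtype=float)
        parts = fg_loglik_score_hessian(self._data, beta)
        ll = parts["loglik"]
        # acceptance slack for the line search: the log-likelihood is a sum of
        # O(n) terms, so recomputation jitters by ~eps*|ll|
        slack = 1e3 * np.finfo(float).eps * max(abs(ll), 1.0)
        for it in range(1, maxiter + 1):
            g, H = parts["score"], parts["hessian"]
            gnorm = np.abs(g).max()
            if gnorm < tol:
                break
            step = np.linalg.solve(-H, g)
            if np.abs(step).max() < 1e-11:  # numerically at the optimum
                beta = beta + step
                parts = fg_loglik_score_hessian(self._data, beta)
                break
            lam = 1.0
            for _ in range(30):
                cand = beta + lam * step
                ll_new = self.loglike(cand)
                if ll_new > ll - slack:
                    break
                lam /= 2.0
            beta, ll = cand, ll_new
            if np.abs(beta).max() > _BETA_BOUND:
                warnings.warn(
                    "possible separation: coefficient capped at "
                    f"+/-{_BETA_BOUND}", RuntimeWarning,
                )
                beta = np.clip(beta, -_BETA_BOUND, _BETA_BOUND)
            parts = fg_loglik_score_hessian(self._data, beta)
            ll = parts["loglik"]
        else:
            gnorm = np.abs(parts["score"]).max()
            raise RuntimeError(
                f"Newton did not converge in {maxiter} iterations "
                f"(gradient max-norm {gnorm:.3e})"
            )
        gnorm = float(np.abs(parts["score"]).max())
        cov = np.linalg.inv(-parts["hessian"])
        baseline = self.baseline_cumhaz(beta)
        return FineGrayResults(self, beta, cov, ll, it, gnorm, baseline)

    def fit_regularized(self, **kwargs):
        """MCP-penalized path; see :func:`crlandmark.mcp.fit_mcp_path`."""
        from .mcp import fit_mcp_path

        return fit_mcp_path(self, **kwargs)

    def baseline_cumhaz(self, beta) -> StepFunction:
        """Breslow-type baseline cumulative subdistribution hazard.

        Anchored at the covariate mean (the model's centering vector): the
        denominators use exp((x - center)' beta).
        """
        d = self._data
        eta = d.X @ np.asarray(beta, dtype=float)
        r = np.exp(eta - eta.max())
        c = np.where(d.is2, r / d.Gm_T, 0.0)
        suf_r = np.concatenate([_suffix_cumsum(r), [0.0]])
        pre_c = np.concatenate([[0.0], np.cumsum(c)])
        D = (suf_r[d.a] + d.Gm_s * pre_c[d.a]) * np.exp(eta.max())
        s = d.t[d.ev]
        # aggregate tied event times (Breslow)
        times, inv = np.unique(s, return_inverse=True)
        inc = np.bincount(inv, weights=1.0 / D, minlength=times.size)
        return StepFunction(times, np.cumsum(inc), baseline=0.0)


class FineGrayResults:
    """Fitted Fine-Gray model: estimates, uncertainty, baseline, prediction."""

    def __init__(self, model, params, cov_params, loglike, niter, grad_norm, baseline):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self._cov = np.asarray(cov_params, dtype=float)
        self.llf = float(loglike)
        self.niter = int(niter)
        self.grad_norm = float(grad_norm)
        self.baseline_cumhaz_ = baseline  # StepFunction, anchored at center_
        self.feature_names = list(model.feature_names)
        self.center_ = model.center_.copy()

    @property
    def bse(self):
        return np.sqrt(np.diag(self._cov))

    def cov_params(self):
        return self._cov

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha=0.05):
        q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def linear_predictor(self, X):
        X = self._conform(X)
        return (X - self.center_) @ self.params

    def _conform(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"unknown/missing schema columns: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.params.size:
            raise ValueError(
                f"expected {self.params.size} columns, got {X.shape[1]}"
            )
        return X

    def predict_cif(self, X, horizons):
        """Predicted cause-1 cumulative incidence F1(h | x).

        F1(h|x) = 1 - exp(-Lambda10(h) * exp((x - center)'beta)); the baseline
        is carried forward flat beyond its last jump.  Returns (n, H) array
        (squeezed to (n,) for scalar ``horizons``).
        """
        scalar = np.isscalar(horizons)
        horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
        if np.any(horizons < 0):
            raise ValueError("horizons must be >= 0")
        lp = self.linear_predictor(X)
        lam = self.baseline_cumhaz_(horizons)
        F = 1.0 - np.exp(-np.outer(np.exp(lp), np.atleast_1d(lam)))
        return F[:, 0] if scalar else F

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "se(coef)": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
                "[0.025": ci[:, 0],
                "0.975]": ci[:, 1],
            },
            index=pd.Index(self.feature_names, name="covariate"),
        )
        return tab

    def to_dict(self):
        """JSON-serializable export (schema, centering, beta, baseline)."""
        return {
            "feature_names": self.feature_names,
            "center": self.center_.tolist(),
            "beta": self.params.tolist(),
            "bse": self.bse.tolist(),
            "baseline_times": self.baseline_cumhaz_.times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz_.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        res = cls.__new__(cls)
        res.model = None
        res.params = np.asarray(d["beta"], dtype=float)
        res._cov = np.diag(np.asarray(d.get("bse", np.zeros_like(res.params))) ** 2)
        res.llf = float("nan")
        res.niter = 0
        res.grad_norm = float("nan")
        res.baseline_cumhaz_ = StepFunction(
            np.asarray(d["baseline_times"], dtype=float),
            np.asarray(d["baseline_cumhaz"], dtype=float),
            baseline=0.0,
        )
        res.feature_names = list(d["feature_names"])
        res.center_ = np.asarray(d["center"], dtype=float)
        return res


def fg_fit(time, event, X, penalty=None, censoring=None, **options):
    """Functional front door: unpenalized fit or MCP path + post-selection refit.

    ``penalty=None`` returns :class:`FineGrayResults`; ``penalty=('mcp', lam,
    gamma)`` runs coordinate descent at that single penalty value and returns
    the coefficient vector refit-free (see :mod:`crlandmark.mcp` for paths).
    """
    model = FineGray(time, event, X, censoring=censoring)
    if penalty is None:
        return model.fit(**options)
    kind, lam, gamma = penalty
    if kind != "mcp":
        raise ValueError(f"unknown penalty {kind!r}")
    path = model.fit_regularized(lambdas=np.array([lam]), gamma=gamma, **options)
    return path
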