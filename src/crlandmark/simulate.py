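"""Synthetic EHR cohort generator with competing kidney-failure/death outcomes.

The outcome process follows the classic indirect-CIF simulation design for
subdistribution-hazard models: the cause-1 (kidney failure) cumulative
incidence is specified directly as

    F1(t | x) = 1 - [1 - p * (1 - exp(-t / tau))]**exp(x' beta1)

so that ``beta1`` is *exactly* the vector of subdistribution log-hazard
ratios, ``p`` (``p_mass``) is the asymptotic cause-1 incidence at x = 0,
and ``tau`` (``time_scale``, default 1 year) stretches the time axis.
Cause-2 (death) times, conditional on not experiencing cause 1, are
exponential with rate exp(x' beta2).  Censoring is exponential at
``censor_rate`` per year, truncated administratively at ``admin_horizon``.

Two surfaces are provided:

``simulate_survival``
    the bare competing-risks records (time, cause, covariates, latent truth)
    used for estimator validation;

``simulate_cohort``
    the same subjects dressed up as long-format EHR tables (patients, labs,
    medications, diagnoses) with irregular visit dates, last-value semantics,
    kidney-failure code/eGFR trails that the outcome-derivation rules can
    reconstruct, and configurable missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import spawn_rng

DAYS_PER_YEAR = 365.25

#: lab names always emitted by the EHR dressing (clinical flavour; the
#: outcome-driving covariates are additionally emitted as ``lab_x*`` / ``med_x*``)
CLINICAL_LABS = ("egfr", "sbp", "hba1c", "uacr", "ldl")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort data-generating process.

    Attributes
    ----------
    n_subjects : int
        Cohort size.
    beta1, beta2 : array-like
        True cause-1 subdistribution and cause-2 log-hazard ratios; their
        common length sets the number of covariates.
    p_mass : float
        Asymptotic cause-1 incidence at covariates = 0, in (0, 1).
    censor_rate : float
        Exponential censoring rate per year (0 disables random censoring).
    admin_horizon : float
        Administrative censoring time in years (``np.inf`` disables it).
    missing_rates : dict
        Map lab name -> fraction of its rows deleted completely at random.
    n_visits_mean : float
        Mean number of visits per year (Poisson).
    covariate_kinds : tuple or None
        Per-column 'binary' / 'normal'; default alternates binary (Bern 0.5)
        every third column, standard normal otherwise.
    seed : int
        Master seed; identical configs give byte-identical output.
    """

    n_subjects: int
    beta1: tuple
    beta2: tuple
    p_mass: float = 0.35
    censor_rate: float = 0.05
    admin_horizon: float = 20.0
    missing_rates: dict = field(default_factory=dict)
    n_visits_mean: float = 2.0
    covariate_kinds: tuple | None = None
    lp1_offset: float = 0.0  # baseline subdistribution-hazard log-scale shift
    lp2_offset: float = 0.0
    time_scale: float = 1.0  # years; stretches the cause-1 latent time axis
    death_rate: float = 1.0  # baseline cause-2 rate per year at covariates = 0
    seed: int = 0

    def __post_init__(self):
        b1 = np.asarray(self.beta1, dtype=float)
        b2 = np.asarray(self.beta2, dtype=float)
        if not (np.all(np.isfinite(b1)) and np.all(np.isfinite(b2))):
            raise ValueError("beta1/beta2 must be finite")
        if b1.shape != b2.shape:
            raise ValueError("beta1 and beta2 must have equal length")
        if not 0.0 < self.p_mass < 1.0:
            raise ValueError("p_mass must lie in (0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {name!r} must be in [0, 1)")
        object.__setattr__(self, "beta1", tuple(b1))
        object.__setattr__(self, "beta2", tuple(b2))

    @property
    def n_covariates(self):
        return len(self.beta1)

    def kinds(self):
        if self.covariate_kinds is not None:
            if len(self.covariate_kinds) != self.n_covariates:
                raise ValueError("covariate_kinds length must match beta1")
            return tuple(self.covariate_kinds)
        return tuple(
            "binary" if i % 3 == 0 else "normal" for i in range(self.n_covariates)
        )


@dataclass
class RawCohort:
    """Long-format EHR tables plus the simulation truth table."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    meds: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self):
        ids = set(self.patients["id"])
        for name in ("labs", "meds", "diagnoses"):
            tab = getattr(self, name)
            if len(tab) and not set(tab["id"]).issubset(ids):
                raise ValueError(f"{name} contains ids absent from patients")
        return self

    def copy(self):
        return RawCohort(
            self.patients.copy(),
            self.labs.copy(),
            self.meds.copy(),
            self.diagnoses.copy(),
            None if self.truth is None else self.truth.copy(),
        )


def _draw_covariates(config, rng):
    n, p = config.n_subjects, config.n_covariates
    X = np.empty((n, p))
    for j, kind in enumerate(config.kinds()):
        if kind == "binary":
            X[:, j] = rng.binomial(1, 0.5, size=n)
        elif kind == "normal":
            X[:, j] = rng.standard_normal(n)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return X


def latent_cif1(t, lp1, p_mass, time_scale=1.0):
    """Closed-form cause-1 CIF F1(t | x) of the data-generating process."""
    t = np.asarray(t, dtype=float)
    return 1.0 - (1.0 - p_mass * (1.0 - np.exp(-t / time_scale))) ** np.exp(lp1)


def simulate_survival(config: SimulationConfig) -> pd.DataFrame:
    """Draw bare competing-risks records from the configured process.

    Returns a frame with ``id``, observed ``time`` (years) and ``event``
    (0 censored / 1 kidney failure / 2 death), covariates ``x0..x{p-1}``,
    and latent truth columns (``lp1``, ``lp2``, ``latent_cause``,
    ``latent_time``).
    """
    rng = spawn_rng(config.seed, "survival")
    n = config.n_subjects
    X = _draw_covariates(config, rng)
    b1 = np.asarray(config.beta1)
    b2 = np.asarray(config.beta2)
    lp1 = X @ b1 + config.lp1_offset
    lp2 = X @ b2 + config.lp2_offset
    p = config.p_mass

    pi1 = 1.0 - (1.0 - p) ** np.exp(lp1)
    cause = np.where(rng.uniform(size=n) < pi1, 1, 2)

    u = rng.uniform(size=n)
    # cause 1: invert F1(t)/F1(inf) = u
    inner = (1.0 - u * pi1) ** np.exp(-lp1)
    with np.errstate(divide="ignore"):
        t1 = -config.time_scale * np.log1p(-(1.0 - inner) / p)
    t2 = rng.exponential(size=n) / (config.death_rate * np.exp(lp2))
    latent_time = np.where(cause == 1, t1, t2)

    if config.censor_rate > 0:
        cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        cens = np.full(n, np.inf)
    cens = np.minimum(cens, config.admin_horizon)

    time = np.minimum(latent_time, cens)
    event = np.where(latent_time <= cens, cause, 0)

    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(config.n_covariates)])
    df.insert(0, "id", np.arange(n))
    df["time"] = time
    df["event"] = event.astype(int)
    df["lp1"] = lp1
    df["lp2"] = lp2
    df["latent_cause"] = cause
    df["latent_time"] = latent_time
    return df


def _dates(index_date, years):
    """index_date + years, elementwise, rounded to days."""
    return index_date + pd.to_timedelta(np.round(np.asarray(years) * DAYS_PER_YEAR), "D")


def simulate_cohort(config: SimulationConfig) -> RawCohort:
    """Generate the full EHR-like cohort (patients/labs/meds/diagnoses + truth).

    Cause-1 subjects receive two coded kidney-failure entries 60 days apart
    and a final pair of eGFR values < 15 at the event date, so the composite
    outcome rule reconstructs the simulated event.  Cause-2 subjects get a
    death date; censored subjects end with a visit at their censoring date.
    """
    surv = simulate_survival(config)
    rng = spawn_rng(config.seed, "ehr")
    n = config.n_subjects

    index_date = pd.Timestamp("2008-01-01") + pd.to_timedelta(
        rng.integers(0, 365 * 4, size=n), "D"
    )
    age = np.clip(rng.normal(60.0, 8.0, size=n), 30, 90)
    birth_date = index_date - pd.to_timedelta(np.round(age * DAYS_PER_YEAR), "D")
    female = rng.uniform(size=n) < 0.07
    race = rng.choice(["white", "black", "other"], size=n, p=[0.68, 0.22, 0.10])
    ethnicity = rng.choice(["not_hispanic", "hispanic"], size=n, p=[0.937, 0.063])

    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    exit_date = _dates(index_date, time)
    death_date = pd.Series(pd.NaT, index=range(n))
    death_date[event == 2] = exit_date[event == 2]

    patients = pd.DataFrame(
        {
            "id": surv["id"],
            "sex": np.where(female, "F", "M"),
            "race": race,
            "ethnicity": ethnicity,
            "birth_date": birth_date,
            "index_date": index_date,
            "death_date": death_date.to_numpy(),
        }
    )

    X = surv[[f"x{j}" for j in range(config.n_covariates)]].to_numpy()
    kinds = config.kinds()

    # ---- visits & labs -------------------------------------------------
    followup = np.maximum(time, 0.05)
    n_visits = 1 + rng.poisson(config.n_visits_mean * np.minimum(followup + 2.0, 25.0))
    lab_rows = []
    egfr_base = np.clip(rng.normal(85.0, 15.0, size=n), 20, 140)
    # cause-1 subjects decline towards dialysis range by their event time
    slope = np.where(event == 1, (egfr_base - 12.0) / np.maximum(time, 0.2), 1.0)
    sbp_true = 135.0 + 15.0 * (X[:, 1] if X.shape[1] > 1 else np.zeros(n))
    hba1c_true = 6.5 + 0.8 * (X[:, 2] if X.shape[1] > 2 else np.zeros(n))
    log_uacr_true = rng.normal(2.5, 1.2, size=n)

    for i in range(n):
        k = n_visits[i]
        vt = np.sort(rng.uniform(-2.0, followup[i], size=k))
        vt[-1] = time[i]  # last visit at exit (censoring-at-last-visit semantics)
        tpos = np.maximum(vt, 0.0)
        egfr = np.clip(egfr_base[i] - slope[i] * tpos, 5.0, None) + rng.normal(
            0, 2.0, size=k
        )
        if event[i] == 1:
            # confirmed dialysis-range pair at the event date
            pair_t = np.array([time[i], time[i] + 60.0 / DAYS_PER_YEAR])
            vt = np.concatenate([vt, pair_t])
            egfr = np.concatenate([egfr, rng.uniform(6.0, 13.0, size=2)])
            k += 2
        rec = {
            "egfr": np.clip(egfr, 3.0, None),
            "sbp": sbp_true[i] + rng.normal(0, 6.0, size=k),
            "hba1c": np.clip(hba1c_true[i] + rng.normal(0, 0.3, size=k), 4.0, None),
            "ldl": np.clip(rng.normal(110.0, 25.0, size=k), 30, None),
            "uacr": np.exp(log_uacr_true[i] + rng.normal(0, 0.25, size=k)),
        }
        for j, kind in enumerate(kinds):
            if kind == "normal":
                rec[f"lab_x{j}"] = X[i, j] + rng.normal(0, 0.1, size=k)
        for name, vals in rec.items():
            for t_v, v in zip(vt, vals):
                lab_rows.append((i, t_v, name, v))

    labs = pd.DataFrame(lab_rows, columns=["id", "years", "name", "value"])
    labs["date"] = patients.loc[labs["id"], "index_date"].to_numpy() + pd.to_timedelta(
        np.round(labs["years"] * DAYS_PER_YEAR), "D"
    )
    labs = labs[["id", "date", "name", "value", "years"]]

    # ---- medications (binary covariates as dispensation trails) --------
    med_rows = []
    for j, kind in enumerate(kinds):
        if kind != "binary":
            continue
        cls = f"med_x{j}"
        for i in np.flatnonzero(X[:, j] > 0.5):
            t_fill = np.arange(-0.1, followup[i], 0.25)
            for t_f in t_fill:
                med_rows.append((i, t_f, cls, 90))
    meds = pd.DataFrame(med_rows, columns=["id", "years", "class", "days_supply"])
    if len(meds):
        meds["date"] = patients.loc[meds["id"], "index_date"].to_numpy() + pd.to_timedelta(
            np.round(meds["years"] * DAYS_PER_YEAR), "D"
        )
    else:
        meds["date"] = pd.Series(dtype="datetime64[ns]")
    meds = meds[["id", "date", "class", "days_supply", "years"]]

    # ---- diagnoses (kidney-failure code trail for cause-1 subjects) ----
    dx_rows = []
    for i in np.flatnonzero(event == 1):
        dx_rows.append((i, time[i], "esrd"))
        dx_rows.append((i, time[i] + 60.0 / DAYS_PER_YEAR, "esrd"))
    diagnoses = pd.DataFrame(dx_rows, columns=["id", "years", "code_group"])
    if len(diagnoses):
        diagnoses["date"] = patients.loc[diagnoses["id"], "index_date"].to_numpy() + (
            pd.to_timedelta(np.round(diagnoses["years"] * DAYS_PER_YEAR), "D")
        )
    else:
        diagnoses["date"] = pd.Series(dtype="datetime64[ns]")
    diagnoses = diagnoses[["id", "date", "code_group", "years"]]

    truth = surv[["id", "time", "event", "lp1", "lp2", "latent_cause", "latent_time"]]
    truth = truth.join(surv[[f"x{j}" for j in range(config.n_covariates)]])
    truth = truth.rename(
        columns={"lp1": "true_linear_predictor_1", "lp2": "true_linear_predictor_2"}
    )

    cohort = RawCohort(patients, labs, meds, diagnoses, truth).validate()
    if config.missing_rates:
        cohort = inject_missingness(cohort, config.missing_rates, seed=config.seed)
    return cohort


def simulate_from_model(results, X, seed=0, other_cause_time=None):
    """Draw competing-risks records whose cause-1 process IS a fitted model.

    Subjects experience the cause-1 event with probability
    F1(inf | x) = 1 - exp(-Lambda_max * exp(lp)) at a time drawn by inverting
    the model's own step-function CIF; everyone else exits as a competing
    event beyond the last baseline jump (``other_cause_time``), so the
    cause-1 cumulative incidence of the sample matches the model exactly.
    Used for calibration self-consistency checks.
    """
    rng = spawn_rng(seed, "from-model")
    lp = results.linear_predictor(X)
    base = results.baseline_cumhaz_
    lam_max = float(base.values[-1])
    t_max = float(base.times[-1])
    if other_cause_time is None:
        other_cause_time = t_max * 1.01
    pi1 = 1.0 - np.exp(-lam_max * np.exp(lp))
    n = len(lp)
    u = rng.uniform(size=n)
    is1 = u < pi1
    # invert F1(t|x) = u  <=>  Lambda(t) = -log(1-u) * exp(-lp)
    target = -np.log1p(-u) * np.exp(-lp)
    idx = np.searchsorted(base.values, np.minimum(target, lam_max) - 1e-12)
    t1 = base.times[np.clip(idx, 0, base.times.size - 1)]
    time = np.where(is1, t1, other_cause_time)
    event = np.where(is1, 1, 2)
    return pd.DataFrame({"time": time, "event": event})


@dataclass(frozen=True)
class MARRule:
    """Missing-at-random rule: deletion probability depends on a driver lab.

    The subject's first observed value of ``driver`` decides which deletion
    probability applies (``p_above`` if value >= threshold else ``p_below``).
    """

    driver: str
    threshold: float
    p_above: float
    p_below: float


def inject_missingness(cohort, missing_rates, mar_rules=None, seed=0):
    """Delete lab rows per feature, MCAR by default or MAR via ``mar_rules``.

    Raises if a named feature has no rows in the labs table.
    """
    rng = spawn_rng(seed, "missingness")
    mar_rules = mar_rules or {}
    out = cohort.copy()
    labs = out.labs
    known = set(labs["name"].unique())
    keep = np.ones(len(labs), dtype=bool)
    for name, rate in {**missing_rates, **{k: None for k in mar_rules}}.items():
        if name not in known:
            raise ValueError(
                f"unknown lab feature {name!r}; known features: {sorted(known)}"
            )
        mask = (labs["name"] == name).to_numpy()
        if name in mar_rules:
            rule = mar_rules[name]
            drv = (
                labs[labs["name"] == rule.driver]
                .sort_values("date")
                .groupby("id")["value"]
                .first()
            )
            subj_val = labs.loc[mask, "id"].map(drv)
            p = np.where(subj_val >= rule.threshold, rule.p_above, rule.p_below)
        else:
            if rate == 0:
                continue
            p = rate
        drop = rng.uniform(size=int(mask.sum())) < p
        keep[np.flatnonzero(mask)[drop]] = False
    out.labs = labs[keep].reset_index(drop=True)
    return out
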