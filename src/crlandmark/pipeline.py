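"""End-to-end study pipeline: simulate -> landmarks -> screen -> fit/tune ->
evaluate -> transport -> benchmark -> explain -> thresholds.

Every stage communicates through serialized artifacts in the run directory;
all randomness is derived from the manifest's master seed.  Metric tables
are tidy (model x landmark x horizon) so the discrimination and calibration
grids can be read side by side.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equations import RiskEquationSpec, compute_equation_risk, recalibrate_equation
from .finegray import FineGray
from .interpret import select_threshold, shap_values
from .landmark import build_landmark, fit_missingness_policy, split_cohort
from .mcp import mcp_path_cv
from .metrics import brier_cr, calibration, timedep_auprc, timedep_auroc
from .outcomes import derive_esrd_outcome
from .simulate import RawCohort, SimulationConfig, simulate_cohort
from .transport import refit_vs_recalibrate

logger = logging.getLogger(__name__)

TABLES = ("patients", "labs", "meds", "diagnoses", "truth")
DATE_COLS = {"patients": ["birth_date", "index_date", "death_date"],
             "labs": ["date"], "meds": ["date"], "diagnoses": ["date"]}


@dataclass
class RunConfig:
    """Human-editable configuration of a full pipeline run."""

    simulation: dict
    landmarks: tuple = (1.0, 5.0, 10.0)
    horizons: tuple = (1.0, 5.0, 10.0)
    split_fraction: float = 0.7
    screening: dict = field(default_factory=lambda: {
        "threshold": 0.1, "alpha": 0.05, "horizon": 10.0,
        "adjusters": ["age", "male", "black_race"],
    })
    mcp: dict = field(default_factory=lambda: {
        "gamma": 3.0, "folds": 5, "cv_horizon": 10.0, "n_lambda": 25,
    })
    calibration_groups: int = 10
    shap_samples: int = 64
    shap_subjects: int = 200
    # clinical cutoffs for heavily-missing markers (UACR: normo-/micro-/
    # macro-albuminuria at 30 and 300 mg/g)
    bin_edges: dict = field(default_factory=lambda: {"uacr": (30.0, 300.0)})
    seed: int = 0
    out_dir: str = "run"

    def __post_init__(self):
        self.landmarks = tuple(float(s) for s in self.landmarks)
        self.horizons = tuple(sorted(float(h) for h in self.horizons))

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_tables(cohort: RawCohort, out_dir, fmt="csv"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in TABLES:
        tab = getattr(cohort, name)
        if tab is None:
            continue
        if fmt == "csv":
            tab.to_csv(out / f"{name}.csv", index=False)
        elif fmt == "parquet":
            tab.to_parquet(out / f"{name}.parquet", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return out


def read_cohort(in_dir) -> RawCohort:
    """Read CSV or Parquet cohort tables with validation.

    Dates must be ISO-8601; a malformed date raises with the row number.
    """
    in_dir = Path(in_dir)
    tabs = {}
    for name in TABLES:
        csv, pq = in_dir / f"{name}.csv", in_dir / f"{name}.parquet"
        if pq.exists():
            tabs[name] = pd.read_parquet(pq)
        elif csv.exists():
            tabs[name] = pd.read_csv(csv)
        elif name == "truth":
            tabs[name] = None
        else:
            raise FileNotFoundError(f"missing required table {name!r} in {in_dir}")
        if tabs[name] is not None:
            for col in DATE_COLS.get(name, []):
                if col not in tabs[name].columns:
                    raise ValueError(f"{name}: missing required column {col!r}")
                try:
                    tabs[name][col] = pd.to_datetime(tabs[name][col], format="ISO8601")
                except (ValueError, TypeError):
                    parsed = pd.to_datetime(tabs[name][col], errors="coerce",
                                            format="ISO8601")
                    bad = parsed.isna() & tabs[name][col].notna()
                    row = int(np.flatnonzero(bad)[0]) if bad.any() else -1
                    raise ValueError(
                        f"{name}.{col}: malformed date at row {row}"
                    ) from None
    return RawCohort(**tabs).validate()


def _evaluate(label, s, test, risk_fn, horizons, groups, rows, cal_rows):
    max_t = test.time.max()
    for h in horizons:
        if h >= max_t:
            continue
        risk = np.asarray(risk_fn(h))
        row = {"model": label, "landmark": s, "horizon": h}
        try:
            row["auroc"] = timedep_auroc(test.time, test.cause, risk, h).auc
            row["auprc"] = timedep_auprc(test.time, test.cause, risk, h).auc
            row["brier"] = brier_cr(test.time, test.cause, risk, h)
            rep = calibration(test.time, test.cause, risk, h, groups=groups)
            row["cal_slope"] = rep.slope
            row["cal_slope_se"] = rep.slope_se
            for g in range(rep.n_groups):
                cal_rows.append({
                    "model": label, "landmark": s, "horizon": h, "group": g,
                    "mean_predicted": rep.group_pred[g],
                    "mean_pseudo_observed": rep.group_obs[g],
                    "n": int(rep.group_size[g]),
                })
        except ValueError as exc:
            row["note"] = str(exc)
        rows.append(row)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    t_start = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "version": __version__, "stages": {}}
    stage_t = _time.time()

    def _mark(stage, **info):
        nonlocal stage_t
        manifest["stages"][stage] = {
            "seconds": round(_time.time() - stage_t, 2), **info
        }
        stage_t = _time.time()
        logger.info("stage %s done: %s", stage, info)

    try:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
        cohort = simulate_cohort(sim_cfg)
        write_tables(cohort, out / "cohort")
        _mark("simulate", n_subjects=sim_cfg.n_subjects)

        outcomes = derive_esrd_outcome(cohort)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        _mark("outcomes", events=int((outcomes["cause"] == 1).sum()),
              deaths=int((outcomes["cause"] == 2).sum()))

        # ---- landmarks with persistent split ---------------------------
        # the missingness policy (bins, imputer, scaling) is fitted once on
        # the first landmark's training split and applied frozen everywhere,
        # so the feature space is identical across landmarks
        datasets = {}
        split_map = None
        schema = None
        for s in config.landmarks:
            ds = build_landmark(cohort, outcomes, s)
            if split_map is None:
                ds = split_cohort(ds, fraction=config.split_fraction,
                                  seed=config.seed)
                split_map = ds.frame.set_index("id")["split"]
            else:
                ds = split_cohort(ds, inherit=split_map)
            if schema is None:
                schema = fit_missingness_policy(
                    ds.train, bin_edges=config.bin_edges, seed=config.seed)
            datasets[s] = {"train": schema.transform(ds.train),
                           "test": schema.transform(ds.test),
                           "full": schema.transform(ds)}
            _mark(f"landmark_{s:g}", n=len(ds.frame),
                  n_train=len(ds.train.frame), cases=int((ds.cause == 1).sum()))

        # ---- screening + MCP selection at the first landmark ------------
        from .screening import screen_features

        s0 = config.landmarks[0]
        train0 = datasets[s0]["train"]
        scr = screen_features(
            train0, adjusters=config.screening["adjusters"],
            horizon=config.screening["horizon"],
            threshold=config.screening["threshold"],
            alpha=config.screening["alpha"],
        )
        scr.to_csv(out / "screening.csv")
        _mark("screening", retained=len(scr.retained))

        feats = scr.retained
        pf = np.array([0.0 if c in config.screening["adjusters"] else 1.0
                       for c in feats])
        cv_h = min(config.mcp["cv_horizon"], float(np.quantile(train0.time, 0.9)))
        path, refit0 = mcp_path_cv(
            train0.time, train0.cause, train0.frame[feats],
            folds=config.mcp["folds"], horizon=cv_h,
            seed=config.seed, gamma=config.mcp["gamma"],
            penalty_factor=pf, n_lambda=config.mcp["n_lambda"],
        )
        selected = [refit0.feature_names[j] for j in range(len(refit0.feature_names))]
        _mark("mcp", selected=len(selected),
              lambda_=path.selected_lambda,
              cv_auroc=float(path.cv_scores[path.selected_index]))

        # ---- landmark models: refit the selected support everywhere ----
        models, rows, cal_rows = {}, [], []
        for s in config.landmarks:
            tr, te = datasets[s]["train"], datasets[s]["test"]
            res = FineGray(tr.time, tr.cause, tr.frame[selected]).fit()
            models[s] = res
            with open(out / f"model_lm{s:g}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=1)
            _evaluate("dynamic_fg", s, te,
                      lambda h, res=res, te=te: res.predict_cif(te.frame[selected], h),
                      config.horizons, config.calibration_groups, rows, cal_rows)
        _mark("fit_evaluate")

        # ---- benchmark equations (recalibrated on train, eval on test) --
        for eq_name in ("kfre4", "recode_esrd_synthetic"):
            spec = RiskEquationSpec.load_builtin(eq_name)
            for s in config.landmarks:
                tr, te = datasets[s]["train"], datasets[s]["test"]
                for engine in ("cox", "fine-gray"):
                    try:
                        recal = recalibrate_equation(spec, tr, engine=engine)
                    except ValueError as exc:
                        logger.warning("%s %s: %s", eq_name, engine, exc)
                        continue
                    _evaluate(
                        f"{eq_name}_{engine}", s, te,
                        lambda h, r=recal, te=te: r.predict_cif(te.frame, h),
                        config.horizons, config.calibration_groups, rows, cal_rows,
                    )
        _mark("benchmark")

        # ---- refit vs recalibrate at later landmarks --------------------
        rvr = []
        for s in config.landmarks[1:]:
            rvr.append(refit_vs_recalibrate(models[s0], datasets[s]["full"],
                                            horizons=config.horizons))
        if rvr:
            pd.concat(rvr).to_csv(out / "refit_vs_recalibrate.csv", index=False)
        _mark("transport")

        # ---- SHAP + thresholds ------------------------------------------
        te0 = datasets[s0]["test"]
        sub = te0.frame[selected].head(config.shap_subjects)
        h_shap = config.horizons[-1]
        rep = shap_values(models[s0], sub, h=h_shap,
                          n_samples=config.shap_samples, seed=config.seed)
        rep.ranking.rename("mean_abs_shap").to_csv(out / "shap_ranking.csv")
        thr_rows = []
        for s in config.landmarks:
            te = datasets[s]["test"]
            for h in config.horizons:
                if h >= te.time.max():
                    continue
                risk = models[s].predict_cif(te.frame[selected], h)
                try:
                    roc = timedep_auroc(te.time, te.cause, risk, h)
                except ValueError:
                    continue
                for method in ("youden", "top_left"):
                    ch = select_threshold(roc, method)
                    thr_rows.append({
                        "landmark": s, "horizon": h, "method": method,
                        "threshold": ch.threshold,
                        "sensitivity": ch.sensitivity,
                        "specificity": ch.specificity,
                    })
        pd.DataFrame(thr_rows).to_csv(out / "thresholds.csv", index=False)
        _mark("explain_thresholds")

        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)
    except Exception as exc:
        manifest["failed_stage"] = f"after {sorted(manifest['stages'])}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    manifest["total_seconds"] = round(_time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
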