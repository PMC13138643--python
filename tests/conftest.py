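import numpy as np
import pandas as pd
import pytest

from crlandmark import FineGray, SimulationConfig, simulate_survival
from crlandmark.landmark import LandmarkDataset

COLS3 = ["x0", "x1", "x2"]


@pytest.fixture(scope="session")
def surv_small():
    """400-subject competing-risks draw shared by estimator tests."""
    return simulate_survival(
        SimulationConfig(400, (0.5, -0.5, 0.3), (0.2, 0.0, -0.2),
                         censor_rate=0.15, seed=20260927)
    )


@pytest.fixture(scope="session")
def surv_10k():
    """Large draw with rarer events for calibration/transport checks."""
    return simulate_survival(
        SimulationConfig(10_000, (0.5, -0.5, 0.3), (0.2, 0.1, -0.1),
                         p_mass=0.15, censor_rate=0.1, seed=42)
    )


@pytest.fixture(scope="session")
def fitted_10k(surv_10k):
    return FineGray(surv_10k["time"], surv_10k["event"], surv_10k[COLS3]).fit()


@pytest.fixture(scope="session")
def nocompete_300():
    """No competing events, ~20% censoring (cause-2 exponential independent
    of covariates, relabelled as censoring)."""
    df = simulate_survival(
        SimulationConfig(300, (0.5, -0.5, 0.3), (0.0, 0.0, 0.0),
                         p_mass=0.85, censor_rate=0.05, seed=5)
    ).copy()
    df.loc[df["event"] == 2, "event"] = 0
    return df


def make_landmark(df, s=5.0, feature_cols=COLS3, split_seed=0, fraction=0.7):
    """Wrap a bare survival frame as a split LandmarkDataset at landmark s."""
    from crlandmark import split_cohort

    frame = df.rename(columns={"time": "residual_time", "event": "cause"})
    frame = frame[["id", "residual_time", "cause"] + list(feature_cols)].copy()
    ds = LandmarkDataset(s, frame, list(feature_cols))
    return split_cohort(ds, fraction=fraction, seed=split_seed)


@pytest.fixture
def toy_roc():
    from crlandmark.metrics import ROCResult

    return ROCResult(
        horizon=1.0,
        thresholds=np.array([0.3, 0.2, 0.1]),
        tpr=np.array([0.5, 0.7, 0.9]),
        fpr=np.array([0.1, 0.2, 0.5]),
        auc=0.8,
    )
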