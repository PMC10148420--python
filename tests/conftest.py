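"""Shared fixtures: small synthetic cohorts and survival data generators."""

import numpy as np
import pandas as pd
import pytest

import reopair as rp

#: study conditions for planted-signal recovery checks: n=400 with ~60%
#: events and planted log-hazard magnitudes of 1.2-1.5
RECOVERY_KW = dict(
    n_samples=400,
    censor_rate=0.40,
    beta_true=(1.2, -1.2, 1.5, -1.5, 1.2),
    n_planted_pairs=5,
)


def make_survival(time, event, **clinical) -> rp.SurvivalTable:
    """Survival table from plain arrays, samples named P0, P1, ..."""
    n = len(time)
    df = pd.DataFrame({"os_days": np.asarray(time, float),
                       "event": np.asarray(event, int)},
                      index=pd.Index([f"P{i}" for i in range(n)], name="sample_id"))
    for k, v in clinical.items():
        df[k] = v
    return rp.SurvivalTable(df)


def random_survival(rng, n, hazard=0.01, censor_scale=None, lp=None):
    """Exponential survival with optional linear predictor and censoring."""
    lp = np.zeros(n) if lp is None else np.asarray(lp, float)
    t_event = rng.exponential(1.0 / (hazard * np.exp(lp)))
    if censor_scale is None:
        return t_event, np.ones(n, dtype=int)
    t_cens = rng.exponential(censor_scale, n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)


@pytest.fixture(scope="session")
def small_cohort() -> rp.SimCohort:
    """A 200-sample cohort with the default five planted pairs."""
    return rp.generate_cohort(rp.SimConfig(n_samples=200, seed=11))


@pytest.fixture(scope="session")
def recovery_cohort() -> rp.SimCohort:
    """One cohort at the recovery study conditions."""
    return rp.generate_cohort(rp.SimConfig(seed=0, **RECOVERY_KW))


@pytest.fixture(scope="session")
def published() -> rp.RiskModel:
    return rp.published_model()
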