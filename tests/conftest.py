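"""Shared fixtures: small simulated panels and a session-scoped null
Monte-Carlo used by several inference-calibration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("derandomized", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("derandomized")

from snfdid import (ModelSpec, SimConfig, build_episode_table, build_panel,
                    calibrate_generator, event_study, fit_fe_ols,
                    generate_population, score_claims_frame,
                    simulate_episode_claims)


def simulate_panel(config: SimConfig) -> pd.DataFrame:
    """Run the generator through scoring, linkage and panel construction."""
    bene, fac = generate_population(config)
    claims = simulate_episode_claims(config, bene, fac)
    profiles = score_claims_frame(claims)
    episodes, _ = build_episode_table(
        claims, bene, fac, announcement_date=config.announcement_date,
        implementation_date=config.implementation_date,
        study_end=config.study_end)
    return build_panel(episodes, claims, profiles, fac)


def null_config(seed: int, n_beneficiaries: int = 2000) -> SimConfig:
    """Generator config with the announcement effect switched off."""
    return SimConfig(n_beneficiaries=n_beneficiaries, n_hospitals=20,
                     n_snfs=40, seed=seed, effect_snf_post=0.0,
                     effect_elix_post=None, effect_fp_extra=0.0,
                     effect_elix_fp_extra=None)


def replicate_seeds(entropy: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(entropy).generate_state(n) & 0x7FFFFFFF


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_beneficiaries=2500, n_hospitals=15, n_snfs=30, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One small end-to-end simulation shared across read-only tests."""
    bene, fac = generate_population(small_config)
    claims = simulate_episode_claims(small_config, bene, fac)
    profiles = score_claims_frame(claims)
    episodes, tally = build_episode_table(
        claims, bene, fac, announcement_date=small_config.announcement_date,
        implementation_date=small_config.implementation_date,
        study_end=small_config.study_end)
    panel = build_panel(episodes, claims, profiles, fac)
    return {"config": small_config, "beneficiaries": bene, "facilities": fac,
            "claims": claims, "profiles": profiles, "episodes": episodes,
            "tally": tally, "panel": panel}


@pytest.fixture(scope="session")
def calibrated_config() -> SimConfig:
    """Generator calibrated to the study's pre-period SNF moments."""
    return calibrate_generator(SimConfig(seed=1234), {"n_dx": 11.7, "elix": 6.49},
                               n_episodes=25000, tol=0.015)


@pytest.fixture(scope="session")
def calibrated_sim(calibrated_config):
    """Calibrated simulation on a fresh seed (not the calibration seed)."""
    cfg = calibrated_config.replace(seed=987654, n_beneficiaries=12000)
    return {"config": cfg, "panel": simulate_panel(cfg)}


@pytest.fixture(scope="session")
def null_mc():
    """Null-effect Monte-Carlo: pooled DiD estimates, clustered CIs.

    Shared by the no-leakage, null-centering and CI-coverage tests so the
    replication cost is paid once.
    """
    import scipy.stats
    # 45 months is the smallest cluster dimension by design; at that count
    # the Student-t critical value is the appropriate one for the interval
    crit = float(scipy.stats.t.ppf(0.975, 45 - 1))
    rows = []
    for seed in replicate_seeds(20240901, 400):
        panel = simulate_panel(null_config(int(seed)))
        res = fit_fe_ols(panel, ModelSpec(outcome="n_dx", crit_value=crit))
        lo, hi = res.ci95["treat_post"]
        rows.append({"beta": res.beta["treat_post"],
                     "se": res.se["treat_post"],
                     "covers_zero": lo <= 0.0 <= hi})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def recovery_mc():
    """Injected-effect recovery Monte-Carlo.

    Calibrates the generator so the realised post-announcement SNF
    increments equal 0.83 diagnoses and 0.88 Elixhauser points (the
    injected true effects), then fits the two-way FE model to 80
    replicates of >=10,000 episodes and collects both interaction
    coefficients (80 keeps the Monte-Carlo error of the mean near 2%).
    """
    cal = calibrate_generator(
        SimConfig(seed=424242),
        {"n_dx": 11.7, "elix": 6.49, "effect_n_dx": 0.83, "effect_elix": 0.88},
        n_episodes=120000, tol=0.01)
    rows = []
    for seed in replicate_seeds(880011, 80):
        panel = simulate_panel(cal.replace(seed=int(seed),
                                           n_beneficiaries=8200))
        rows.append({
            "n_episodes": panel["episode_id"].nunique(),
            "beta_n_dx": fit_fe_ols(
                panel, ModelSpec(outcome="n_dx",
                                 on_collinear="drop")).beta["treat_post"],
            "beta_elix": fit_fe_ols(
                panel, ModelSpec(outcome="elix",
                                 on_collinear="drop")).beta["treat_post"],
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pretrend_null_pvalues():
    """Null-design pre-trend F-test p-values over 200 replicates.

    The replicate size (about 9,000 episodes) keeps each month cell well
    populated so the joint Wald statistic is in its calibrated regime.
    """
    import datetime as dt
    ps = []
    for seed in replicate_seeds(777333, 200):
        panel = simulate_panel(null_config(int(seed), n_beneficiaries=6000))
        es = event_study(panel, "n_dx",
                         announcement_date=dt.date(2018, 10, 1))
        ps.append(es.pretrend_p)
    return np.array(ps)
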