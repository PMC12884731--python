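"""Synthetic claims generator: determinism, injected-effect structure, and
calibration to the study's pre-period moments."""

import numpy as np
import pandas as pd
import pytest

from snfdid import (SimConfig, calibrate_generator, expected_increments,
                    generate_population, score_claims_frame,
                    simulate_episode_claims)
from snfdid.comorbidity import CATEGORIES
from snfdid.exceptions import ConfigError, GenerationError


def test_config_validation_names_offending_field():
    with pytest.raises(ConfigError, match="n_snfs"):
        SimConfig(n_snfs=0).validate()
    with pytest.raises(ConfigError, match="for_profit_share"):
        SimConfig(for_profit_share=1.4).validate()
    with pytest.raises(ConfigError, match="implementation_date"):
        SimConfig(implementation_date=SimConfig().announcement_date).validate()


def test_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_beneficiaries=123, seed=9, for_profit_share=0.5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SimConfig.from_yaml(path) == cfg


def test_for_profit_share_degenerate_and_binomial():
    fac_all = generate_population(SimConfig(for_profit_share=1.0, seed=1))[1]
    snf = fac_all[fac_all.setting == "snf"]
    assert (snf.profit_status == "for_profit").all()

    cfg = SimConfig(n_snfs=10000, n_beneficiaries=10, seed=2)
    snf = generate_population(cfg)[1].query("setting == 'snf'")
    share = (snf.profit_status == "for_profit").mean()
    sd = np.sqrt(0.73 * 0.27 / 10000)
    assert abs(share - 0.73) < 3 * sd


def test_seeded_determinism_and_seed_sensitivity():
    cfg = SimConfig(n_beneficiaries=300, seed=5)
    out = []
    for seed in (5, 5, 6):
        c = cfg.replace(seed=seed)
        bene, fac = generate_population(c)
        claims = simulate_episode_claims(c, bene, fac)
        out.append((bene, fac, claims))
    pd.testing.assert_frame_equal(out[0][2], out[1][2])
    pd.testing.assert_frame_equal(out[0][0], out[1][0])
    assert not out[0][2].equals(out[2][2])
    assert not (out[0][1].profit_status == out[2][1].profit_status).all()


def test_empty_setting_raises():
    cfg = SimConfig(n_beneficiaries=50, seed=0)
    bene, fac = generate_population(cfg)
    with pytest.raises(GenerationError):
        simulate_episode_claims(cfg, bene, fac[fac.setting == "snf"])


def test_claim_shape_invariants(small_sim):
    claims = small_sim["claims"]
    dx = claims[[f"dx{i}" for i in range(1, 26)]].to_numpy(dtype=object)
    n_codes = (dx != "").sum(axis=1)
    assert n_codes.min() >= 1 and n_codes.max() <= 25
    assert (claims.admit_date <= claims.discharge_date).all()
    # paired structure: one hospital and one SNF claim per episode index
    assert (claims.setting == "hospital").sum() == (claims.setting == "snf").sum()


def test_transfer_gap_distribution(small_sim):
    claims = small_sim["claims"]
    h = claims[claims.setting == "hospital"].set_index(
        claims[claims.setting == "hospital"].claim_id.str[1:])
    s = claims[claims.setting == "snf"].set_index(
        claims[claims.setting == "snf"].claim_id.str[1:])
    gap = (s.admit_date - h.discharge_date).dt.days
    core = gap[gap <= 3]
    assert (core >= 0).all()
    # mode at 1-2 days
    assert core.value_counts().idxmax() in (1, 2)
    # a small minority violates the 3-day window to exercise the filters
    assert 0 < (gap > 3).mean() < 0.1


def _claim_did(cfg):
    """Unpaired DiD of claim means by the claim's own admit date."""
    bene, fac = generate_population(cfg)
    claims = simulate_episode_claims(cfg, bene, fac)
    scored = claims[["claim_id", "setting", "admit_date"]].merge(
        score_claims_frame(claims), on="claim_id")
    scored["post"] = scored.admit_date >= pd.Timestamp(cfg.announcement_date)
    m = scored.groupby(["post", "setting"]).n_dx.mean().unstack("setting")
    return ((m.loc[True, "snf"] - m.loc[True, "hospital"])
            - (m.loc[False, "snf"] - m.loc[False, "hospital"]))


def test_no_effect_means_no_snf_hospital_divergence():
    cfg = SimConfig(n_beneficiaries=20000, n_hospitals=20, n_snfs=40, seed=3,
                    effect_snf_post=0.0, effect_elix_post=None,
                    effect_fp_extra=0.0, effect_elix_fp_extra=None)
    # DiD of raw claim means has SE ~ 0.11 at this size; 0.35 is a 3-sigma band
    assert abs(_claim_did(cfg)) < 0.35


def test_injected_effect_raises_post_snf_counts():
    """Coupled Monte-Carlo over >=10^4 episodes: the same seed with and
    without the injection isolates the announcement increment, which must
    match the configured target (up to probability clamping and the 25-code
    cap) and be strictly positive."""
    cfg = SimConfig(n_beneficiaries=7000, n_hospitals=20, n_snfs=40, seed=4)
    null = cfg.replace(delta_a_snf=0.0, delta_b_snf=0.0,
                       delta_a_fp=0.0, delta_b_fp=0.0)
    means = {}
    for tag, c in (("eff", cfg), ("null", null)):
        bene, fac = generate_population(c)
        claims = simulate_episode_claims(c, bene, fac)
        scored = claims[["claim_id", "setting", "admit_date"]].merge(
            score_claims_frame(claims), on="claim_id")
        post_snf = scored[(scored.setting == "snf")
                          & (scored.admit_date
                             >= pd.Timestamp(c.announcement_date))]
        means[tag] = post_snf.n_dx.mean()
    increment = means["eff"] - means["null"]
    exp = expected_increments(cfg)
    target = exp["n_dx"] + cfg.for_profit_share * exp["n_dx_fp_extra"]
    assert increment > 0
    assert increment == pytest.approx(target, rel=0.10)


def test_documentation_monotonicity_by_coupled_simulation():
    """Raising a documentation probability never lowers any claim's
    diagnosis count (common random numbers via the shared seed)."""
    base = SimConfig(n_beneficiaries=800, seed=6)
    bumped = base.replace(
        doc_prob_snf={c: min(v + 0.2, 1.0) for c, v in base.doc_prob_snf.items()},
        doc_prob_hospital={c: min(v + 0.2, 1.0)
                           for c, v in base.doc_prob_hospital.items()})
    counts = {}
    for tag, cfg in (("base", base), ("bumped", bumped)):
        bene, fac = generate_population(cfg)
        claims = simulate_episode_claims(cfg, bene, fac)
        dx = claims[[f"dx{i}" for i in range(1, 26)]].to_numpy(dtype=object)
        counts[tag] = (dx != "").sum(axis=1)
    assert (counts["bumped"] >= counts["base"]).all()


def test_latent_prevalence_zero_category_never_documented():
    prev = dict(SimConfig().latent_prevalence)
    prev["liver"] = 0.0
    cfg = SimConfig(n_beneficiaries=500, seed=7, latent_prevalence=prev)
    bene, fac = generate_population(cfg)
    assert not bene["latent_liver"].any()


def test_covid_rates_zero_before_onset(small_sim):
    claims = small_sim["claims"]
    cfg = small_sim["config"]
    pre = claims[claims.admit_date < pd.Timestamp(cfg.covid_start)]
    post = claims[claims.admit_date >= pd.Timestamp(cfg.covid_start)
                  + pd.Timedelta(days=31)]
    assert (pre.county_covid_rate == 0).all()
    assert (post.county_covid_rate > 0).all()


@pytest.mark.parametrize("targets,checks", [
    ({"n_dx": 11.7, "elix": 6.49}, {"n_dx": 0.2, "elix": 0.15}),
])
def test_calibration_hits_table1_baselines_on_fresh_seed(targets, checks):
    """Calibrated generator reproduces the pre-period SNF means on a seed it
    was not calibrated with."""
    cal = calibrate_generator(SimConfig(seed=21), targets,
                              n_episodes=25000, tol=0.015)
    cfg = cal.replace(seed=22, n_beneficiaries=16000)
    bene, fac = generate_population(cfg)
    claims = simulate_episode_claims(cfg, bene, fac)
    scored = claims[["claim_id", "setting", "admit_date"]].merge(
        score_claims_frame(claims), on="claim_id")
    pre_snf = scored[(scored.setting == "snf")
                     & (scored.admit_date < pd.Timestamp(cfg.announcement_date))]
    for key, tol in checks.items():
        assert pre_snf[key].mean() == pytest.approx(targets[key], abs=tol)


def test_calibration_is_a_fixed_point_when_targets_met():
    cal = calibrate_generator(SimConfig(seed=31), {"n_dx": 11.7, "elix": 6.49},
                              n_episodes=20000, tol=0.02)
    again = calibrate_generator(cal, {"n_dx": 11.7, "elix": 6.49},
                                n_episodes=20000, tol=0.02)
    assert again.calibration["iterations"] == 1
    assert again.filler_mean == cal.filler_mean
    assert again.doc_prob_snf == cal.doc_prob_snf


def test_calibration_nonconvergence_raises_with_trace_and_best_iterate():
    """An unreachable tolerance raises, carrying the iteration trace and
    the closest iterate for callers that can tolerate a near-miss."""
    from snfdid.exceptions import CalibrationError
    with pytest.raises(CalibrationError) as err:
        calibrate_generator(SimConfig(seed=5), {"n_dx": 11.7, "elix": 6.49},
                            n_episodes=3000, tol=1e-7, max_iter=2)
    assert len(err.value.trace) == 2
    best = err.value.best_config
    assert best is not None
    assert best.calibration["converged"] is False
    assert best.calibration["max_rel_err"] < 0.2


def test_calibration_rejects_unknown_or_missing_targets():
    with pytest.raises(ConfigError):
        calibrate_generator(SimConfig(), {"nope": 1.0})
    with pytest.raises(ConfigError):
        calibrate_generator(SimConfig(), {"effect_n_dx": 0.8})


def test_expected_increments_match_configured_targets():
    exp = expected_increments(SimConfig())
    assert exp["n_dx"] == pytest.approx(0.70, abs=1e-9)
    assert exp["elix"] == pytest.approx(0.75, abs=1e-9)
    assert exp["n_dx_fp_extra"] == pytest.approx(0.15, abs=1e-9)
    assert exp["elix_fp_extra"] == pytest.approx(0.16, abs=1e-9)


def test_latent_condition_universe_matches_categories():
    bene, _ = generate_population(SimConfig(n_beneficiaries=10, seed=0))
    latent_cols = [c for c in bene.columns if c.startswith("latent_")]
    assert sorted(c[len("latent_"):] for c in latent_cols) == sorted(CATEGORIES)
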