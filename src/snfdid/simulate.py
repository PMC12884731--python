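"""Synthetic Medicare hospital/SNF claims generator.

Generates beneficiaries, facilities, and paired hospital/SNF claims with the
statistical structure the downstream analysis assumes:

* each episode is one hospital claim plus one SNF claim for the same
  beneficiary, with a 0-3 day transfer gap (mode at 1-2 days);
* every beneficiary carries a latent set of Elixhauser comorbidities; each
  latent condition is *documented* on a claim with a per-setting probability,
  so the hospital claim is a noisy control measurement of the same person's
  complexity (the non-equivalent dependent-variable design);
* at the policy announcement date, SNF documentation probabilities shift
  upward by a per-category increment ``delta_c = a + b * w_c`` (``w_c`` the
  Van Walraven weight), calibrated so the expected extra diagnoses and extra
  Elixhauser points per SNF claim equal the configured targets, with an
  additional increment in for-profit SNFs;
* non-comorbidity "acute" filler codes (drawn from a fixed pool that maps to
  no Elixhauser category) bring the total diagnosis count to its target mean;
* a configurable minority of records violate the study inclusion rules
  (age < 18, discharge against medical advice, transfer gap > 3 days,
  hospital-based SNF) to exercise the episode filters.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comorbidity import CATEGORIES, WEIGHT_VECTOR, score_claims_frame
from .config import SimConfig
from .exceptions import CalibrationError, ConfigError, GenerationError

N_CAT = len(CATEGORIES)

#: One representative ICD-10-CM code per Elixhauser category; each maps to
#: exactly that category (tested), so category documentation events translate
#: one-to-one into claim codes.
REPRESENTATIVE_CODES: dict[str, str] = {
    "chf": "I509", "arrhythmia": "I4891", "valvular": "I350",
    "pulm_circ": "I2720", "pvd": "I739", "htn": "I10",
    "paralysis": "G8190", "neuro_other": "G20", "chronic_pulm": "J449",
    "dm_uncomp": "E119", "dm_comp": "E1122", "hypothyroid": "E039",
    "renal_fail": "N189", "liver": "K7469", "pud": "K259", "hiv": "B20",
    "lymphoma": "C8339", "mets": "C787", "tumor": "C3490", "rheum": "M069",
    "coag": "D689", "obesity": "E669", "wtloss": "R634",
    "fluid_elec": "E8770", "anemia_bl": "D500", "anemia_def": "D509",
    "alcohol": "F1020", "drug": "F1120", "psychoses": "F209",
    "depression": "F329",
}

_RURALITY = ("urban", "large_rural", "small_rural", "isolated_rural")
_HOSP_RURAL_P = (0.873, 0.096, 0.026, 0.005)
_SNF_RURAL_P = (0.818, 0.109, 0.051, 0.022)
_STAR_P = (0.10, 0.13, 0.22, 0.31, 0.24)  # mean 3.46


def load_filler_codes() -> list[str]:
    from importlib import resources
    text = resources.files("snfdid.data").joinpath("acute_filler_codes.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


_FILLER_POOL = np.array(load_filler_codes(), dtype=object)


def _prevalence_vector(config: SimConfig) -> np.ndarray:
    return np.array([config.latent_prevalence.get(c, 0.0) for c in CATEGORIES])


def _doc_vector(mapping: dict[str, float]) -> np.ndarray:
    return np.array([mapping.get(c, 0.0) for c in CATEGORIES])


def resolve_deltas(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-category documentation-probability increments (SNF-post, FP-extra).

    ``delta_c = a + b * w_c`` with (a, b) either taken from the calibrated
    config fields or solved in closed form from the effect targets via the
    moment system  sum(p*delta)=target_dx,  sum(p*w*delta)=target_elix.
    """
    p = _prevalence_vector(config)
    w = WEIGHT_VECTOR.astype(float)
    sp, spw, spw2 = p.sum(), (p * w).sum(), (p * w * w).sum()

    def solve(a_cal, b_cal, eff_dx, eff_elix):
        if a_cal is not None:
            return float(a_cal), float(b_cal or 0.0)
        if eff_dx == 0 and not eff_elix:
            return 0.0, 0.0
        if eff_elix is None:
            return eff_dx / sp, 0.0
        m = np.array([[sp, spw], [spw, spw2]])
        a, b = np.linalg.solve(m, np.array([eff_dx, eff_elix], dtype=float))
        return float(a), float(b)

    a_s, b_s = solve(config.delta_a_snf, config.delta_b_snf,
                     config.effect_snf_post, config.effect_elix_post)
    a_f, b_f = solve(config.delta_a_fp, config.delta_b_fp,
                     config.effect_fp_extra, config.effect_elix_fp_extra)
    return a_s + b_s * w, a_f + b_f * w


def expected_increments(config: SimConfig) -> dict[str, float]:
    """Analytic expected announcement increments (ignoring clamping and the
    25-code cap); useful as a first-order check of an injected effect."""
    p = _prevalence_vector(config)
    w = WEIGHT_VECTOR.astype(float)
    d_snf, d_fp = resolve_deltas(config)
    return {
        "n_dx": float((p * d_snf).sum()),
        "elix": float((p * w * d_snf).sum()),
        "n_dx_fp_extra": float((p * d_fp).sum()),
        "elix_fp_extra": float((p * w * d_fp).sum()),
    }


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw beneficiaries and facilities.

    Returns
    -------
    beneficiaries
        ``beneficiary_id, age_years, part_a_months_post_discharge`` plus one
        boolean ``latent_<category>`` column per Elixhauser category.
    facilities
        One row per facility (both settings) with profit status, quality and
        rurality attributes, and the county used for COVID case-rate lookup.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_beneficiaries

    ages = np.clip(np.round(rng.normal(79.0, 9.0, n)), 21, 105).astype(int)
    under18 = rng.random(n) < config.under18_rate
    ages[under18] = rng.integers(5, 18, under18.sum())
    part_a = np.full(n, 12, dtype=int)
    short = rng.random(n) < config.short_part_a_rate
    part_a[short] = rng.integers(0, 3, short.sum())
    latent = rng.random((n, N_CAT)) < _prevalence_vector(config)[None, :]

    bene = pd.DataFrame({
        "beneficiary_id": [f"B{i:07d}" for i in range(n)],
        "age_years": ages,
        "part_a_months_post_discharge": part_a,
    })
    for i, cat in enumerate(CATEGORIES):
        bene[f"latent_{cat}"] = latent[:, i]

    nh, ns = config.n_hospitals, config.n_snfs
    hosp = pd.DataFrame({
        "facility_id": [f"HOSP{i:04d}" for i in range(nh)],
        "setting": "hospital",
        "profit_status": np.where(rng.random(nh) < config.hospital_fp_share,
                                  "for_profit", "not_for_profit"),
        "hospital_based_snf": False,
        "chain": False,
        "star_rating": np.nan,
        "rurality": rng.choice(_RURALITY, size=nh, p=_HOSP_RURAL_P),
        "vbp_participant": rng.random(nh) < config.vbp_share,
        "aco_participant": rng.random(nh) < config.aco_share,
        "affiliated_snfs": rng.random(nh) < config.affiliated_snf_share,
        "county_id": rng.integers(0, config.n_counties, nh),
    })
    snf = pd.DataFrame({
        "facility_id": [f"SNF{i:04d}" for i in range(ns)],
        "setting": "snf",
        "profit_status": np.where(rng.random(ns) < config.for_profit_share,
                                  "for_profit", "not_for_profit"),
        "hospital_based_snf": rng.random(ns) < config.hospital_based_snf_share,
        "chain": rng.random(ns) < config.chain_share,
        "star_rating": rng.choice(np.arange(1.0, 6.0), size=ns, p=_STAR_P),
        "rurality": rng.choice(_RURALITY, size=ns, p=_SNF_RURAL_P),
        "vbp_participant": False,
        "aco_participant": False,
        "affiliated_snfs": False,
        "county_id": rng.integers(0, config.n_counties, ns),
    })
    return bene, pd.concat([hosp, snf], ignore_index=True)


def _covid_surface(config: SimConfig, n_months: int) -> np.ndarray:
    """County x 30-day-period COVID case rates (per 100k), seeded
    log-normal; zeroing before covid_start happens per claim by day."""
    rng = np.random.default_rng([config.seed, 2])
    return np.exp(rng.normal(np.log(400.0), 1.0, (config.n_counties, n_months)))


def simulate_episode_claims(config: SimConfig, beneficiaries: pd.DataFrame,
                            facilities: pd.DataFrame) -> pd.DataFrame:
    """Simulate paired hospital/SNF claims for every episode.

    Returns a MedPAR-style wide table: one row per claim with ``dx1..dx25``
    diagnosis columns, admission/discharge dates, an against-medical-advice
    flag on hospital claims, and the county COVID case rate matched to the
    claim's admission month.
    """
    config.validate()
    hosp = facilities[facilities["setting"] == "hospital"].reset_index(drop=True)
    snfs = facilities[facilities["setting"] == "snf"].reset_index(drop=True)
    if hosp.empty or snfs.empty:
        raise GenerationError("need at least one facility of each setting")

    rng = np.random.default_rng([config.seed, 1])
    n_b = len(beneficiaries)
    n_ep_per_b = rng.geometric(1.0 / (1.0 + config.mean_extra_episodes), n_b)
    bene_idx = np.repeat(np.arange(n_b), n_ep_per_b)
    n_ep = len(bene_idx)

    total_days = (config.study_end - config.study_start).days
    n_months = total_days // 30 + 3
    announce_day = (config.announcement_date - config.study_start).days
    impl_day = (config.implementation_date - config.study_start).days

    hosp_discharge = rng.integers(5, total_days - 8, n_ep)
    hosp_admit = np.maximum(hosp_discharge - (3 + rng.poisson(2.0, n_ep)), 0)
    gap = rng.choice(len(config.gap_probs), size=n_ep, p=config.gap_probs)
    long_gap = rng.random(n_ep) < config.long_gap_rate
    gap[long_gap] = 4 + rng.poisson(1.0, long_gap.sum())
    snf_admit = hosp_discharge + gap
    snf_discharge = snf_admit + 10 + rng.poisson(15.0, n_ep)

    hosp_i = rng.integers(len(hosp), size=n_ep)
    snf_i = rng.integers(len(snfs), size=n_ep)
    fp = (snfs["profit_status"].to_numpy()[snf_i] == "for_profit").astype(float)

    exposure_day = snf_admit if config.exposure_index == "snf_admit" else hosp_admit
    post = (exposure_day >= announce_day).astype(float)
    eff_mult = post * np.where(exposure_day < impl_day,
                               config.anticipation_effect_frac, 1.0)

    delta_snf, delta_fp = resolve_deltas(config)
    latent = beneficiaries[[f"latent_{c}" for c in CATEGORIES]].to_numpy()[bene_idx]
    surface = _covid_surface(config, n_months)
    ama = rng.random(n_ep) < config.ama_rate

    m = max(config.filler_mean, 1.0)
    r = config.filler_dispersion
    p_nb = r / (r + (m - 1.0)) if m > 1.0 else 1.0

    blocks = []
    for setting, q_map, admit, discharge, fac_frame, fac_idx, prefix in (
            ("hospital", config.doc_prob_hospital, hosp_admit, hosp_discharge,
             hosp, hosp_i, "H"),
            ("snf", config.doc_prob_snf, snf_admit, snf_discharge,
             snfs, snf_i, "S")):
        t_month = admit // 30
        prob = (_doc_vector(q_map)[None, :]
                + config.secular_trend * t_month[:, None])
        if setting == "snf":
            prob = prob + eff_mult[:, None] * (delta_snf[None, :]
                                               + fp[:, None] * delta_fp[None, :])
        prob = np.clip(prob, 0.0, 1.0)
        documented = latent & (rng.random((n_ep, N_CAT)) < prob)

        n_fill_extra = (rng.negative_binomial(r, p_nb, n_ep)
                        if p_nb < 1.0 else np.zeros(n_ep, dtype=int))
        perm = np.argsort(rng.random((n_ep, len(_FILLER_POOL))), axis=1)

        n_com = documented.sum(axis=1)
        n_com_kept = np.minimum(n_com, 24)
        n_fill_kept = np.minimum(n_fill_extra, 24 - n_com_kept)

        arr = np.full((n_ep, 25), "", dtype=object)
        arr[:, 0] = _FILLER_POOL[perm[:, 0]]
        pos = np.cumsum(documented, axis=1)  # 1-based slot past the principal
        for ci, cat in enumerate(CATEGORIES):
            rows = documented[:, ci] & (pos[:, ci] <= 24)
            arr[rows, pos[rows, ci]] = REPRESENTATIVE_CODES[cat]
        max_fill = int(n_fill_kept.max()) if n_ep else 0
        for j in range(max_fill):
            rows = n_fill_kept > j
            arr[rows, 1 + n_com_kept[rows] + j] = _FILLER_POOL[perm[rows, j + 1]]

        county = fac_frame["county_id"].to_numpy()[fac_idx]
        covid_day = (config.covid_start - config.study_start).days
        covid_rate = surface[county, np.minimum(admit // 30, n_months - 1)]
        covid_rate = np.where(admit < covid_day, 0.0, covid_rate)
        block = pd.DataFrame({
            "claim_id": [f"{prefix}{e:08d}" for e in range(n_ep)],
            "beneficiary_id": beneficiaries["beneficiary_id"].to_numpy()[bene_idx],
            "facility_id": fac_frame["facility_id"].to_numpy()[fac_idx],
            "setting": setting,
            "admit_date": pd.to_datetime(config.study_start)
                + pd.to_timedelta(admit, unit="D"),
            "discharge_date": pd.to_datetime(config.study_start)
                + pd.to_timedelta(discharge, unit="D"),
            "discharged_ama": ama if setting == "hospital" else False,
            "county_covid_rate": covid_rate,
        })
        for k in range(25):
            block[f"dx{k + 1}"] = arr[:, k]
        blocks.append(block)

    return pd.concat(blocks, ignore_index=True)


def _measure(config: SimConfig, n_beneficiaries: int, seed: int) -> pd.DataFrame:
    """Simulate one draw and return scored SNF/hospital claim outcomes with
    exposure labels (internal to calibration)."""
    cfg = config.replace(seed=seed, n_beneficiaries=n_beneficiaries)
    bene, fac = generate_population(cfg)
    claims = simulate_episode_claims(cfg, bene, fac)
    scored = score_claims_frame(claims)
    out = claims[["claim_id", "setting", "admit_date"]].merge(scored, on="claim_id")
    out["post"] = out["admit_date"] >= pd.Timestamp(config.announcement_date)
    return out


def calibrate_generator(config: SimConfig, targets: dict[str, float], *,
                        n_episodes: int = 60000, tol: float = 0.02,
                        max_iter: int = 8, sim_seed: int | None = None) -> SimConfig:
    """Tune the generator so simulated moments match the given targets.

    Supported target keys:

    ``n_dx``
        pre-announcement mean diagnosis count on SNF claims (tunes the
        filler-code mean);
    ``elix``
        pre-announcement mean weighted Elixhauser score on SNF claims (tunes
        a common scale on the documentation probabilities);
    ``effect_n_dx`` / ``effect_elix``
        realised expected announcement increments on SNF claims (tunes the
        probability-scale injection ``(a, b)`` by Newton steps on the moment
        system, measured by coupled same-seed simulation with and without the
        effect so the 25-code cap and probability clamping are accounted for).

    Iterates simulation until every target is within ``tol`` (relative);
    raises :class:`CalibrationError` with the trace otherwise. The returned
    config carries the achieved values under ``.calibration``.
    """
    unknown = set(targets) - {"n_dx", "elix", "effect_n_dx", "effect_elix"}
    if unknown:
        raise ConfigError(f"unknown calibration targets: {sorted(unknown)}")
    if not ({"n_dx", "elix"} & set(targets)):
        raise ConfigError("targets must include n_dx and/or elix")

    base_seed = config.seed if sim_seed is None else sim_seed
    n_bene = max(int(n_episodes / (1.0 + config.mean_extra_episodes)), 200)
    want_effect = {"effect_n_dx", "effect_elix"} & set(targets)

    cfg = config
    p = _prevalence_vector(config)
    w = WEIGHT_VECTOR.astype(float)
    moment = np.array([[p.sum(), (p * w).sum()],
                       [(p * w).sum(), (p * w * w).sum()]])
    trace: list[dict] = []
    best: tuple[float, SimConfig] | None = None

    for it in range(max_iter):
        seed = int((base_seed * 1000003 + 7919 * it) % (2 ** 31))
        d_snf, d_fp = resolve_deltas(cfg)
        a, b = _ab_from_delta(d_snf, w)
        cfg_zero = cfg.replace(delta_a_snf=0.0, delta_b_snf=0.0,
                               delta_a_fp=0.0, delta_b_fp=0.0)
        zero = _measure(cfg_zero, n_bene, seed)
        pre_snf = zero[(zero["setting"] == "snf") & ~zero["post"]]
        measured = {"n_dx": float(pre_snf["n_dx"].mean()),
                    "elix": float(pre_snf["elix"].mean())}
        if want_effect:
            eff = _measure(cfg.replace(delta_a_snf=a, delta_b_snf=b), n_bene, seed)
            post_snf_e = eff[(eff["setting"] == "snf") & eff["post"]]
            post_snf_0 = zero[(zero["setting"] == "snf") & zero["post"]]
            measured["effect_n_dx"] = float(post_snf_e["n_dx"].mean()
                                            - post_snf_0["n_dx"].mean())
            measured["effect_elix"] = float(post_snf_e["elix"].mean()
                                            - post_snf_0["elix"].mean())

        rel = {k: abs(measured[k] - v) / max(abs(v), 1e-9)
               for k, v in targets.items()}
        trace.append({"iteration": it, "measured": {k: measured[k] for k in targets},
                      "targets": dict(targets), "rel_err": rel})
        worst = max(rel.values())
        if best is None or worst < best[0]:
            achieved = {k: measured[k] for k in targets}
            best = (worst, cfg.replace(calibration={
                "achieved": achieved, "tol": tol, "iterations": it + 1,
                "converged": False, "max_rel_err": worst, "trace": trace}))
        if all(e <= tol for e in rel.values()):
            achieved = {k: measured[k] for k in targets}
            return cfg.replace(calibration={"achieved": achieved, "tol": tol,
                                            "iterations": it + 1,
                                            "converged": True, "trace": trace})

        scale = 1.0
        if "elix" in targets:
            scale = targets["elix"] / max(measured["elix"], 1e-9)
            scale = float(np.clip(scale, 0.5, 2.0))
            cfg = cfg.replace(
                doc_prob_hospital={c: min(v * scale, 0.98)
                                   for c, v in cfg.doc_prob_hospital.items()},
                doc_prob_snf={c: min(v * scale, 0.98)
                              for c, v in cfg.doc_prob_snf.items()})
        if "n_dx" in targets:
            comorb = measured["n_dx"] - cfg.filler_mean  # approx comorbidity codes
            new_mean = targets["n_dx"] - comorb * scale
            cfg = cfg.replace(filler_mean=float(max(new_mean, 1.0)))
        if want_effect:
            resid = np.array([targets.get("effect_n_dx", measured["effect_n_dx"])
                              - measured["effect_n_dx"],
                              targets.get("effect_elix", measured["effect_elix"])
                              - measured["effect_elix"]])
            if "effect_elix" in targets:
                step = np.linalg.solve(moment, resid)
                a, b = a + step[0], b + step[1]
            else:
                a = a + resid[0] / moment[0, 0]
            cfg = cfg.replace(delta_a_snf=float(a), delta_b_snf=float(b))

    raise CalibrationError(
        f"calibration did not converge within {max_iter} iterations "
        f"(last rel errors {trace[-1]['rel_err']})", trace=trace,
        best_config=None if best is None else best[1])


def _ab_from_delta(delta: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Recover (a, b) from delta = a + b*w by least squares (exact here)."""
    x = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(x, delta, rcond=None)
    return float(coef[0]), float(coef[1])
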