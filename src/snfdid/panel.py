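"""Long-format analysis panel for the NEDV difference-in-differences design.

Each episode contributes exactly two rows: the hospital claim (control
measurement, ``treat = 0``) and the SNF claim (treated measurement,
``treat = 1``). Outcomes are taken from each row's own claim; the time
fixed-effect key is the SNF-admission year-month for BOTH rows, so the pair
shares a time cell; the facility fixed-effect key is the row's own facility.
The SNF's profit status is attached to both rows (it is the stratifying /
triple-interaction variable). Facility covariates enter row-specifically,
zero-coded on the other setting's rows, with urban as the rurality
reference; the county COVID case rate is matched to the row's own stay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError

#: Covariate columns produced by build_panel, in canonical order.
COVARIATE_COLUMNS = (
    "h_vbp", "h_aco", "h_fp", "h_affiliated",
    "h_rural_isolated", "h_rural_small", "h_rural_large",
    "s_chain", "s_star",
    "s_rural_isolated", "s_rural_small", "s_rural_large",
    "covid_rate",
)

OUTCOME_COLUMNS = ("n_dx", "elix", "cond_chronic_pulmonary",
                   "cond_diabetes_complicated", "cond_heart_failure",
                   "cond_obesity", "cond_weight_loss")


def _facility_covariates(fac: pd.DataFrame) -> pd.DataFrame:
    """Per-facility covariate block in panel naming, keyed by facility_id."""
    out = pd.DataFrame(index=fac.index)
    is_h = fac["setting"] == "hospital"
    out["h_vbp"] = np.where(is_h, fac["vbp_participant"].astype(float), 0.0)
    out["h_aco"] = np.where(is_h, fac["aco_participant"].astype(float), 0.0)
    out["h_fp"] = np.where(is_h, (fac["profit_status"] == "for_profit").astype(float), 0.0)
    out["h_affiliated"] = np.where(is_h, fac["affiliated_snfs"].astype(float), 0.0)
    for tag, level in (("isolated", "isolated_rural"), ("small", "small_rural"),
                       ("large", "large_rural")):
        rural = (fac["rurality"] == level).astype(float)
        out[f"h_rural_{tag}"] = np.where(is_h, rural, 0.0)
        out[f"s_rural_{tag}"] = np.where(~is_h, rural, 0.0)
    out["s_chain"] = np.where(~is_h, fac["chain"].astype(float), 0.0)
    out["s_star"] = np.where(~is_h, fac["star_rating"].fillna(0.0), 0.0)
    return out


def build_panel(episodes: pd.DataFrame, claims: pd.DataFrame,
                profiles: pd.DataFrame, facilities: pd.DataFrame) -> pd.DataFrame:
    """Expand labeled episodes into the two-row-per-episode panel.

    Parameters
    ----------
    episodes
        Labeled episode table from the episode builder (must carry
        ``period``, ``post_announcement``, ``snf_admit_month``,
        ``snf_profit_status``).
    claims
        Wide claims table (for the COVID rate of each row's stay).
    profiles
        Scored outcomes per claim from the comorbidity module.
    facilities
        Facility attribute table.

    Returns a DataFrame with 2 x len(episodes) rows and the treatment,
    period, outcome, covariate, fixed-effect and cluster-key columns.
    """
    prof = profiles.set_index("claim_id")
    missing = (set(episodes["hospital_claim_id"]) | set(episodes["snf_claim_id"])
               ) - set(prof.index)
    if missing:
        raise DataIntegrityError(
            f"claims without scored profiles, e.g. {sorted(missing)[:3]}")
    fac = facilities.set_index("facility_id")
    missing_f = (set(episodes["hospital_facility_id"])
                 | set(episodes["snf_facility_id"])) - set(fac.index)
    if missing_f:
        raise DataIntegrityError(
            f"episodes reference unknown facilities, e.g. {sorted(missing_f)[:3]}")
    fac_cov = _facility_covariates(fac)
    covid = claims.set_index("claim_id")["county_covid_rate"]

    outcome_cols = [c for c in prof.columns
                    if c in OUTCOME_COLUMNS or c.startswith("cond_")]
    rows = []
    for treat, claim_col, fac_col in ((0, "hospital_claim_id", "hospital_facility_id"),
                                      (1, "snf_claim_id", "snf_facility_id")):
        block = pd.DataFrame({
            "episode_id": episodes["episode_id"].to_numpy(),
            "beneficiary_id": episodes["beneficiary_id"].to_numpy(),
            "treat": treat,
            "period": episodes["period"].to_numpy(),
            "post": episodes["post_announcement"].to_numpy(),
            "fp": (episodes["snf_profit_status"] == "for_profit").astype(int).to_numpy(),
            "facility_id": episodes[fac_col].to_numpy(),
            "ym": episodes["snf_admit_month"].to_numpy(),
        })
        block = pd.concat(
            [block,
             prof.reindex(episodes[claim_col])[outcome_cols].reset_index(drop=True),
             fac_cov.reindex(episodes[fac_col]).reset_index(drop=True)],
            axis=1)
        block["covid_rate"] = covid.reindex(episodes[claim_col]).to_numpy()
        rows.append(block)

    panel = pd.concat(rows, ignore_index=True)
    panel["treat_post"] = panel["treat"] * panel["post"]
    panel["fp_post"] = panel["fp"] * panel["post"]
    panel["treat_post_fp"] = panel["treat_post"] * panel["fp"]
    panel = panel.sort_values(["episode_id", "treat"], kind="stable",
                              ignore_index=True)
    return panel


def subset_excluding_anticipation(panel: pd.DataFrame) -> pd.DataFrame:
    """Drop both rows of every anticipation-period episode, leaving a clean
    pre-announcement vs post-implementation contrast."""
    return panel[panel["period"] != "anticipation"].reset_index(drop=True)


def pre_period_snf_mean(panel: pd.DataFrame, outcome: str) -> float:
    """Pre-announcement SNF mean of an outcome — the baseline against which
    relative percent changes are expressed."""
    rows = panel[(panel["treat"] == 1) & (panel["period"] == "pre")]
    return float(rows[outcome].mean())
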