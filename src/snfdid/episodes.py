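"""Hospital-to-SNF episode construction.

Links each hospital claim to the earliest subsequent SNF claim of the same
beneficiary within a 3-day window, applies the study inclusion rules
(adults, continuous Part A coverage for 3 months after discharge, no
discharge against medical advice, freestanding SNFs, admissions within the
verifiable window), and labels each episode's exposure period relative to
the policy announcement and implementation dates.

Exclusions are tallied under the FIRST failing rule in a fixed order so the
tally is reproducible; the tally plus the included episodes always
reconciles with the candidate pairs examined.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError

#: Inclusion rules in tally order (first failing rule gets the count).
EXCLUSION_RULES = (
    "age_under_18",
    "no_continuous_part_a",
    "ama_discharge",
    "gap_over_3_days",
    "hospital_based_snf",
    "admit_after_study_end",
    "unmatched_hospital_claim",
)


@dataclass
class ExclusionTally:
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})
    candidates_examined: int = 0
    included: int = 0

    def add(self, rule: str, n: int = 1) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + n

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts),
                "candidates_examined": self.candidates_examined,
                "included": self.included}


def link_episodes(claims: pd.DataFrame, window_days: int = 3,
                  ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Pair hospital claims with SNF claims into candidate episodes.

    For each hospital claim (in discharge order within beneficiary) the
    earliest not-yet-used SNF claim of the same beneficiary with
    ``0 <= SNF admit - hospital discharge <= window_days`` is linked; ties in
    admission date break on the smaller SNF claim id. Hospital claims whose
    nearest available SNF claim lies 4-7 days out are tallied as
    ``gap_over_3_days``; those with none as ``unmatched_hospital_claim``.
    Linkage is invariant to the input row order (sort-before-link).
    """
    if claims["claim_id"].duplicated().any():
        dup = claims.loc[claims["claim_id"].duplicated(), "claim_id"].iloc[0]
        raise DataIntegrityError(f"duplicate claim_id: {dup!r}")

    hosp = claims[claims["setting"] == "hospital"].sort_values(
        ["beneficiary_id", "discharge_date", "claim_id"]).reset_index(drop=True)
    snf = claims[claims["setting"] == "snf"].sort_values(
        ["beneficiary_id", "admit_date", "claim_id"]).reset_index(drop=True)

    tally = ExclusionTally()
    tally.candidates_examined = len(hosp)

    h_cols = {c: hosp[c].to_numpy() for c in
              ("beneficiary_id", "claim_id", "facility_id", "admit_date",
               "discharge_date", "discharged_ama")}
    s_cols = {c: snf[c].to_numpy() for c in
              ("beneficiary_id", "claim_id", "facility_id", "admit_date",
               "discharge_date")}
    # per-beneficiary greedy matching in discharge order
    h_start = np.flatnonzero(np.r_[True, h_cols["beneficiary_id"][1:]
                                   != h_cols["beneficiary_id"][:-1]])
    h_bounds = np.r_[h_start, len(hosp)]
    s_index: dict[str, tuple[int, int]] = {}
    s_start = np.flatnonzero(np.r_[True, s_cols["beneficiary_id"][1:]
                                   != s_cols["beneficiary_id"][:-1]])
    for k, st in enumerate(s_start):
        en = s_start[k + 1] if k + 1 < len(s_start) else len(snf)
        s_index[s_cols["beneficiary_id"][st]] = (st, en)

    day = np.timedelta64(1, "D")
    records = []
    for k in range(len(h_bounds) - 1):
        hi0, hi1 = h_bounds[k], h_bounds[k + 1]
        bene = h_cols["beneficiary_id"][hi0]
        rng_s = s_index.get(bene)
        if rng_s is None:
            tally.add("unmatched_hospital_claim", hi1 - hi0)
            continue
        st, en = rng_s
        used = np.zeros(en - st, dtype=bool)
        for hi in range(hi0, hi1):
            disch = h_cols["discharge_date"][hi]
            gaps = (s_cols["admit_date"][st:en] - disch) / day
            eligible = (~used) & (gaps >= 0)
            if not eligible.any():
                tally.add("unmatched_hospital_claim")
                continue
            j = int(np.flatnonzero(eligible)[0])  # earliest admit, then claim_id
            gap = int(gaps[j])
            if gap > window_days:
                tally.add("gap_over_3_days" if gap <= 7
                          else "unmatched_hospital_claim")
                continue
            used[j] = True
            sj = st + j
            records.append((bene, h_cols["claim_id"][hi], s_cols["claim_id"][sj],
                            h_cols["facility_id"][hi], s_cols["facility_id"][sj],
                            h_cols["admit_date"][hi], disch,
                            s_cols["admit_date"][sj], s_cols["discharge_date"][sj],
                            gap, bool(h_cols["discharged_ama"][hi])))

    episodes = pd.DataFrame(records, columns=[
        "beneficiary_id", "hospital_claim_id", "snf_claim_id",
        "hospital_facility_id", "snf_facility_id",
        "hospital_admit", "hospital_discharge", "snf_admit", "snf_discharge",
        "gap_days", "ama_discharge"])
    episodes.insert(0, "episode_id",
                    [f"E{i:08d}" for i in range(len(episodes))])
    return episodes, tally


def apply_inclusion(episodes: pd.DataFrame, beneficiaries: pd.DataFrame,
                    facilities: pd.DataFrame, tally: ExclusionTally | None = None,
                    study_end: dt.date = dt.date(2021, 9, 30),
                    ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Drop episodes failing the study population rules.

    Rules, in tally order: beneficiary age under 18; fewer than 3 months of
    continuous Part A coverage after discharge; hospital discharge against
    medical advice; SNF located within a hospital; SNF admission after the
    latest verifiable date. Each dropped episode counts once, under its
    first failing rule.
    """
    tally = tally or ExclusionTally()
    if tally.candidates_examined == 0:
        tally.candidates_examined = len(episodes)

    bene = beneficiaries.set_index("beneficiary_id")
    fac = facilities.set_index("facility_id")
    missing_b = set(episodes["beneficiary_id"]) - set(bene.index)
    missing_f = set(episodes["snf_facility_id"]) - set(fac.index)
    if missing_b or missing_f:
        raise DataIntegrityError(
            f"dangling references: beneficiaries {sorted(missing_b)[:3]}, "
            f"facilities {sorted(missing_f)[:3]}")

    age = bene["age_years"].reindex(episodes["beneficiary_id"]).to_numpy()
    part_a = bene["part_a_months_post_discharge"].reindex(
        episodes["beneficiary_id"]).to_numpy()
    hosp_based = fac["hospital_based_snf"].reindex(
        episodes["snf_facility_id"]).to_numpy().astype(bool)

    fails = {
        "age_under_18": age < 18,
        "no_continuous_part_a": part_a < 3,
        "ama_discharge": episodes["ama_discharge"].to_numpy().astype(bool),
        "hospital_based_snf": hosp_based,
        "admit_after_study_end":
            episodes["snf_admit"].to_numpy() > np.datetime64(study_end),
    }
    dropped = np.zeros(len(episodes), dtype=bool)
    for rule in EXCLUSION_RULES:
        if rule not in fails:
            continue
        hit = fails[rule] & ~dropped
        tally.add(rule, int(hit.sum()))
        dropped |= fails[rule]

    included = episodes[~dropped].reset_index(drop=True)
    tally.included = len(included)
    return included, tally


def label_periods(episodes: pd.DataFrame, announcement_date: dt.date,
                  implementation_date: dt.date) -> pd.DataFrame:
    """Assign exposure periods by SNF admission date.

    ``pre`` before the announcement, ``anticipation`` from announcement to
    the day before implementation, ``post`` from implementation on.
    Also attaches the year-month time key used for time fixed effects.
    """
    out = episodes.copy()
    admit = pd.to_datetime(out["snf_admit"])
    ann = pd.Timestamp(announcement_date)
    impl = pd.Timestamp(implementation_date)
    out["period"] = np.select(
        [admit < ann, admit < impl], ["pre", "anticipation"], default="post")
    out["post_announcement"] = (out["period"] != "pre").astype(int)
    out["snf_admit_month"] = admit.dt.strftime("%Y-%m")
    return out


def build_episode_table(claims: pd.DataFrame, beneficiaries: pd.DataFrame,
                        facilities: pd.DataFrame, *,
                        announcement_date: dt.date,
                        implementation_date: dt.date,
                        study_end: dt.date = dt.date(2021, 9, 30),
                        window_days: int = 3,
                        ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Convenience wrapper: link, filter, and label in one pass, attaching
    the SNF profit status used by the triple-difference models."""
    linked, tally = link_episodes(claims, window_days=window_days)
    included, tally = apply_inclusion(linked, beneficiaries, facilities,
                                      tally, study_end=study_end)
    labeled = label_periods(included, announcement_date, implementation_date)
    fac = facilities.set_index("facility_id")
    labeled["snf_profit_status"] = fac["profit_status"].reindex(
        labeled["snf_facility_id"]).to_numpy()
    return labeled, tally
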