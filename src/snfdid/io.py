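"""Flat-file readers and writers for the pipeline tables.

Claims follow MedPAR layout conventions: one row per claim with 25
fixed-width diagnosis columns ``dx1..dx25`` (empty when absent). All tables
are plain CSV with documented column names; dates are ISO ``YYYY-MM-DD``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DATE_COLUMNS = {
    "claims": ["admit_date", "discharge_date"],
    "episodes": ["hospital_admit", "hospital_discharge",
                 "snf_admit", "snf_discharge"],
}


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={f"dx{i}": "string" for i in range(1, 26)},
                     keep_default_na=False, na_values=[])
    for c in DATE_COLUMNS["claims"]:
        df[c] = pd.to_datetime(df[c])
    for i in range(1, 26):
        df[f"dx{i}"] = df[f"dx{i}"].fillna("").astype(object)
    df["discharged_ama"] = df["discharged_ama"].astype(str).str.lower().isin(
        ["true", "1"])
    df["county_covid_rate"] = pd.to_numeric(df["county_covid_rate"])
    return df


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in DATE_COLUMNS["episodes"]:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


def read_beneficiaries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_facilities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("hospital_based_snf", "chain", "vbp_participant",
              "aco_participant", "affiliated_snfs"):
        df[c] = df[c].astype(str).str.lower().isin(["true", "1"])
    return df


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)
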