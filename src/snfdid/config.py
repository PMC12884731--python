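"""Simulation configuration for the synthetic claims generator.

:class:`SimConfig` carries every knob of the generator: the study window
and the two policy dates (announcement of the payment model, then its
implementation one year later), the latent comorbidity prevalences of the
simulated SNF-bound population, per-setting documentation probabilities,
and the injected announcement effects.

Default values emulate the published study conditions: a January 2018 -
September 2021 window, announcement on 2018-10-01, implementation on
2019-10-01, 73% for-profit SNF share, baseline SNF means of 11.7 recorded
diagnoses and a weighted Elixhauser score of 6.49 in the pre-announcement
period, and injected announcement effects of +0.83 diagnoses / +0.88
Elixhauser points on SNF claims (with +0.15 / +0.16 extra in for-profit
facilities).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import yaml

from .comorbidity import CATEGORIES
from .exceptions import ConfigError

#: Latent (true underlying) prevalence of each Elixhauser category in the
#: simulated hospital-to-SNF population. With the default documentation
#: probability these reproduce the pre-period documented prevalences of the
#: five documentation-sensitive conditions and a pre-period mean weighted
#: Elixhauser score of 6.49.
DEFAULT_LATENT_PREVALENCE: dict[str, float] = {
    "chf": 0.369,
    "arrhythmia": 0.35,
    "valvular": 0.12,
    "pulm_circ": 0.08,
    "pvd": 0.15,
    "htn": 0.65,
    "paralysis": 0.06,
    "neuro_other": 0.12,
    "chronic_pulm": 0.346,
    "dm_uncomp": 0.20,
    "dm_comp": 0.161,
    "hypothyroid": 0.18,
    "renal_fail": 0.22,
    "liver": 0.04,
    "pud": 0.02,
    "hiv": 0.002,
    "lymphoma": 0.015,
    "mets": 0.03,
    "tumor": 0.05,
    "rheum": 0.05,
    "coag": 0.06,
    "obesity": 0.0743,
    "wtloss": 0.0589,
    "fluid_elec": 0.40,
    "anemia_bl": 0.03,
    "anemia_def": 0.20,
    "alcohol": 0.04,
    "drug": 0.03,
    "psychoses": 0.05,
    "depression": 0.25,
}

#: Baseline per-category probability that a latent condition is documented
#: on a claim. Uniform across categories by default; calibration rescales it.
DEFAULT_DOC_PROB = 0.645


def _doc_prob_map() -> dict[str, float]:
    return {c: DEFAULT_DOC_PROB for c in CATEGORIES}


@dataclass
class SimConfig:
    """All generator knobs. See module docstring for the default regime."""

    n_beneficiaries: int = 33000
    n_hospitals: int = 60
    n_snfs: int = 120
    study_start: dt.date = dt.date(2018, 1, 1)
    study_end: dt.date = dt.date(2021, 9, 30)
    announcement_date: dt.date = dt.date(2018, 10, 1)
    implementation_date: dt.date = dt.date(2019, 10, 1)
    for_profit_share: float = 0.73
    latent_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_PREVALENCE))
    doc_prob_hospital: dict[str, float] = field(default_factory=_doc_prob_map)
    doc_prob_snf: dict[str, float] = field(default_factory=_doc_prob_map)
    #: additive drift in documentation probability per month since study start
    secular_trend: float = 0.0015
    #: injected announcement effect: target additional expected diagnoses on
    #: post-announcement SNF claims in not-for-profit facilities (the base
    #: effect; for-profit facilities add effect_fp_extra on top)
    effect_snf_post: float = 0.70
    #: target additional expected weighted Elixhauser points on
    #: post-announcement SNF claims (None: inject on the diagnosis scale only)
    effect_elix_post: float | None = 0.75
    #: additional for-profit effect on the diagnosis scale
    effect_fp_extra: float = 0.15
    #: additional for-profit effect on the Elixhauser scale
    effect_elix_fp_extra: float | None = 0.16
    covid_start: dt.date = dt.date(2020, 3, 1)
    seed: int = 0

    # --- plumbing knobs -------------------------------------------------
    #: expected filler (non-comorbidity) codes per claim, incl. the principal
    filler_mean: float = 9.0
    #: negative-binomial dispersion of the extra-filler count
    filler_dispersion: float = 4.0
    #: mean number of episodes beyond the first per beneficiary (geometric)
    mean_extra_episodes: float = 0.5
    n_counties: int = 40
    hospital_based_snf_share: float = 0.03
    ama_rate: float = 0.01
    under18_rate: float = 0.01
    short_part_a_rate: float = 0.02
    long_gap_rate: float = 0.02
    chain_share: float = 0.59
    hospital_fp_share: float = 0.146
    vbp_share: float = 0.918
    aco_share: float = 0.004
    affiliated_snf_share: float = 0.085
    #: P(gap days = 0,1,2,3) between hospital discharge and SNF admission
    gap_probs: tuple[float, ...] = (0.15, 0.45, 0.30, 0.10)
    #: month index exposure/time-FE convention: "snf_admit" or "hospital_admit"
    exposure_index: str = "snf_admit"
    #: fraction of the injected effect active during the anticipation period
    anticipation_effect_frac: float = 1.0

    # --- calibrated probability-scale increments ------------------------
    # delta_c = a + b * weight_c. None -> solved in closed form from the
    # effect targets; calibrate_generator refines them by simulation.
    delta_a_snf: float | None = None
    delta_b_snf: float | None = None
    delta_a_fp: float | None = None
    delta_b_fp: float | None = None

    #: filled by calibrate_generator with the achieved values
    calibration: dict | None = None

    def validate(self) -> "SimConfig":
        for name in ("n_beneficiaries", "n_hospitals", "n_snfs", "n_counties"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        probs = {
            "for_profit_share": self.for_profit_share,
            "hospital_based_snf_share": self.hospital_based_snf_share,
            "ama_rate": self.ama_rate,
            "under18_rate": self.under18_rate,
            "short_part_a_rate": self.short_part_a_rate,
            "long_gap_rate": self.long_gap_rate,
            "chain_share": self.chain_share,
            "hospital_fp_share": self.hospital_fp_share,
            "vbp_share": self.vbp_share,
            "aco_share": self.aco_share,
            "affiliated_snf_share": self.affiliated_snf_share,
            "anticipation_effect_frac": self.anticipation_effect_frac,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0,1], got {value}")
        for name, mapping in (("latent_prevalence", self.latent_prevalence),
                              ("doc_prob_hospital", self.doc_prob_hospital),
                              ("doc_prob_snf", self.doc_prob_snf)):
            unknown = set(mapping) - set(CATEGORIES)
            if unknown:
                raise ConfigError(f"{name} has unknown categories: {sorted(unknown)}")
            for cat, value in mapping.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigError(f"{name}[{cat}] must be in [0,1], got {value}")
        if not (self.announcement_date < self.implementation_date <= self.study_end):
            raise ConfigError(
                "announcement_date < implementation_date <= study_end required, got "
                f"{self.announcement_date}, {self.implementation_date}, {self.study_end}")
        if self.study_start >= self.announcement_date:
            raise ConfigError("study_start must precede announcement_date")
        if abs(sum(self.gap_probs) - 1.0) > 1e-9:
            raise ConfigError("gap_probs must sum to 1")
        if self.exposure_index not in ("snf_admit", "hospital_admit"):
            raise ConfigError(f"exposure_index must be snf_admit or hospital_admit, "
                              f"got {self.exposure_index!r}")
        return self

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    # --- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, dt.date):
                d[k] = v.isoformat()
        d["gap_probs"] = list(self.gap_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kw = dict(d)
        for k in ("study_start", "study_end", "announcement_date",
                  "implementation_date", "covid_start"):
            if k in kw and isinstance(kw[k], str):
                kw[k] = dt.date.fromisoformat(kw[k])
        if "gap_probs" in kw:
            kw["gap_probs"] = tuple(kw["gap_probs"])
        return cls(**kw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
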