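"""Elixhauser comorbidity mapping and Van Walraven weighted scoring.

Maps lists of ICD-10-CM diagnosis codes to the 30 Elixhauser comorbidity
categories (hypertension combined) by prefix matching against the Quan
ICD-10 coding algorithm, and scores the resulting flag set with the Van
Walraven integer weights. The weighted score ranges from -19 (all
negative-weight categories present) to 89 (all positive-weight categories
present); higher values indicate greater clinical complexity and mortality
risk.

The category definitions and weights are shipped as versioned plain-text
tables under ``snfdid/data`` so alternative dialects or weightings can be
swapped in.

Two scoring surfaces are provided: :func:`score_claim` for a single claim
record, and :func:`score_claims_frame` for vectorised scoring of a wide
(``dx1..dx25``) claims table, which is the path the pipeline uses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import InvalidCodeError

MAPPING_VERSION = "quan-icd10-v1"
WEIGHTS_VERSION = "vw-v1"

#: The five documentation-sensitive conditions studied, keyed by the public
#: condition name with the underlying Elixhauser category as value.
CONDITION_CATEGORIES = {
    "chronic_pulmonary": "chronic_pulm",
    "diabetes_complicated": "dm_comp",
    "heart_failure": "chf",
    "obesity": "obesity",
    "weight_loss": "wtloss",
}

# ICD-10-CM codes after dot-stripping: one letter, one digit, then 1-5
# alphanumerics (7th-character extensions are letters).
_CODE_RE = re.compile(r"^[A-Z][0-9][A-Z0-9]{1,5}$")


def _read_table(name: str) -> list[tuple[str, str]]:
    text = resources.files("snfdid.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        rows.append((key, value))
    return rows


def load_category_prefixes(name: str = "elixhauser_icd10_quan_v1.tsv") -> dict[str, tuple[str, ...]]:
    """Category -> tuple of dot-stripped uppercase ICD-10 prefixes."""
    return {cat: tuple(p.strip().upper() for p in prefixes.split(","))
            for cat, prefixes in _read_table(name)}


def load_weights(name: str = "van_walraven_weights_v1.tsv") -> dict[str, int]:
    """Category -> Van Walraven integer weight, in canonical category order."""
    return {cat: int(w) for cat, w in _read_table(name)}


_PREFIXES = load_category_prefixes()
_WEIGHTS = load_weights()

#: Canonical ordered category list (order of the weights table).
CATEGORIES: tuple[str, ...] = tuple(_WEIGHTS)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
WEIGHT_VECTOR = np.array([_WEIGHTS[c] for c in CATEGORIES], dtype=np.int64)

if set(_PREFIXES) != set(CATEGORIES):  # pragma: no cover - data-file sanity
    raise RuntimeError("category mismatch between mapping and weight tables")

# Prefix lookup structures: for each prefix length, map prefix -> bitmask of
# category indices. A code can activate several categories (the source table
# intentionally cross-lists some subcodes).
_MASKS_BY_LEN: dict[int, dict[str, int]] = {}
for _cat, _plist in _PREFIXES.items():
    for _p in _plist:
        _MASKS_BY_LEN.setdefault(len(_p), {}).setdefault(_p, 0)
        _MASKS_BY_LEN[len(_p)][_p] |= 1 << _CAT_INDEX[_cat]
_PREFIX_LENGTHS = sorted(_MASKS_BY_LEN)

_DM_UNCOMP = _CAT_INDEX["dm_uncomp"]
_DM_COMP = _CAT_INDEX["dm_comp"]


@dataclass
class ComorbidityProfile:
    """Scored complexity outcomes for one claim."""

    claim_id: str
    n_diagnoses: int
    weighted_score: int
    flags: dict[str, bool]
    condition_flags: dict[str, bool] = field(default_factory=dict)


def normalize_code(code: str) -> str:
    """Uppercase and strip the decimal point; validate the ICD-10 shape.

    Raises :class:`InvalidCodeError` naming the offending code.
    """
    norm = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(norm):
        raise InvalidCodeError(f"not a valid ICD-10 code: {code!r}")
    return norm


def _code_mask(norm: str) -> int:
    mask = 0
    for ln in _PREFIX_LENGTHS:
        mask |= _MASKS_BY_LEN[ln].get(norm[:ln], 0)
    return mask


def _mask_to_flags(mask: int) -> dict[str, bool]:
    # diabetes hierarchy: complicated suppresses uncomplicated
    if mask >> _DM_COMP & 1:
        mask &= ~(1 << _DM_UNCOMP)
    return {c: bool(mask >> i & 1) for i, c in enumerate(CATEGORIES)}


def map_elixhauser(codes: list[str]) -> dict[str, bool]:
    """Map a diagnosis code list to Elixhauser category flags.

    A category is flagged when at least one code starts with one of its
    prefixes (after dot-stripping and uppercasing). An empty list yields
    all-false flags. Duplicate codes are idempotent.
    """
    mask = 0
    for code in codes:
        mask |= _code_mask(normalize_code(code))
    return _mask_to_flags(mask)


def weighted_elixhauser(flags: dict[str, bool]) -> int:
    """Van Walraven weighted score: sum of category weights over set flags."""
    score = 0
    for cat, on in flags.items():
        if cat not in _WEIGHTS:
            raise InvalidCodeError(f"unknown comorbidity category: {cat!r}")
        if on:
            score += _WEIGHTS[cat]
    return score


def score_claim(claim) -> ComorbidityProfile:
    """Score one claim (mapping, weighted score, condition indicators).

    ``claim`` may be a mapping/namespace with ``claim_id`` and either a
    ``diagnosis_codes`` list or MedPAR-style ``dx1..dx25`` fields.
    """
    get = claim.get if hasattr(claim, "get") else lambda k, d=None: getattr(claim, k, d)
    codes = get("diagnosis_codes")
    if codes is None:
        codes = [v for v in (get(f"dx{i}") for i in range(1, 26))
                 if isinstance(v, str) and v.strip()]
    flags = map_elixhauser(list(codes))
    return ComorbidityProfile(
        claim_id=get("claim_id", ""),
        n_diagnoses=len(codes),
        weighted_score=weighted_elixhauser(flags),
        flags=flags,
        condition_flags={name: flags[cat] for name, cat in CONDITION_CATEGORIES.items()},
    )


def score_claims_frame(claims: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a wide claims table.

    Parameters
    ----------
    claims
        One row per claim with ``claim_id`` and ``dx1..dx25`` columns
        (empty string or NaN when absent).

    Returns
    -------
    DataFrame keyed by ``claim_id`` with ``n_dx``, ``elix``, one boolean
    ``flag_<category>`` column per Elixhauser category, and one
    ``cond_<name>`` column per documentation-sensitive condition.
    """
    dx_cols = [c for c in claims.columns if re.fullmatch(r"dx\d+", c)]
    if not dx_cols:
        raise InvalidCodeError("claims table has no dx1..dx25 columns")
    wide = claims[dx_cols].to_numpy(dtype=object)
    n = len(claims)
    codes = pd.Series(wide.ravel(order="C"), dtype=object)
    present = codes.notna() & (codes.astype(str).str.strip() != "")
    norm = codes[present].astype(str).str.strip().str.upper().str.replace(".", "", regex=False)
    bad = ~norm.str.match(_CODE_RE.pattern)
    if bad.any():
        raise InvalidCodeError(f"not a valid ICD-10 code: {norm[bad].iloc[0]!r}")

    mask = pd.Series(np.zeros(len(norm), dtype=np.int64), index=norm.index)
    for ln in _PREFIX_LENGTHS:
        mask |= norm.str[:ln].map(_MASKS_BY_LEN[ln]).fillna(0).astype(np.int64)

    claim_masks = np.zeros(n * len(dx_cols), dtype=np.int64)
    claim_masks[mask.index.to_numpy()] = mask.to_numpy()
    claim_masks = np.bitwise_or.reduce(claim_masks.reshape(n, len(dx_cols)), axis=1)
    # diabetes hierarchy
    has_comp = claim_masks >> _DM_COMP & 1
    claim_masks &= ~(has_comp << _DM_UNCOMP)

    flags = (claim_masks[:, None] >> np.arange(len(CATEGORIES))[None, :] & 1).astype(bool)
    out = pd.DataFrame({
        "claim_id": claims["claim_id"].to_numpy(),
        "n_dx": present.to_numpy().reshape(n, len(dx_cols)).sum(axis=1),
        "elix": flags @ WEIGHT_VECTOR,
    })
    for i, cat in enumerate(CATEGORIES):
        out[f"flag_{cat}"] = flags[:, i]
    for name, cat in CONDITION_CATEGORIES.items():
        out[f"cond_{name}"] = flags[:, _CAT_INDEX[cat]].astype(np.int8)
    return out


def score_bounds() -> tuple[int, int]:
    """Exact (min, max) weighted score over admissible flag combinations.

    Categories are independent except the diabetes pair, where the hierarchy
    forbids flagging both; the optimum therefore decomposes per category,
    with the diabetes pair contributing the best single choice.
    """
    lo = hi = 0
    for cat in CATEGORIES:
        if cat in ("dm_uncomp", "dm_comp"):
            continue
        w = _WEIGHTS[cat]
        hi += max(w, 0)
        lo += min(w, 0)
    dm = (_WEIGHTS["dm_uncomp"], _WEIGHTS["dm_comp"])
    hi += max(0, *dm)
    lo += min(0, *dm)
    return lo, hi
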