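"""Fixed-effects difference-in-differences estimation with multiway
cluster-robust inference.

The estimating equation is

    y_ijt = b1*Treat_j + b3*(Treat_j x Post_t) + b4'X_jt + a_j + l_t + e_ijt

with facility fixed effects a_j and year-month fixed effects l_t, both
absorbed by iterated group demeaning (alternating projections). Because
every facility is purely hospital or purely SNF, the Treat main effect is
collinear with the facility effects, and the Post main effect with the time
effects; both are reported as absorbed rather than estimated. Triple-
difference models add Post x ForProfit and Treat x Post x ForProfit.

Variances are Cameron-Gelbach-Miller multiway cluster-robust: the sandwich
is computed for every nonempty subset of the cluster dimensions (clustering
on the intersection of the subset's dimensions) and combined by
inclusion-exclusion with alternating signs; each term carries the
G/(G-1) * (N-1)/(N-K) small-sample factor. A non-positive-semidefinite
combination is repaired by truncating negative eigenvalues at zero (logged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .exceptions import DomainError, SingularityError, SpecificationError
from .panel import COVARIATE_COLUMNS, pre_period_snf_mean

logger = logging.getLogger(__name__)

#: Map user-facing outcome names to panel columns.
OUTCOME_MAP = {
    "n_dx": "n_dx",
    "elix": "elix",
    "chronic_pulmonary": "cond_chronic_pulmonary",
    "diabetes_complicated": "cond_diabetes_complicated",
    "heart_failure": "cond_heart_failure",
    "obesity": "cond_obesity",
    "weight_loss": "cond_weight_loss",
}


@dataclass
class ModelSpec:
    """What to estimate and how."""

    outcome: str = "n_dx"
    interaction: str = "two_way"        # "two_way" | "three_way"
    family: str = "linear"              # "linear" | "logit"
    clusters: tuple[str, ...] = ("beneficiary", "facility", "time")
    exclude_anticipation: bool = False
    covariates: tuple[str, ...] | None = None   # None -> panel defaults
    on_collinear: str = "error"         # "error" | "drop"
    crit_value: float = 1.96
    demean_tol: float = 1e-8
    demean_max_iter: int = 500
    logit_tol: float = 1e-8
    logit_max_iter: int = 100

    def outcome_column(self) -> str:
        col = OUTCOME_MAP.get(self.outcome, self.outcome)
        return col

    def interaction_terms(self) -> list[str]:
        if self.interaction == "two_way":
            return ["treat_post"]
        if self.interaction == "three_way":
            return ["treat_post", "fp_post", "treat_post_fp", "fp"]
        raise SpecificationError(f"unknown interaction {self.interaction!r}")


@dataclass
class DiDResult:
    """Point estimates, multiway-clustered variance, and derived quantities."""

    beta: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    vcov: pd.DataFrame
    n_obs: int
    n_episodes: int
    baseline: float
    relative_change: dict[str, float]
    absorbed: dict[str, str]
    dropped: list[str] = field(default_factory=list)
    cluster_counts: dict[str, int] = field(default_factory=dict)
    vcov_repaired: bool = False
    family: str = "linear"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_obs": self.n_obs, "n_episodes": self.n_episodes,
            "baseline": self.baseline, "relative_change": self.relative_change,
            "absorbed": self.absorbed, "dropped": self.dropped,
            "cluster_counts": self.cluster_counts,
            "vcov_repaired": self.vcov_repaired, "family": self.family,
            "extra": self.extra,
        }


# --------------------------------------------------------------------------
# within-transformation

def within_transform(values: np.ndarray, groups: list[np.ndarray],
                     tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Demean columns of ``values`` within each grouping by alternating
    projections, iterating until the largest within-group mean is below
    ``tol``. With a single grouping one pass is exact."""
    out = np.array(values, dtype=float, copy=True)
    if out.ndim == 1:
        out = out[:, None]
    codes = [np.asarray(g) for g in groups]
    counts = [np.bincount(g).astype(float) for g in codes]
    for _ in range(max_iter):
        max_dev = 0.0
        for g, cnt in zip(codes, counts):
            means = np.empty((len(cnt), out.shape[1]))
            for j in range(out.shape[1]):
                means[:, j] = np.bincount(g, weights=out[:, j]) / cnt
            out -= means[g]
            if means.size:
                max_dev = max(max_dev, float(np.abs(means).max()))
        if max_dev < tol:
            break
    else:
        logger.warning("within_transform: not converged below %g", tol)
    return out


def _factorize(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, sort=True)
    return codes.astype(np.int64), len(uniques)


def _combine_codes(code_list: list[np.ndarray]) -> np.ndarray:
    combined = code_list[0].astype(np.int64)
    for c in code_list[1:]:
        combined = combined * (int(c.max()) + 1) + c
    codes, _ = pd.factorize(combined)
    return codes.astype(np.int64)


# --------------------------------------------------------------------------
# multiway clustered variance

def multiway_cluster_vcov(x: np.ndarray, resid: np.ndarray,
                          clusters: dict[str, np.ndarray], k_model: int,
                          repair: bool = True,
                          ) -> tuple[np.ndarray, dict[str, int], bool]:
    """Cameron-Gelbach-Miller inclusion-exclusion sandwich.

    Parameters
    ----------
    x
        Demeaned regressor matrix (n, k).
    resid
        OLS residuals (n,).
    clusters
        Cluster-dimension name -> integer code array (n,).
    k_model
        Total parameter count (regressors plus absorbed fixed effects) used
        in the (N-1)/(N-K) degrees-of-freedom factor.

    Returns ``(vcov, cluster_counts, repaired)``; ``cluster_counts`` maps
    each subset (joined by ``*``) to its cluster count.
    """
    n, k = x.shape
    names = sorted(clusters)
    codes = {m: _factorize(clusters[m])[0] for m in names}
    for m in names:
        g = int(codes[m].max()) + 1
        if g < 2:
            raise SpecificationError(
                f"cluster dimension {m!r} has a single cluster; remove it")
    bread = np.linalg.inv(x.T @ x)
    xu = x * resid[:, None]

    vcov = np.zeros((k, k))
    counts: dict[str, int] = {}
    for size in range(1, len(names) + 1):
        for subset in itertools.combinations(names, size):
            combined = _combine_codes([codes[m] for m in subset])
            g = int(combined.max()) + 1
            scores = np.zeros((g, k))
            np.add.at(scores, combined, xu)
            meat = scores.T @ scores
            factor = (g / (g - 1)) * ((n - 1) / (n - k_model)) if g > 1 else 1.0
            term = factor * bread @ meat @ bread
            vcov += ((-1) ** (size + 1)) * term
            counts["*".join(subset)] = g

    repaired = False
    eigval = np.linalg.eigvalsh(vcov)
    if eigval.min() < -1e-12 * max(eigval.max(), 1.0):
        if repair:
            w, v = np.linalg.eigh(vcov)
            vcov = (v * np.clip(w, 0.0, None)) @ v.T
            repaired = True
            logger.warning("multiway vcov not PSD; negative eigenvalues "
                           "truncated (min eigenvalue %.3g)", eigval.min())
    return vcov, counts, repaired


# --------------------------------------------------------------------------
# core fitting machinery (shared with the event-study diagnostics)

def fe_ols_core(df: pd.DataFrame, ycol: str, xcols: list[str],
                spec: ModelSpec) -> dict:
    """Absorb facility and time fixed effects, run OLS, cluster the vcov.

    Covariate columns constant within every facility group or every time
    group are structurally absorbed by the fixed effects and are removed
    up front (recorded under ``dropped``); genuine collinearity among the
    remaining regressors raises :class:`SingularityError` unless
    ``spec.on_collinear == "drop"``.
    """
    fac_codes, n_fac = _factorize(df["facility_id"].to_numpy())
    ym_codes, n_ym = _factorize(df["ym"].to_numpy())
    groups = [fac_codes, ym_codes]

    keep, dropped = [], []
    for c in xcols:
        vals = df[c].to_numpy(dtype=float)
        absorbed = any(_constant_within(vals, g) for g in groups)
        if absorbed:
            dropped.append(c)
        else:
            keep.append(c)
    if not keep:
        raise SpecificationError("all regressors are absorbed by the fixed effects")

    y = df[ycol].to_numpy(dtype=float)
    x = df[keep].to_numpy(dtype=float)
    z = within_transform(np.column_stack([y, x]), groups,
                         tol=spec.demean_tol, max_iter=spec.demean_max_iter)
    yd, xd = z[:, 0], z[:, 1:]

    # pivoted-QR rank screen on the demeaned design
    _, r, piv = scipy.linalg.qr(xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    bad = piv[diag < 1e-10 * max(diag.max(), 1.0)] if diag.size else []
    if len(bad):
        bad_cols = [keep[i] for i in bad]
        if spec.on_collinear == "drop":
            logger.warning("dropping collinear columns: %s", bad_cols)
            dropped += bad_cols
            keep = [c for c in keep if c not in bad_cols]
            x = df[keep].to_numpy(dtype=float)
            z = within_transform(np.column_stack([y, x]), groups,
                                 tol=spec.demean_tol,
                                 max_iter=spec.demean_max_iter)
            yd, xd = z[:, 0], z[:, 1:]
        else:
            raise SingularityError(
                f"rank-deficient design after demeaning; dependent columns: "
                f"{bad_cols}", columns=bad_cols)

    beta = np.linalg.lstsq(xd, yd, rcond=None)[0]
    resid = yd - xd @ beta
    k_model = len(keep) + (n_fac - 1) + (n_ym - 1) + 1

    cluster_cols = {"beneficiary": "beneficiary_id", "facility": "facility_id",
                    "time": "ym"}
    clusters = {m: df[cluster_cols[m]].to_numpy() for m in spec.clusters}
    vcov, counts, repaired = multiway_cluster_vcov(xd, resid, clusters, k_model)

    return {"terms": keep, "beta": beta, "vcov": vcov, "resid": resid,
            "dropped": dropped, "cluster_counts": counts,
            "vcov_repaired": repaired, "n_obs": len(df),
            "k_model": k_model}


def _constant_within(values: np.ndarray, codes: np.ndarray) -> bool:
    cnt = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=values) / cnt
    return bool(np.abs(values - means[codes]).max() < 1e-12)


# --------------------------------------------------------------------------
# public operations

def fit_fe_ols(panel: pd.DataFrame, spec: ModelSpec) -> DiDResult:
    """Fit the linear fixed-effects DiD (or DDD) model.

    The Treat and Post main effects are absorbed by the facility and time
    fixed effects respectively and reported as such; the coefficient of
    interest is ``treat_post`` (plus ``treat_post_fp`` in three-way models).
    """
    if spec.family != "linear":
        raise SpecificationError("fit_fe_ols requires spec.family='linear'")
    df = panel
    if spec.exclude_anticipation:
        df = df[df["period"] != "anticipation"].reset_index(drop=True)
    ycol = spec.outcome_column()
    covs = list(spec.covariates) if spec.covariates is not None else \
        [c for c in COVARIATE_COLUMNS if c in df.columns]
    xcols = spec.interaction_terms() + [c for c in covs
                                        if c not in spec.interaction_terms()]

    core = fe_ols_core(df, ycol, xcols, spec)
    baseline = pre_period_snf_mean(df, ycol)
    return _package_result(core, spec, baseline,
                           n_episodes=df["episode_id"].nunique())


def _package_result(core: dict, spec: ModelSpec, baseline: float,
                    n_episodes: int, family: str = "linear") -> DiDResult:
    terms = core["terms"]
    beta = dict(zip(terms, core["beta"].tolist()))
    se = dict(zip(terms, np.sqrt(np.diag(core["vcov"])).tolist()))
    ci = {t: (beta[t] - spec.crit_value * se[t],
              beta[t] + spec.crit_value * se[t]) for t in terms}
    rel = {}
    for t in ("treat_post", "treat_post_fp"):
        if t in beta and baseline > 0:
            rel[t] = relative_change(beta[t], baseline)
    return DiDResult(
        beta=beta, se=se, ci95=ci,
        vcov=pd.DataFrame(core["vcov"], index=terms, columns=terms),
        n_obs=core["n_obs"], n_episodes=n_episodes, baseline=baseline,
        relative_change=rel,
        absorbed={"treat": "facility fixed effects",
                  "post": "time fixed effects"},
        dropped=core["dropped"], cluster_counts=core["cluster_counts"],
        vcov_repaired=core["vcov_repaired"], family=family)


def fit_fe_logit_ame(panel: pd.DataFrame, spec: ModelSpec) -> DiDResult:
    """Logit with explicit facility and time dummies; reports the average
    marginal effect of the announcement on the treated setting.

    The AME is the mean over SNF rows of P(y=1 | treat_post=1) minus
    P(y=1 | treat_post=0), all else held at observed values. Facilities or
    months whose outcome has no variation (perfect-prediction groups) are
    dropped with a warning, mirroring standard fixed-effects logit practice.
    A linear-probability fit on the same sample is reported alongside.
    """
    ycol = spec.outcome_column()
    if not ycol.startswith("cond_"):
        raise SpecificationError("logit models are for binary condition outcomes")
    df = panel
    if spec.exclude_anticipation:
        df = df[df["period"] != "anticipation"]
    df = df.reset_index(drop=True)

    # iteratively remove no-variation groups (separation guard)
    n_dropped_groups = 0
    while True:
        changed = False
        for key in ("facility_id", "ym"):
            var = df.groupby(key)[ycol].agg(["min", "max"])
            bad = var.index[var["min"] == var["max"]]
            if len(bad):
                df = df[~df[key].isin(bad)].reset_index(drop=True)
                n_dropped_groups += len(bad)
                changed = True
        if not changed:
            break
    if n_dropped_groups:
        logger.warning("logit: dropped %d no-variation facility/month groups",
                       n_dropped_groups)
    if df.empty:
        raise SpecificationError("no rows left after separation screening")

    covs = list(spec.covariates) if spec.covariates is not None else \
        [c for c in COVARIATE_COLUMNS if c in df.columns]
    inter = spec.interaction_terms()
    fac_codes, _ = _factorize(df["facility_id"].to_numpy())
    ym_codes, _ = _factorize(df["ym"].to_numpy())
    keep_cov = []
    for c in covs:
        vals = df[c].to_numpy(dtype=float)
        if not (_constant_within(vals, fac_codes) or _constant_within(vals, ym_codes)):
            keep_cov.append(c)
    xcols = inter + [c for c in keep_cov if c not in inter]

    design = [df[xcols].astype(float),
              pd.get_dummies(df["facility_id"], prefix="fac",
                             drop_first=True, dtype=float),
              pd.get_dummies(df["ym"], prefix="t", drop_first=True, dtype=float)]
    x = pd.concat(design, axis=1)
    x["const"] = 1.0
    y = df[ycol].astype(float)
    try:
        fit = sm.Logit(y, x).fit(disp=0, method="newton",
                                 maxiter=spec.logit_max_iter, tol=spec.logit_tol)
    except Exception:  # Newton can overshoot on near-separated designs
        fit = sm.Logit(y, x).fit(disp=0, method="lbfgs",
                                 maxiter=max(spec.logit_max_iter, 500))

    snf_rows = df["treat"] == 1
    x1, x0 = x[snf_rows].copy(), x[snf_rows].copy()
    x1["treat_post"] = 1.0
    x0["treat_post"] = 0.0
    if "treat_post_fp" in x.columns:
        x1["treat_post_fp"] = df.loc[snf_rows, "fp"].astype(float).to_numpy()
        x0["treat_post_fp"] = 0.0
    ame = float((fit.predict(x1) - fit.predict(x0)).mean())

    lpm_spec = ModelSpec(outcome=spec.outcome, interaction=spec.interaction,
                         family="linear", clusters=spec.clusters,
                         exclude_anticipation=False,  # df already subset
                         covariates=tuple(keep_cov), on_collinear="drop",
                         crit_value=spec.crit_value)
    lpm = fit_fe_ols(df, lpm_spec)

    baseline = pre_period_snf_mean(df, ycol)
    rel = {"treat_post": relative_change(ame, baseline)} if baseline > 0 else {}
    return DiDResult(
        beta={"treat_post_ame": ame,
              "treat_post_lpm": lpm.beta["treat_post"]},
        se={"treat_post_lpm": lpm.se["treat_post"]},
        ci95={"treat_post_lpm": lpm.ci95["treat_post"]},
        vcov=lpm.vcov, n_obs=len(df),
        n_episodes=df["episode_id"].nunique(), baseline=baseline,
        relative_change=rel, absorbed=lpm.absorbed,
        dropped=lpm.dropped, cluster_counts=lpm.cluster_counts,
        vcov_repaired=lpm.vcov_repaired, family="logit",
        extra={"n_dropped_groups": n_dropped_groups,
               "logit_converged": bool(getattr(fit, "mle_retvals", {}).get(
                   "converged", True))})


def relative_change(estimate: float, baseline: float) -> float:
    """Percent change of an estimated effect against the pre-period SNF
    baseline, rounded to one decimal below 100 and to the nearest integer
    above (the convention used when printing results)."""
    if baseline <= 0:
        raise DomainError(f"baseline must be positive, got {baseline}")
    value = 100.0 * estimate / baseline
    return round(value, 1) if abs(value) < 100 else float(round(value))


def fit_stratified(panel: pd.DataFrame, spec: ModelSpec,
                   stratum: str) -> DiDResult:
    """Fit the two-way model within one SNF profit stratum
    (``"for_profit"`` / ``"not_for_profit"``, or ``"fp"`` / ``"nfp"``)."""
    fp_value = {"for_profit": 1, "fp": 1, "not_for_profit": 0, "nfp": 0}.get(stratum)
    if fp_value is None:
        raise SpecificationError(f"unknown stratum {stratum!r}")
    sub = panel[panel["fp"] == fp_value].reset_index(drop=True)
    if sub.empty:
        raise SpecificationError(f"stratum {stratum!r} is empty")
    strat_spec = ModelSpec(outcome=spec.outcome, interaction="two_way",
                           family=spec.family, clusters=spec.clusters,
                           exclude_anticipation=spec.exclude_anticipation,
                           covariates=spec.covariates,
                           on_collinear=spec.on_collinear,
                           crit_value=spec.crit_value)
    return fit_fe_ols(sub, strat_spec)
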