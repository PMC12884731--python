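"""Parallel-trends diagnostics: event-study estimation, joint pre-trend
F-test, and unadjusted monthly trend series.

The event study replaces the single Treat x Post interaction with
Treat x month dummies (the last pre-announcement month is the omitted
reference), using the same fixed-effect absorption and multiway-clustered
variance machinery as the pooled model. The joint F-test asks whether the
pre-announcement interaction coefficients are all zero; a rejection flags a
differential pre-trend. These are diagnostic outputs, not gates: the
analysis proceeds either way and the test result travels with the report.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .estimation import ModelSpec, fe_ols_core
from .exceptions import SpecificationError
from .panel import COVARIATE_COLUMNS


@dataclass
class EventStudyResult:
    """Treat x month coefficients with clustered SEs and the pre-trend test."""

    coefficients: pd.DataFrame        # columns: month, coef, se, pre
    reference_month: str
    pretrend_F: float
    pretrend_df: tuple[int, int]
    pretrend_p: float
    cluster_counts: dict[str, int] = field(default_factory=dict)
    pre_vcov: np.ndarray | None = None
    pre_terms: list[str] = field(default_factory=list)


def event_study(panel: pd.DataFrame, outcome: str = "n_dx",
                announcement_date: dt.date = dt.date(2018, 10, 1),
                spec: ModelSpec | None = None,
                reference_month: str | None = None) -> EventStudyResult:
    """Estimate Treat x month coefficients around the announcement.

    Requires at least 6 pre-announcement months in the panel. The reference
    month (coefficient fixed at 0 by omission) defaults to the last month
    before the announcement.

    Unless a spec overrides it, standard errors are clustered on the
    beneficiary only: each Treat x month regressor is non-zero inside a
    single time cluster (so a time-clustered variance component is not
    identified for it), and the per-coefficient score support is too thin
    for a reliable facility-cluster sandwich when the month-dummy count
    approaches the facility count. Beneficiary clustering captures the
    within-episode pairing that drives the sampling error here.
    """
    spec = spec or ModelSpec(outcome=outcome, clusters=("beneficiary",))
    ycol = spec.outcome_column() if spec.outcome == outcome else \
        ModelSpec(outcome=outcome).outcome_column()
    months = sorted(panel["ym"].unique())
    ann_ym = f"{announcement_date.year}-{announcement_date.month:02d}"
    pre_months = [m for m in months if m < ann_ym]
    if len(pre_months) < 6:
        raise SpecificationError(
            f"need >=6 pre-announcement months, found {len(pre_months)}")
    ref = reference_month or pre_months[-1]
    if ref not in months:
        raise SpecificationError(f"reference month {ref!r} not in panel")

    df = panel.reset_index(drop=True)
    treat = df["treat"].to_numpy(dtype=float)
    ym = df["ym"].to_numpy()
    es_block = {f"es_{m}": treat * (ym == m) for m in months if m != ref}
    es_cols = list(es_block)
    df = pd.concat([df, pd.DataFrame(es_block, index=df.index)], axis=1)

    covs = list(spec.covariates) if spec.covariates is not None else \
        [c for c in COVARIATE_COLUMNS if c in df.columns]
    core_spec = ModelSpec(outcome=outcome, clusters=spec.clusters,
                          on_collinear="drop", crit_value=spec.crit_value,
                          demean_tol=spec.demean_tol,
                          demean_max_iter=spec.demean_max_iter)
    core = fe_ols_core(df, ycol, es_cols + covs, core_spec)

    terms = core["terms"]
    beta = dict(zip(terms, core["beta"]))
    se = dict(zip(terms, np.sqrt(np.diag(core["vcov"]))))
    rows = [{"month": ref, "coef": 0.0, "se": 0.0, "pre": True}]
    for m in months:
        col = f"es_{m}"
        if m == ref or col not in beta:
            continue
        rows.append({"month": m, "coef": float(beta[col]),
                     "se": float(se[col]), "pre": m < ann_ym})
    coef_table = pd.DataFrame(rows).sort_values("month", ignore_index=True)

    pre_terms = [f"es_{m}" for m in pre_months if m != ref and f"es_{m}" in terms]
    idx = [terms.index(t) for t in pre_terms]
    b_pre = core["beta"][idx]
    v_pre = core["vcov"][np.ix_(idx, idx)]
    g_min = min(core["cluster_counts"][m] for m in core["cluster_counts"]
                if "*" not in m)
    f_stat, dfs, p = _wald_f(b_pre, v_pre, g_min)

    return EventStudyResult(
        coefficients=coef_table, reference_month=ref,
        pretrend_F=f_stat, pretrend_df=dfs, pretrend_p=p,
        cluster_counts=core["cluster_counts"],
        pre_vcov=v_pre, pre_terms=pre_terms)


def _wald_f(b: np.ndarray, v: np.ndarray, g_min: int
            ) -> tuple[float, tuple[int, int], float]:
    q = len(b)
    if q == 0:
        raise SpecificationError("no pre-period coefficients to test")
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e12:
        raise SpecificationError(
            f"singular restriction covariance (condition number {cond:.3g})")
    wald = float(b @ np.linalg.solve(v, b))
    f_stat = wald / q
    df2 = max(g_min - 1, 1)
    p = float(scipy.stats.f.sf(f_stat, q, df2))
    return f_stat, (q, df2), p


def pretrend_ftest(es: EventStudyResult) -> tuple[float, float]:
    """Joint Wald test (F form) that all pre-announcement Treat x month
    coefficients are zero, using the multiway-clustered covariance.
    Returns ``(F, p)``."""
    if es.pre_vcov is None or len(es.pre_terms) == 0:
        return es.pretrend_F, es.pretrend_p
    coefs = es.coefficients.set_index("month")
    months = [t[len("es_"):] for t in es.pre_terms]
    b = coefs.loc[months, "coef"].to_numpy()
    if len(b) >= 2:
        g_min = min((v for k, v in es.cluster_counts.items() if "*" not in k),
                    default=es.pretrend_df[1] + 1)
        f_stat, _, p = _wald_f(b, es.pre_vcov, g_min)
        return f_stat, p
    # single pre coefficient: F = (b/se)^2 / 1
    se = float(np.sqrt(es.pre_vcov[0, 0]))
    f_stat = float((b[0] / se) ** 2) if se > 0 else 0.0
    p = float(scipy.stats.f.sf(f_stat, 1, max(es.pretrend_df[1], 1)))
    return f_stat, p


def monthly_trends(panel: pd.DataFrame, outcome: str = "n_dx") -> pd.DataFrame:
    """Unadjusted monthly means by setting and their difference.

    Returns a plot-ready table with one row per month present in the panel:
    ``month, mean_hospital, mean_snf, difference`` (SNF minus hospital).
    Months with no observations are omitted.
    """
    ycol = ModelSpec(outcome=outcome).outcome_column()
    g = panel.groupby(["ym", "treat"])[ycol].mean().unstack("treat")
    out = pd.DataFrame({
        "month": g.index,
        "mean_hospital": g.get(0, np.nan),
        "mean_snf": g.get(1, np.nan),
    }).reset_index(drop=True)
    out["difference"] = out["mean_snf"] - out["mean_hospital"]
    return out


def plot_trends(trends: pd.DataFrame, announcement_month: str | None = None,
                ax=None, title: str | None = None):
    """Line chart of the monthly trend table (optional output helper)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 5))
    x = np.arange(len(trends))
    ax.plot(x, trends["mean_hospital"], label="hospital claims")
    ax.plot(x, trends["mean_snf"], label="SNF claims")
    ax.plot(x, trends["difference"], label="difference (SNF - hospital)")
    if announcement_month is not None and announcement_month in set(trends["month"]):
        ax.axvline(list(trends["month"]).index(announcement_month),
                   linestyle="--", color="grey")
    step = max(len(trends) // 12, 1)
    ax.set_xticks(x[::step])
    ax.set_xticklabels(trends["month"][::step], rotation=45, ha="right")
    ax.set_xlabel("month")
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
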