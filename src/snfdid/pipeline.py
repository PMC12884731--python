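"""End-to-end orchestration: simulate -> score -> link -> panel -> fit ->
diagnose, with a report shaped like the study's headline tables.

``run_pipeline`` executes every stage from a single master seed, writes all
intermediate tables under a run directory, and emits a JSON report with:

* ``table2`` — DiD estimates for diagnosis count and weighted Elixhauser
  score: all SNFs, for-profit and not-for-profit strata, and the three-way
  profit interaction, each including and excluding the anticipation period;
* ``table3`` — per-condition probability increases (logit marginal effects
  with a linear-probability companion) and relative increases;
* ``diagnostics_summary`` — pre-trend F and p per continuous outcome;
* ``provenance`` — seed, package version, timestamps, resolved config.

Every relative change in the report is recomputable from its own estimate
and baseline via :func:`snfdid.estimation.relative_change`.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .comorbidity import CONDITION_CATEGORIES, score_claims_frame
from .config import SimConfig
from .diagnostics import event_study, monthly_trends
from .episodes import build_episode_table
from .estimation import (ModelSpec, fit_fe_logit_ame, fit_fe_ols,
                         fit_stratified)
from .io import write_table
from .panel import build_panel
from .simulate import generate_population, simulate_episode_claims

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    config_echo: dict
    exclusions: dict
    table2: dict
    table3: dict
    diagnostics_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"config_echo": self.config_echo, "exclusions": self.exclusions,
                "table2": self.table2, "table3": self.table3,
                "diagnostics_summary": self.diagnostics_summary,
                "provenance": self.provenance}


def _entry(result) -> dict:
    key = "treat_post" if "treat_post" in result.beta else "treat_post_ame"
    d = {
        "estimate": result.beta[key],
        "ci95": list(result.ci95.get(key, result.ci95.get("treat_post_lpm", (None, None)))),
        "baseline": result.baseline,
        "relative_change": result.relative_change.get("treat_post"),
        "n_obs": result.n_obs, "n_episodes": result.n_episodes,
    }
    if "treat_post_fp" in result.beta:
        d["triple_term"] = {
            "estimate": result.beta["treat_post_fp"],
            "ci95": list(result.ci95["treat_post_fp"]),
            "relative_change": result.relative_change.get("treat_post_fp"),
        }
    if "treat_post_lpm" in result.beta:
        d["lpm_estimate"] = result.beta["treat_post_lpm"]
    return d


def run_pipeline(config: SimConfig, out_dir, *, seed: int | None = None,
                 logit_conditions: bool = True,
                 event_study_outcomes: tuple[str, ...] = ("n_dx", "elix"),
                 ) -> RunReport:
    """Run every stage and write tables, diagnostics and the final report."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.replace(seed=seed)
    config.validate()

    logger.info("stage 1/6: population")
    bene, fac = generate_population(config)
    logger.info("  %d beneficiaries, %d facilities", len(bene), len(fac))

    logger.info("stage 2/6: claims")
    claims = simulate_episode_claims(config, bene, fac)
    logger.info("  %d claims", len(claims))

    logger.info("stage 3/6: comorbidity scoring")
    profiles = score_claims_frame(claims)

    logger.info("stage 4/6: episodes")
    episodes, tally = build_episode_table(
        claims, bene, fac,
        announcement_date=config.announcement_date,
        implementation_date=config.implementation_date,
        study_end=config.study_end)
    logger.info("  %d episodes included; exclusions %s",
                len(episodes), tally.counts)

    logger.info("stage 5/6: panel")
    panel = build_panel(episodes, claims, profiles, fac)

    write_table(bene, out / "beneficiaries.csv")
    write_table(fac, out / "facilities.csv")
    write_table(claims, out / "claims.csv")
    write_table(profiles, out / "profiles.csv")
    write_table(episodes, out / "episodes.csv")
    write_table(panel, out / "panel.csv")

    logger.info("stage 6/6: estimation")
    table2: dict = {}
    for outcome in ("n_dx", "elix"):
        table2[outcome] = {}
        for antic_label, excl in (("including_anticipation", False),
                                  ("excluding_anticipation", True)):
            spec2 = ModelSpec(outcome=outcome, exclude_anticipation=excl,
                              on_collinear="drop")
            spec3 = ModelSpec(outcome=outcome, interaction="three_way",
                              exclude_anticipation=excl, on_collinear="drop")
            table2[outcome][antic_label] = {
                "all_snfs": _entry(fit_fe_ols(panel, spec2)),
                "for_profit": _entry(fit_stratified(panel, spec2, "for_profit")),
                "not_for_profit": _entry(fit_stratified(panel, spec2,
                                                        "not_for_profit")),
                "three_way": _entry(fit_fe_ols(panel, spec3)),
            }

    table3: dict = {}
    if logit_conditions:
        for name in CONDITION_CATEGORIES:
            spec = ModelSpec(outcome=name, family="logit",
                             exclude_anticipation=False, on_collinear="drop")
            res = fit_fe_logit_ame(panel, spec)
            entry = _entry(res)
            entry["estimate_pp"] = 100.0 * entry["estimate"]
            table3[name] = entry

    diagnostics_summary: dict = {}
    for outcome in event_study_outcomes:
        es = event_study(panel, outcome,
                         announcement_date=config.announcement_date,
                         spec=ModelSpec(outcome=outcome, on_collinear="drop",
                                        clusters=("beneficiary",)))
        diagnostics_summary[outcome] = {
            "pretrend_F": es.pretrend_F, "pretrend_p": es.pretrend_p,
            "pretrend_df": list(es.pretrend_df),
            "reference_month": es.reference_month,
        }
        write_table(es.coefficients, out / f"event_study_{outcome}.csv")
        write_table(monthly_trends(panel, outcome),
                    out / f"monthly_trends_{outcome}.csv")

    report = RunReport(
        config_echo=config.to_dict(),
        exclusions=tally.as_dict(),
        table2=table2, table3=table3,
        diagnostics_summary=diagnostics_summary,
        provenance={
            "seed": config.seed, "version": __version__,
            "timestamp": dt.datetime.now().isoformat(timespec="seconds"),
            "runtime_seconds": round(time.time() - t0, 1),
        })
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=float)
    _write_human_readable(report, out / "report.txt")
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return report


def _write_human_readable(report: RunReport, path) -> None:
    lines = ["Coding-intensity DiD report", "=" * 40, ""]
    for outcome, blocks in report.table2.items():
        lines.append(f"Outcome: {outcome}")
        for antic, models in blocks.items():
            lines.append(f"  [{antic}]")
            for model, e in models.items():
                ci = e["ci95"]
                rel = e["relative_change"]
                lines.append(
                    f"    {model:15s} {e['estimate']:+.3f} "
                    f"[{ci[0]:.3f}, {ci[1]:.3f}]  baseline {e['baseline']:.2f}"
                    f"  relative {rel if rel is not None else 'n/a'}%")
                if "triple_term" in e:
                    t = e["triple_term"]
                    lines.append(
                        f"      triple term {t['estimate']:+.3f} "
                        f"[{t['ci95'][0]:.3f}, {t['ci95'][1]:.3f}]"
                        f"  relative {t['relative_change']}%")
        lines.append("")
    if report.table3:
        lines.append("Documentation-sensitive conditions (probability scale)")
        for name, e in report.table3.items():
            lines.append(
                f"  {name:22s} AME {e['estimate_pp']:+.2f} pp"
                f"  baseline {100 * e['baseline']:.1f}%"
                f"  relative {e['relative_change']}%")
        lines.append("")
    lines.append("Pre-trend tests")
    for outcome, d in report.diagnostics_summary.items():
        lines.append(f"  {outcome}: F={d['pretrend_F']:.2f} "
                     f"df={tuple(d['pretrend_df'])} p={d['pretrend_p']:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
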