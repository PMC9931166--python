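"""Pipeline stages: simulate -> extract IPs -> AUC -> fits -> stability -> report.

Each stage reads/writes plain files (CSV for tables, JSON for nested
results, Markdown for the report) inside an output directory.  Every JSON
artifact is stamped with the run's seed and configuration hash; the trial
CSV carries the seed as a column.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from .cohort import simulate_cohort
from .config import RunConfig
from .measures import auc_table
from .models import compare_models_table
from .stability import StabilityAnalysis
from .titration import curves_to_frame, extract_ips

__all__ = [
    "stage_simulate",
    "stage_extract_ips",
    "stage_auc",
    "stage_fit_models",
    "stage_stability",
    "stage_report",
    "run_all",
]

log = logging.getLogger("discountkit")

FILES = {
    "trials": "trials.csv",
    "truth": "truth.csv",
    "ips": "ips.csv",
    "auc": "auc.csv",
    "fits": "fits.json",
    "stability": "stability.json",
    "report": "report.md",
    "config": "config.yaml",
}


def _stamp(config: RunConfig) -> dict:
    return {"seed": config.master_seed, "config_hash": config.config_hash()}


def _timed(stage):
    def wrapper(config, outdir, *a, **kw):
        t0 = time.perf_counter()
        result = stage(config, outdir, *a, **kw)
        log.info("%s finished in %.2fs", stage.__name__, time.perf_counter() - t0)
        return result

    return wrapper


@_timed
def stage_simulate(config: RunConfig, outdir: Path) -> None:
    trials, truth = simulate_cohort(
        config.cohort, config.schedule_objects(), ip_rule=config.ip_rule
    )
    trials.to_csv(outdir / FILES["trials"], index=False)
    truth.to_csv(outdir / FILES["truth"], index=False)
    log.info("simulate: %d trial rows, %d truth rows", len(trials), len(truth))


@_timed
def stage_extract_ips(config: RunConfig, outdir: Path) -> None:
    trials = pd.read_csv(outdir / FILES["trials"])
    curves = extract_ips(trials, ip_rule=config.ip_rule)
    curves_to_frame(curves).to_csv(outdir / FILES["ips"], index=False)
    log.info("extract-ips: %d curves", len(curves))


def _load_curves(config: RunConfig, outdir: Path):
    from .titration import IndifferenceCurve

    ips = pd.read_csv(outdir / FILES["ips"])
    curves = []
    for (pid, tp, task), grp in ips.groupby(
        ["participant_id", "timepoint", "task"], sort=True
    ):
        grp = grp.sort_values("cost_value")
        curves.append(
            IndifferenceCurve(
                participant_id=str(pid),
                timepoint=int(tp),
                task=task,
                costs=tuple(grp["cost_value"]),
                ips=tuple(grp["ip"]),
                amount_large=config.amount,
            )
        )
    return curves


@_timed
def stage_auc(config: RunConfig, outdir: Path) -> None:
    curves = _load_curves(config, outdir)
    table = auc_table(curves, config.amount, config.anchor, config.anchor_y)
    table.to_csv(outdir / FILES["auc"], index=False)
    log.info("auc: %d rows", len(table))


@_timed
def stage_fit_models(config: RunConfig, outdir: Path) -> None:
    curves = _load_curves(config, outdir)
    by_key: dict = {}
    for c in curves:
        by_key.setdefault((c.task.value, c.timepoint), []).append(c)
    table = compare_models_table(by_key, amount=config.amount)
    payload = {**_stamp(config), "comparisons": table.to_dict(orient="records")}
    (outdir / FILES["fits"]).write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info("fit-models: %d rows", len(table))


@_timed
def stage_stability(config: RunConfig, outdir: Path) -> None:
    auc = pd.read_csv(outdir / FILES["auc"])
    results = StabilityAnalysis(
        auc, zscore_scope=config.zscore_scope, kappa=config.kappa
    ).fit()
    payload = {**_stamp(config), **results.to_dict()}
    (outdir / FILES["stability"]).write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    log.info("stability: %d tasks", len(results.iccs))


@_timed
def stage_report(config: RunConfig, outdir: Path) -> None:
    fits = json.loads((outdir / FILES["fits"]).read_text())
    stab = json.loads((outdir / FILES["stability"]).read_text())
    auc = pd.read_csv(outdir / FILES["auc"])
    stamp = _stamp(config)

    lines = [
        "# Discounting pipeline report",
        "",
        f"seed: {stamp['seed']}  |  config hash: `{stamp['config_hash']}`",
        "",
        "## Model comparison (AICc)",
        "",
        "| task | timepoint | model | b | s | AICc | dAICc | support | best |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for row in fits["comparisons"]:
        lines.append(
            "| {task} | {timepoint} | {model_form} | {b:.4g} | {s:.3g} "
            "| {aicc:.2f} | {delta_aicc:.2f} | {support} | {best_mark} |".format(
                best_mark="*" if row["best"] else "", **row
            )
        )

    lines += ["", "## Test-retest correlations (relative stability)", ""]
    lines += [
        "| task | pair | r | BF10 | 95% CI | r band | BF band |",
        "|---|---|---|---|---|---|---|",
    ]
    for task, pairs in stab["retest"].items():
        for pair, bc in pairs.items():
            lines.append(
                f"| {task} | {pair} | {bc['r']:.2f} | {bc['bf10']:.2f} "
                f"| [{bc['rho_ci'][0]:.2f}, {bc['rho_ci'][1]:.2f}] "
                f"| {bc['r_band']} | {bc['bf_band']} |"
            )

    lines += ["", "## AUC_ord distribution by task and time point", ""]
    summary = (
        auc.groupby(["task", "timepoint"])["auc_ord"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )
    lines += [
        "| task | timepoint | n | mean | 25% | median | 75% |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, row in summary.iterrows():
        lines.append(
            f"| {row['task']} | {row['timepoint']} | {int(row['count'])} "
            f"| {row['mean']:.3f} | {row['25%']:.3f} | {row['50%']:.3f} "
            f"| {row['75%']:.3f} |"
        )

    lines += ["", "## Intraclass correlations (absolute agreement)", ""]
    lines += [
        "| task | ICC | 95% CI | band | % trait-like |",
        "|---|---|---|---|---|",
    ]
    for task, res in stab["icc"].items():
        lines.append(
            f"| {task} | {res['icc']:.2f} "
            f"| [{res['ci95'][0]:.2f}, {res['ci95'][1]:.2f}] "
            f"| {res['band']} | {res['pct_between']:.0f}% |"
        )
    lines.append("")
    (outdir / FILES["report"]).write_text("\n".join(lines))
    log.info("report written")


STAGES = [
    stage_simulate,
    stage_extract_ips,
    stage_auc,
    stage_fit_models,
    stage_stability,
    stage_report,
]


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage in order into ``outdir``; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / FILES["config"])
    for stage in STAGES:
        stage(config, outdir)
    return outdir
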