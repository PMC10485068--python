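"""End-to-end orchestration: simulate/load -> exclude -> describe -> slopes
-> efficiency -> report, with a single master seed and a config hash so a
rerun reproduces every number exactly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .descriptives import apply_exclusions, group_table, performance_summary
from .efficiency import EfficiencyContrast, EfficiencyEstimate, bootstrap_efficiency, efficiency_contrast
from .schema import TASKS, read_trials
from .sensitivity import contrast_slopes, fit_all_slopes


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``cohort`` (simulate) or ``input_csv`` (load) must be
    set.  ``master_seed`` fans out to per-stage child seeds by fixed
    derivation so stages can be rerun in isolation.
    """

    master_seed: int
    cohort: CohortConfig | None = None
    input_csv: str | None = None
    ceiling_accuracy: float = 0.95
    min_error_trials: int = 5
    n_boot_efficiency: int = 1000
    n_boot_slopes: int = 2000
    n_bins: int = 10
    r_scale: float = 0.7
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.cohort is None) == (self.input_csv is None):
            raise PipelineError("exactly one of cohort / input_csv must be set")

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.master_seed).generate_state(4, np.uint32)
        names = ("simulate", "slopes", "efficiency", "report")
        return {name: int(s % 2**31) for name, s in zip(names, state)}

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            if isinstance(o, dict):
                return {str(k): v for k, v in o.items()}
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: RunConfig
    trials: pd.DataFrame
    summaries: pd.DataFrame
    excluded: pd.DataFrame
    group_table: pd.DataFrame
    slope_table: pd.DataFrame
    slope_contrasts: list
    task_contrasts: list
    efficiency: dict  # (task, group) -> EfficiencyEstimate
    efficiency_contrasts: dict  # task -> EfficiencyContrast (scz - control)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage; write machine-readable outputs if configured."""
    config.validate()
    seeds = config.stage_seeds()
    stage = "load"
    try:
        if config.cohort is not None:
            stage = "simulate"
            cohort_cfg = dataclasses.replace(config.cohort, master_seed=seeds["simulate"])
            trials, _ = simulate_cohort(cohort_cfg)
        else:
            if not Path(config.input_csv).exists():
                raise PipelineError(f"input CSV not found: {config.input_csv}")
            trials = read_trials(config.input_csv)

        stage = "describe"
        summaries = performance_summary(trials)
        kept, excluded = apply_exclusions(
            summaries,
            ceiling_accuracy=config.ceiling_accuracy,
            min_error_trials=config.min_error_trials,
        )
        kept_trials = trials[trials["subject_id"].isin(kept["subject_id"])]
        gtab = group_table(kept, r_scale=config.r_scale)

        stage = "slopes"
        slope_table = fit_all_slopes(kept_trials)
        slope_contrasts = contrast_slopes(
            slope_table,
            by="group_within_task",
            n_boot=config.n_boot_slopes,
            seed=seeds["slopes"],
            r_scale=config.r_scale,
        )
        task_contrasts = contrast_slopes(
            slope_table,
            by="task_within_group",
            n_boot=config.n_boot_slopes,
            seed=seeds["slopes"] + 1,
            r_scale=config.r_scale,
        )

        stage = "efficiency"
        from .efficiency import confidence_bin_edges

        eff: dict = {}
        eff_contrasts: dict = {}
        for ti, task in enumerate(TASKS):
            task_trials = kept_trials[kept_trials["task"] == task]
            # shared bins across groups: comparable estimates, binning
            # noise cancelled from the contrast
            edges = confidence_bin_edges(
                task_trials["confidence"].to_numpy(), n_bins=config.n_bins
            )
            per_group = {}
            for gi, group in enumerate(("control", "scz")):
                sub = task_trials[task_trials["group"] == group]
                per_group[group] = bootstrap_efficiency(
                    sub,
                    B=config.n_boot_efficiency,
                    seed=seeds["efficiency"] + 10 * ti + gi,
                    n_bins=config.n_bins,
                    task=task,
                    group=group,
                    bin_edges=edges,
                )
                eff[(task, group)] = per_group[group]
            eff_contrasts[task] = efficiency_contrast(per_group["scz"], per_group["control"])

        stage = "manifest"
        manifest = {
            "software": f"metaconf {__version__}",
            "master_seed": config.master_seed,
            "stage_seeds": seeds,
            "config_hash": config.config_hash(),
            "n_subjects_kept": int(kept["subject_id"].nunique()),
            "n_subjects_excluded": int(excluded["subject_id"].nunique()) if len(excluded) else 0,
        }
        bundle = ReportBundle(
            config=config,
            trials=trials,
            summaries=summaries,
            excluded=excluded,
            group_table=gtab,
            slope_table=slope_table,
            slope_contrasts=slope_contrasts,
            task_contrasts=task_contrasts,
            efficiency=eff,
            efficiency_contrasts=eff_contrasts,
            manifest=manifest,
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err
    if config.output_dir is not None:
        _write_outputs(bundle, Path(config.output_dir))
    return bundle


def _efficiency_json(bundle: ReportBundle) -> dict:
    out = {"estimates": {}, "contrasts": {}}
    for (task, group), est in bundle.efficiency.items():
        out["estimates"][f"{task}/{group}"] = {
            "eta": est.eta,
            "auc2_observer": est.auc2_observer,
            "auc2_ideal": est.auc2_ideal,
            "sigma_c_hat": est.sigma_c_hat,
            "alpha_hat": est.alpha_hat,
            "ci95": list(est.ci95) if est.ci95 else None,
            "n_bootstrap": int(len(est.bootstrap_etas)) if est.bootstrap_etas is not None else 0,
            "seed": est.seed,
        }
    for task, con in bundle.efficiency_contrasts.items():
        out["contrasts"][task] = {
            "label": con.label,
            "mean_diff": con.mean_diff,
            "ci95": list(con.ci95),
        }
    return out


def _write_outputs(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.summaries.to_csv(outdir / "summaries.csv", index=False)
    bundle.excluded.to_csv(outdir / "exclusions.csv", index=False)
    bundle.group_table.to_csv(outdir / "group_table.csv", index=False)
    bundle.slope_table.to_csv(outdir / "slope_table.csv", index=False)
    contrasts = pd.DataFrame(
        [dataclasses.asdict(c) for c in bundle.slope_contrasts + bundle.task_contrasts]
    )
    contrasts.to_csv(outdir / "slope_contrasts.csv", index=False)
    (outdir / "efficiency.json").write_text(
        json.dumps(_efficiency_json(bundle), indent=2, sort_keys=True)
    )
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
    (outdir / "report.txt").write_text(make_report(bundle))


def _fmt(x, nd=2) -> str:
    return "—" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def make_report(bundle: ReportBundle) -> str:
    """Human-readable run summary (group tables, contrasts, efficiency)."""
    lines = [
        f"metaconf run — config {bundle.manifest.get('config_hash', '?')}, "
        f"seed {bundle.config.master_seed}",
        f"{bundle.manifest.get('n_subjects_excluded', 0)} excluded, "
        f"{bundle.manifest.get('n_subjects_kept', '?')} analyzed",
        "",
        "Group descriptives (control vs scz; Welch t, JZS BF):",
    ]
    for _, r in bundle.group_table.iterrows():
        lines.append(
            f"  {r['task']:<12} {r['measure']:<26} "
            f"{_fmt(r['control_mean'])} ± {_fmt(r['control_sd'])}  vs  "
            f"{_fmt(r['scz_mean'])} ± {_fmt(r['scz_sd'])}   "
            f"t={_fmt(r['t'])} p={_fmt(r['p'], 3)} BF={_fmt(r['bf10'])}"
        )
    lines += ["", "Metacognitive-sensitivity contrasts (slope units):"]
    for c in bundle.slope_contrasts + bundle.task_contrasts:
        lines.append(
            f"  {c.label:<36} {c.estimate:+.2f} "
            f"[{c.interval_low:+.2f}, {c.interval_high:+.2f}]  BF={_fmt(c.bf10)}"
        )
    lines += ["", "Confidence efficiency (eta, bootstrap 95% CI):"]
    for (task, group), est in sorted(bundle.efficiency.items()):
        ci = f"[{est.ci95[0]:.2f}, {est.ci95[1]:.2f}]" if est.ci95 else "—"
        lines.append(f"  {task:<12} {group:<8} eta={est.eta:.2f} {ci}")
    for task, con in bundle.efficiency_contrasts.items():
        lines.append(
            f"  {task:<12} scz-control  diff={con.mean_diff:+.2f} "
            f"[{con.ci95[0]:+.2f}, {con.ci95[1]:+.2f}]"
        )
    return "\n".join(lines) + "\n"
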