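"""One-call pipeline: synthesize (or accept) a dataset, compute trial
metrics, summarize by block, run the group statistics, write all outputs.

Deterministic given the run configuration's seed: the experiment generator
and the Monte-Carlo post-hoc draw from independent children of one seed
sequence, and every CSV is written with a fixed float format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .analysis import (
    AnovaResult,
    PosthocResult,
    ReferencePaths,
    compute_trial_metrics,
    many_to_one_posthoc,
    one_way_anova,
    summarize_blocks,
)
from .config import RunConfig
from .synth import ExperimentDataset, generate_experiment

logger = logging.getLogger("kinepath")

__all__ = ["PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.12g"
METRICS = ("dfd_straight", "dfd_energy")


@dataclass
class PipelineResult:
    """Everything the analysis produced, plus where it was written."""

    dataset: ExperimentDataset
    metrics: pd.DataFrame
    subject_summary: pd.DataFrame
    group_summary: pd.DataFrame
    anova: dict[str, AnovaResult]
    posthoc: dict[str, PosthocResult]
    last_block_means: pd.DataFrame
    excluded: int
    output_files: dict = field(default_factory=dict)


def _last_block_groups(subject_summary: pd.DataFrame, metric: str):
    last = subject_summary["block"].max()
    sel = subject_summary[subject_summary["block"] == last]
    labels = sorted(sel["group"].unique())
    return labels, [sel[sel["group"] == g][metric].to_numpy() for g in labels]


def run_pipeline(
    config: RunConfig | None = None,
    dataset: ExperimentDataset | None = None,
    out_dir=None,
    make_figures: bool = True,
) -> PipelineResult:
    """Run the full analysis; write outputs when an output directory is set.

    ``dataset=None`` synthesizes the experiment from the configuration.  The
    control group for the many-to-one contrasts is the first (veridical-
    feedback) group.
    """
    config = config or RunConfig()
    out_dir = out_dir if out_dir is not None else config.out_dir
    rng_tree = np.random.SeedSequence(config.seed).spawn(2)
    if dataset is None:
        logger.info("generating synthetic experiment (seed=%d)", config.seed)
        dataset = generate_experiment(
            replace(config.experiment, seed=config.seed),
            specs=config.groups,
            layout=config.layout,
            pend_params=config.pendulum,
            pm_params=config.point_mass,
            coupling=config.coupling,
            simulate_forces=config.simulate_forces,
        )
    if len(dataset) == 0:
        raise ValueError("no trials in dataset")
    refs = ReferencePaths(
        dataset.layout,
        pend_params=config.pendulum,
        pm_params=config.point_mass,
        n_samples=config.analysis.n_samples,
        cache_dir=config.cache_dir,
    )
    metrics = compute_trial_metrics(dataset, refs, frac=config.analysis.frac)
    excluded = int(metrics["excluded"].sum())
    if excluded:
        logger.info("excluded %d non-segmentable trials", excluded)
    subject_summary, group_summary = summarize_blocks(metrics)

    anova: dict[str, AnovaResult] = {}
    posthoc: dict[str, PosthocResult] = {}
    mc_rng = np.random.default_rng(rng_tree[1])
    rows = []
    for metric in METRICS:
        labels, groups = _last_block_groups(subject_summary, metric)
        anova[metric] = one_way_anova(groups)
        posthoc[metric] = many_to_one_posthoc(
            groups, control=0, n_mc=config.analysis.n_mc, seed=mc_rng
        )
        for g, vals in zip(labels, groups):
            rows.append({"metric": metric, "group": g, "mean": vals.mean(),
                         "sd": vals.std(ddof=1), "n": vals.size})
    last_block_means = pd.DataFrame(rows)

    result = PipelineResult(
        dataset=dataset, metrics=metrics, subject_summary=subject_summary,
        group_summary=group_summary, anova=anova, posthoc=posthoc,
        last_block_means=last_block_means, excluded=excluded,
    )
    if out_dir is not None:
        result.output_files = _write_outputs(result, config, refs, FsPath(out_dir), make_figures)
    return result


def _comparisons_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    labels = sorted(result.last_block_means["group"].unique())
    for metric in METRICS:
        a = result.anova[metric]
        rows.append({"metric": metric, "test": "anova", "comparison": "omnibus",
                     "statistic": a.F, "df1": a.df_between, "df2": a.df_within,
                     "p_value": a.p_value, "p_adjusted": np.nan, "p_bonferroni": np.nan})
        ph = result.posthoc[metric]
        for (i, c), t, pu, pb, pa in zip(ph.comparisons, ph.t_stats, ph.p_unadjusted,
                                         ph.p_bonferroni, ph.p_adjusted):
            rows.append({"metric": metric, "test": "many_to_one",
                         "comparison": f"group{labels[i]}_vs_group{labels[c]}",
                         "statistic": t, "df1": 1, "df2": ph.df,
                         "p_value": pu, "p_adjusted": pa, "p_bonferroni": pb})
    return pd.DataFrame(rows)


def _write_outputs(result, config, refs, out: FsPath, make_figures: bool) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(name, df):
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        files[name] = path

    _write("metrics.csv", result.metrics)
    _write("summary_subject.csv", result.subject_summary)
    _write("summary_group.csv", result.group_summary)
    _write("comparisons.csv", _comparisons_frame(result))
    _write("last_block_means.csv", result.last_block_means)
    import hashlib

    import numpy
    import scipy

    from . import __version__

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "versions": {"kinepath": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
        "n_trials": len(result.dataset),
        "n_excluded": result.excluded,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest.json"] = out / "manifest.json"
    log_lines = [
        f"seed={config.seed} config_hash={cfg_hash}",
        f"trials={len(result.dataset)} excluded={result.excluded}",
    ]
    for metric in METRICS:
        a = result.anova[metric]
        ph = result.posthoc[metric]
        adj = ", ".join(f"{p:.3e}" for p in ph.p_adjusted)
        log_lines.append(
            f"{metric}: F({a.df_between},{a.df_within})={a.F:.4f} p={a.p_value:.3e} "
            f"adjusted_p=[{adj}]"
        )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    files["run.log"] = out / "run.log"
    if make_figures:
        from .plots import figure_average_paths, figure_learning_curves, save_figure

        fig = figure_average_paths(result.dataset, refs)
        save_figure(fig, out / "fig_average_paths.png")
        files["fig_average_paths.png"] = out / "fig_average_paths.png"
        fig = figure_learning_curves(result.group_summary)
        save_figure(fig, out / "fig_learning_curves.png")
        files["fig_learning_curves.png"] = out / "fig_learning_curves.png"
    return files
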