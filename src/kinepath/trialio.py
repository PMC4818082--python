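"""On-disk formats: per-trial CSV, dataset directories with a manifest.

Trial CSV dialect: comma-separated, header ``t,x,y,vx,vy,fx,fy``, UTF-8,
decimal point, one row per 100 Hz sample; ``fx``/``fy`` are empty for
purely kinematic trajectories.  A dataset directory holds one CSV per trial
under ``trials/``, a ``manifest.csv`` indexing them, and a ``dataset.json``
sidecar echoing the generating configuration for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import Trajectory
from .synth import ExperimentDataset, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "write_trial_csv",
    "read_trial_csv",
    "write_dataset",
    "read_dataset",
]

TRIAL_COLUMNS = ["t", "x", "y", "vx", "vy", "fx", "fy"]
_FLOAT_FMT = "%.12g"


def write_trial_csv(path, traj: Trajectory) -> None:
    """Write one trajectory in the trial CSV dialect."""
    force = traj.force if traj.force is not None else np.full_like(traj.pos, np.nan)
    df = pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.pos[:, 0], "y": traj.pos[:, 1],
            "vx": traj.vel[:, 0], "vy": traj.vel[:, 1],
            "fx": force[:, 0], "fy": force[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_csv(path) -> Trajectory:
    """Read a trial CSV; malformed content raises a line-numbered error."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed trial CSV: {exc}") from exc
    for col in TRIAL_COLUMNS[:5]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    num = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: line {line}: could not parse value "
                f"{df[col][bad.idxmax()]!r} in column '{col}'"
            )
        num[col] = coerced.to_numpy(dtype=float)
    force = None
    if "fx" in num and "fy" in num and not (np.all(np.isnan(num["fx"]))):
        force = np.column_stack([num["fx"], num["fy"]])
    return Trajectory(
        t=num["t"],
        pos=np.column_stack([num["x"], num["y"]]),
        vel=np.column_stack([num["vx"], num["vy"]]),
        force=force,
    )


def _trial_filename(tr: TrialRecord) -> str:
    return f"g{tr.group}_s{tr.subject:02d}_b{tr.block:02d}_t{tr.trial:03d}.csv"


def write_dataset(dataset: ExperimentDataset, out_dir, config: RunConfig | None = None) -> FsPath:
    """Write a dataset directory: per-trial CSVs, manifest, JSON sidecar."""
    out = FsPath(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in dataset:
        fname = _trial_filename(tr)
        write_trial_csv(trials_dir / fname, tr.trajectory)
        rows.append(
            {
                "group": tr.group, "subject": tr.subject, "block": tr.block,
                "trial": tr.trial, "start_target": tr.start_target,
                "end_target": tr.end_target, "file": f"trials/{fname}",
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    sidecar = {
        "experiment": {
            k: getattr(dataset.config, k)
            for k in ("subjects", "blocks", "reaches_per_block", "T", "rate",
                      "hold", "lead", "sim_dt", "seed")
        },
        "groups": [
            {"label": g.label, "object": g.haptic_object, "w_inf": g.w_inf,
             "learning_rate": g.learning_rate, "sigma": g.sigma,
             "endpoint_sigma": g.endpoint_sigma}
            for g in dataset.specs
        ],
        "layout": {"centers": [list(c) for c in dataset.layout.centers],
                   "diameter": dataset.layout.diameter},
    }
    if config is not None:
        sidecar["run_config"] = config.to_dict()
    (out / "dataset.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return out


def read_dataset(in_dir) -> ExperimentDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    from .paths import TargetLayout
    from .synth import ExperimentConfig, GroupSpec

    root = FsPath(in_dir)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{root}: no manifest.csv — not a dataset directory")
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"{root}: no trials listed in manifest")
    sidecar = json.loads((root / "dataset.json").read_text())
    cfg = ExperimentConfig(**sidecar["experiment"])
    specs = tuple(
        GroupSpec(label=g["label"], haptic_object=g["object"], w_inf=g["w_inf"],
                  learning_rate=g["learning_rate"], sigma=g["sigma"],
                  endpoint_sigma=g["endpoint_sigma"])
        for g in sidecar["groups"]
    )
    layout = TargetLayout(
        centers=tuple(tuple(c) for c in sidecar["layout"]["centers"]),
        diameter=sidecar["layout"]["diameter"],
    )
    trials = [
        TrialRecord(
            group=int(r.group), subject=int(r.subject), block=int(r.block),
            trial=int(r.trial), start_target=int(r.start_target),
            end_target=int(r.end_target),
            trajectory=read_trial_csv(root / r.file),
        )
        for r in manifest.itertuples()
    ]
    return ExperimentDataset(trials=trials, config=cfg, specs=specs, layout=layout)
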