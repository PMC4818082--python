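"""End-to-end analysis: per-trial path distances, summaries, group statistics.

Every reach is segmented at 10 % of peak speed, time-normalized, and compared
by discrete Fréchet distance to two references for its ordered target pair:
the straight segment and the path of least kinetic energy of the group's
haptic object (for the point mass the two coincide).  Subject means over the
last block are the unit of analysis: a one-way ANOVA tests for a group
effect, and many-to-one (Dunnett-style) contrasts compare each group against
the veridical-feedback group with family-wise error control, realized by
Monte-Carlo evaluation of the joint null distribution of the max-|t|
statistic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Path
from .dynamics import PendulumParams, PointMassParams
from .metrics import NoMovementError, discrete_frechet, segment_movement, time_normalize
from .paths import TargetLayout, geodesic_path, straight_path
from .synth import ExperimentDataset

__all__ = [
    "ReferencePaths",
    "compute_trial_metrics",
    "summarize_blocks",
    "one_way_anova",
    "many_to_one_posthoc",
    "AnovaResult",
    "PosthocResult",
]


class ReferencePaths:
    """Per-ordered-target-pair reference paths, cached in memory and on disk.

    The disk cache is keyed by a hash of the object parameters, layout and
    pair, so a change in any mechanical property invalidates it.
    """

    def __init__(
        self,
        layout: TargetLayout,
        pend_params: PendulumParams | None = None,
        pm_params: PointMassParams | None = None,
        n_samples: int = 100,
        cache_dir: str | FsPath | None = None,
    ):
        self.layout = layout
        self.pend_params = pend_params or PendulumParams()
        self.pm_params = pm_params or PointMassParams()
        self.n_samples = n_samples
        self.cache_dir = FsPath(cache_dir) if cache_dir is not None else None
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self._memory: dict = {}

    def _key(self, kind: str, pair: tuple[int, int]) -> str:
        payload = {
            "kind": kind,
            "pair": list(pair),
            "n": self.n_samples,
            "layout": {"centers": list(self.layout.centers), "diameter": self.layout.diameter},
            "pendulum": {
                k: getattr(self.pend_params, k)
                for k in ("m1", "m2", "l1", "l2", "I1", "I2", "c1", "c2", "base")
            },
            "point_mass": self.pm_params.m,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:24]

    def straight(self, pair: tuple[int, int]) -> Path:
        key = ("straight", pair)
        if key not in self._memory:
            self._memory[key] = straight_path(
                self.layout.center(pair[0]), self.layout.center(pair[1]), self.n_samples
            )
        return self._memory[key]

    def energy(self, pair: tuple[int, int], haptic_object: str = "pendulum") -> Path:
        """Least-kinetic-energy path for the pair (straight for a point mass)."""
        if haptic_object == "point_mass":
            return self.straight(pair)
        key = ("energy", pair)
        if key in self._memory:
            return self._memory[key]
        digest = self._key("energy", pair)
        if self.cache_dir is not None:
            f = self.cache_dir / f"geodesic_{digest}.json"
            if f.exists():
                pts = np.asarray(json.loads(f.read_text())["points"])
                path = Path(pts)
                self._memory[key] = path
                return path
        path = geodesic_path(
            self.pend_params,
            self.layout.center(pair[0]),
            self.layout.center(pair[1]),
            n_samples=self.n_samples,
        )
        if self.cache_dir is not None:
            f = self.cache_dir / f"geodesic_{digest}.json"
            f.write_text(json.dumps({"points": path.points.tolist()}))
        self._memory[key] = path
        return path


def compute_trial_metrics(
    dataset: ExperimentDataset,
    references: ReferencePaths | None = None,
    n_samples: int = 100,
    frac: float = 0.10,
    cache_dir=None,
) -> pd.DataFrame:
    """Per-trial discrete Fréchet distances to the two reference paths.

    Returns one row per trial with columns ``dfd_straight`` and
    ``dfd_energy`` (meters).  Trials whose movement cannot be segmented are
    flagged ``excluded`` with a reason and carry NaN distances.
    """
    refs = references or ReferencePaths(
        dataset.layout, n_samples=n_samples, cache_dir=cache_dir
    )
    objects = {spec.label: spec.haptic_object for spec in dataset.specs}
    rows = []
    for tr in dataset:
        row = {
            "group": tr.group,
            "subject": tr.subject,
            "block": tr.block,
            "trial": tr.trial,
            "start_target": tr.start_target,
            "end_target": tr.end_target,
            "dfd_straight": np.nan,
            "dfd_energy": np.nan,
            "excluded": False,
            "reason": "",
        }
        pair = (tr.start_target, tr.end_target)
        try:
            seg = segment_movement(tr.trajectory, frac=frac)
            path = time_normalize(seg, n=refs.n_samples)
            row["dfd_straight"] = discrete_frechet(path, refs.straight(pair))
            row["dfd_energy"] = discrete_frechet(
                path, refs.energy(pair, objects.get(tr.group, "pendulum"))
            )
        except NoMovementError as exc:
            row["excluded"] = True
            row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_blocks(metrics: pd.DataFrame, confidence: float = 0.95):
    """Subject-by-block means and group-by-block means with confidence bands.

    Subjects — not trials — are the unit of analysis: group means average the
    subject means, and the half-widths are t-intervals over subjects.
    Returns ``(subject_means, group_means)`` DataFrames.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    ok = metrics[~metrics["excluded"]]
    subject = (
        ok.groupby(["group", "subject", "block"])[["dfd_straight", "dfd_energy"]]
        .mean()
        .reset_index()
    )
    subject["n_trials"] = (
        ok.groupby(["group", "subject", "block"]).size().reset_index(drop=True)
    )

    def _ci(x):
        k = x.count()
        if k < 2:
            return 0.0
        return float(stats.t.ppf(0.5 + confidence / 2.0, k - 1) * x.std(ddof=1) / np.sqrt(k))

    group = (
        subject.groupby(["group", "block"])
        .agg(
            dfd_straight=("dfd_straight", "mean"),
            dfd_straight_ci=("dfd_straight", _ci),
            dfd_energy=("dfd_energy", "mean"),
            dfd_energy_ci=("dfd_energy", _ci),
            n_subjects=("subject", "count"),
        )
        .reset_index()
    )
    return subject, group


@dataclass
class AnovaResult:
    """Omnibus one-way ANOVA: F = MS_between / MS_within with (k−1, N−k) df."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False

    def __post_init__(self):
        if np.isfinite(self.F) and self.F < 0:
            raise ValueError("F statistic must be nonnegative")


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over a sequence of per-group observations.

    With zero within-group variance and unequal means the statistic is
    degenerate: F is infinite and p is reported as 0 with the
    ``degenerate`` flag set.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    n = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = int(n.sum()) - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p_value=1.0,
                               degenerate=True)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p_value=0.0,
                           degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p_value=p)


@dataclass
class PosthocResult:
    """Many-to-one comparisons of each group against the control group.

    ``p_adjusted`` are family-wise (max-|t|) Monte-Carlo adjusted p-values,
    coherently clipped into the provable [unadjusted, Bonferroni] bracket.
    """

    comparisons: list
    t_stats: np.ndarray
    p_unadjusted: np.ndarray
    p_bonferroni: np.ndarray
    p_adjusted: np.ndarray
    df: int
    n_mc: int


def many_to_one_posthoc(
    groups,
    control: int = 0,
    n_mc: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> PosthocResult:
    """Dunnett-style simultaneous contrasts of every group against a control.

    The family-wise adjustment references the joint null distribution of the
    maximum |t| over all contrasts, evaluated by Monte Carlo (``n_mc``
    simulated experiments with the observed group sizes; at least 1000
    replicates are required, 100k recommended).  Two-sided.
    """
    if n_mc < 1000:
        raise ValueError("n_mc < 1000 gives unusable precision; use >= 1000")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    k = len(arrays)
    n = np.array([a.size for a in arrays])
    df = int(n.sum()) - k
    means = np.array([a.mean() for a in arrays])
    s2 = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df
    if s2 <= 0:
        raise ValueError("pooled within-group variance is zero; t statistics undefined")
    others = [i for i in range(k) if i != control]
    se = np.sqrt(s2 * (1.0 / n[others] + 1.0 / n[control]))
    t_obs = (means[others] - means[control]) / se
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)
    p_bonf = np.minimum(1.0, len(others) * p_unadj)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # simulate the joint null: iid normal samples with the observed sizes
    z = rng.standard_normal((n_mc, int(n.sum())))
    edges = np.concatenate([[0], np.cumsum(n)])
    gsum = np.add.reduceat(z, edges[:-1], axis=1)
    gmean = gsum / n
    ss_w = np.zeros(n_mc)
    for i in range(k):
        block = z[:, edges[i]: edges[i + 1]]
        ss_w += np.sum((block - gmean[:, i][:, None]) ** 2, axis=1)
    s2_sim = ss_w / df
    t_sim = (gmean[:, others] - gmean[:, [control]]) / np.sqrt(s2_sim[:, None] * (1.0 / n[others] + 1.0 / n[control]))
    max_abs_t = np.max(np.abs(t_sim), axis=1)
    p_adj_mc = np.array([(np.sum(max_abs_t >= abs(t)) + 1) / (n_mc + 1) for t in t_obs])
    p_adj = np.clip(p_adj_mc, p_unadj, p_bonf)
    return PosthocResult(
        comparisons=[(i, control) for i in others],
        t_stats=t_obs,
        p_unadjusted=p_unadj,
        p_bonferroni=p_bonf,
        p_adjusted=p_adj,
        df=df,
        n_mc=n_mc,
    )
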