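"""Run configuration: one JSON-serializable object covering every module.

The on-disk format is a plain JSON document with sections ``dynamics``
(mechanical constants, keys m1..c2, K, B, mass_point, base_x, base_y),
``optimal`` (trajectory-optimizer settings), ``synth`` (experiment sizes,
group specs and target layout) and ``analysis`` (statistics settings), plus
a global ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path as FsPath

from .dynamics import CouplingParams, PendulumParams, PointMassParams
from .paths import TargetLayout, default_layout
from .synth import ExperimentConfig, GroupSpec, default_group_specs

__all__ = ["OptimalSettings", "AnalysisSettings", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class OptimalSettings:
    """Settings of the effort-optimal and geodesic solvers."""

    n_knots: int = 40
    cost_form: str = "squared"  # "squared" | "abs"
    max_iter: int = 500
    tol: float = 1e-10
    n_starts: int = 8
    seed: int = 0


@dataclass(frozen=True)
class AnalysisSettings:
    """Settings of the trial-metrics and statistics stage."""

    n_mc: int = 100_000
    n_samples: int = 100
    frac: float = 0.10


@dataclass
class RunConfig:
    """Everything a full run needs; deterministic given ``seed``."""

    seed: int = 0
    out_dir: str | None = None
    cache_dir: str | None = None
    log_level: str = "INFO"
    simulate_forces: bool = True
    pendulum: PendulumParams = field(default_factory=PendulumParams)
    point_mass: PointMassParams = field(default_factory=PointMassParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    layout: TargetLayout = field(default_factory=default_layout)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    groups: tuple = field(default_factory=default_group_specs)
    optimal: OptimalSettings = field(default_factory=OptimalSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, experiment=replace(self.experiment, seed=seed))

    def to_dict(self) -> dict:
        p = self.pendulum
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "cache_dir": self.cache_dir,
            "log_level": self.log_level,
            "simulate_forces": self.simulate_forces,
            "dynamics": {
                "m1": p.m1, "m2": p.m2, "l1": p.l1, "l2": p.l2,
                "I1": p.I1, "I2": p.I2, "c1": p.c1, "c2": p.c2,
                "K": self.coupling.K, "B": self.coupling.B,
                "mass_point": self.point_mass.m,
                "base_x": p.base[0], "base_y": p.base[1],
            },
            "optimal": asdict(self.optimal),
            "synth": {
                **{k: getattr(self.experiment, k) for k in (
                    "subjects", "blocks", "reaches_per_block", "T", "rate",
                    "hold", "lead", "sim_dt", "seed")},
                "groups": [
                    {"label": g.label, "object": g.haptic_object, "w_inf": g.w_inf,
                     "learning_rate": g.learning_rate, "sigma": g.sigma,
                     "endpoint_sigma": g.endpoint_sigma}
                    for g in self.groups
                ],
                "layout": {"centers": [list(c) for c in self.layout.centers],
                           "diameter": self.layout.diameter},
            },
            "analysis": asdict(self.analysis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        dyn = d.get("dynamics", {})
        pend_kwargs = {k: dyn[k] for k in ("m1", "m2", "l1", "l2", "I1", "I2", "c1", "c2")
                       if k in dyn}
        if "base_x" in dyn or "base_y" in dyn:
            pend_kwargs["base"] = (dyn.get("base_x", 0.0), dyn.get("base_y", 0.0))
        pendulum = PendulumParams(**pend_kwargs)
        point_mass = PointMassParams(m=dyn.get("mass_point", 15.0))
        coupling = CouplingParams(K=dyn.get("K", 2200.0), B=dyn.get("B", 65.0))
        synth = d.get("synth", {})
        exp_kwargs = {k: synth[k] for k in (
            "subjects", "blocks", "reaches_per_block", "T", "rate", "hold",
            "lead", "sim_dt", "seed") if k in synth}
        experiment = ExperimentConfig(**exp_kwargs)
        if "groups" in synth:
            groups = tuple(
                GroupSpec(label=g["label"], haptic_object=g.get("object", "pendulum"),
                          w_inf=g.get("w_inf", 0.0),
                          learning_rate=g.get("learning_rate", 0.0),
                          sigma=g.get("sigma", 0.004),
                          endpoint_sigma=g.get("endpoint_sigma", 0.002))
                for g in synth["groups"]
            )
        else:
            groups = default_group_specs()
        if "layout" in synth:
            lay = TargetLayout(
                centers=tuple(tuple(c) for c in synth["layout"]["centers"]),
                diameter=synth["layout"].get("diameter", 0.03),
            )
        else:
            lay = default_layout(base=pendulum.base)
        optimal = OptimalSettings(**d.get("optimal", {}))
        analysis = AnalysisSettings(**d.get("analysis", {}))
        return cls(
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir"),
            cache_dir=d.get("cache_dir"),
            log_level=d.get("log_level", "INFO"),
            simulate_forces=d.get("simulate_forces", True),
            pendulum=pendulum, point_mass=point_mass, coupling=coupling,
            layout=lay, experiment=experiment, groups=groups,
            optimal=optimal, analysis=analysis,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def save_config(cfg: RunConfig, path) -> None:
    FsPath(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
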