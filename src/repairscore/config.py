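"""Run configuration: stage toggles, parameters, and per-stage seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "ConfigError", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "score", "associate", "crossval", "roc", "risk_update", "expression")

#: stages whose outputs feed a later stage
_STAGE_DEPS = {
    "score": ("simulate",),
    "associate": ("score",),
    "crossval": ("score",),
    "roc": ("score",),
    "risk_update": ("score",),
    "expression": ("score", "simulate"),
}

_STOCHASTIC_STAGES = ("simulate", "roc", "expression")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Every stochastic stage (simulation, bootstrap ROC inference,
    permutation enrichment) must carry an explicit seed; the whole config
    is echoed into the run report for provenance.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    seeds: dict = field(default_factory=lambda: {"simulate": 1, "roc": 2, "expression": 3})
    cohort: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    bootstrap_B: int = 2000
    n_perm: int = 1000
    min_set_size: int = 15
    max_set_size: int = 500
    target_specificities: tuple[float, ...] = (0.90, 0.95)
    risk_priors: tuple[float, ...] = (0.016, 0.045)
    risk_regions: tuple[str, ...] = ("le:5", "ge:75")
    outdir: str = "repairscore_run"

    def validate(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in _STAGE_DEPS.get(stage, ()):
                if dep not in self.stages:
                    raise ConfigError(f"stage '{stage}' requires stage '{dep}'")
        for stage in self.stages:
            if stage in _STOCHASTIC_STAGES and stage not in self.seeds:
                raise ConfigError(f"stochastic stage '{stage}' has no seed")
        if self.bootstrap_B < 200:
            raise ConfigError("bootstrap_B must be >= 200")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
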