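"""YAML pipeline configuration.

One file materialises every stage's defaults; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_CHOICE_COEF, DEFAULT_LEAVE_COEF, AgentPolicy
from .learner import LearnerConfig
from .task import PATTERN_LABELS, EnvironmentConfig, PatternConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


_DEFAULT_PATTERNS = {
    "high_noise_low_vol": {"noise_sd": 0.12, "hazard": 0.04},
    "low_noise_high_vol": {"noise_sd": 0.04, "hazard": 0.25},
    "intermediate": {"noise_sd": 0.08, "hazard": 0.12},
}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Materialised configuration for all pipeline stages."""

    environment: dict = field(default_factory=dict)
    learner: dict = field(default_factory=dict)
    coding: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "lpexplore_out"

    def environment_config(self) -> EnvironmentConfig:
        env = dict(self.environment)
        _check_keys(env, {"patterns", "character_assignment", "seed"}, "environment")
        patterns_raw = env.get("patterns", _DEFAULT_PATTERNS)
        patterns = {}
        for label, p in patterns_raw.items():
            if label not in PATTERN_LABELS:
                raise ValueError(f"unknown pattern label {label!r}; expected one of {PATTERN_LABELS}")
            _check_keys(p, {"noise_sd", "hazard", "mean_init"}, f"environment.patterns.{label}")
            patterns[label] = PatternConfig(
                noise_sd=float(p["noise_sd"]), hazard=float(p["hazard"]),
                mean_init=p.get("mean_init", "random"), label=label,
            )
        assignment = {int(k): v for k, v in env.get(
            "character_assignment",
            {1: "high_noise_low_vol", 2: "low_noise_high_vol", 3: "intermediate"},
        ).items()}
        return EnvironmentConfig(patterns=patterns, character_assignment=assignment,
                                 seed=int(env.get("seed", self.seed)))

    def learner_config(self) -> LearnerConfig:
        allowed = {f.name for f in dataclasses.fields(LearnerConfig)}
        _check_keys(self.learner, allowed, "learner")
        return LearnerConfig(**self.learner)

    def coding_options(self) -> dict:
        _check_keys(self.coding, {"min_trials_per_character"}, "coding")
        return {"min_trials_per_character": int(self.coding.get("min_trials_per_character", 10))}

    def model_options(self) -> dict:
        _check_keys(self.models, {"include_performance_main", "min_choice_events",
                                  "choice_order_seed"}, "models")
        return {
            "include_performance_main": bool(self.models.get("include_performance_main", True)),
            "min_choice_events": int(self.models.get("min_choice_events", 20)),
            "choice_order_seed": int(self.models.get("choice_order_seed", self.seed)),
        }

    def agent_policy(self) -> AgentPolicy:
        sim = dict(self.simulation)
        allowed = {
            "n_children", "motor_sd", "heterogeneity_sd", "leave_intercept_sd", "impair_learner",
            "session_rule", "fixed_n_trials", "quit_prob", "quit_after", "hard_stop_per_character",
            "leave_coef", "choice_coef", "choice_mode",
        }
        _check_keys(sim, allowed, "simulation")
        leave = dict(DEFAULT_LEAVE_COEF)
        leave.update(sim.get("leave_coef", {}))
        choice = dict(DEFAULT_CHOICE_COEF)
        choice.update(sim.get("choice_coef", {}))
        kwargs = {k: sim[k] for k in
                  ("motor_sd", "heterogeneity_sd", "leave_intercept_sd", "impair_learner",
                   "session_rule", "fixed_n_trials", "quit_prob", "quit_after",
                   "hard_stop_per_character", "choice_mode")
                  if k in sim}
        return AgentPolicy(learner=dataclasses.replace(self.learner_config(), anchor="belief"),
                           leave_coef=leave, choice_coef=choice, **kwargs)

    @property
    def n_children(self) -> int:
        return int(self.simulation.get("n_children", 87))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; None gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    _check_keys(raw, allowed, "top level")
    cfg = PipelineConfig(**raw)
    # validate every section eagerly so errors surface at load time
    cfg.environment_config()
    cfg.learner_config()
    cfg.coding_options()
    cfg.model_options()
    cfg.agent_policy()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the materialised configuration (for run manifests)."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
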