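"""Generative model of the volatile hide-and-seek environment.

Three characters hide along a one-dimensional hedge (screen width normalised
to [0, 1]; 0 is the far-left corner).  Each character hides at locations drawn
from a Gaussian whose mean occasionally jumps to a new position: the standard
deviation of the Gaussian is the character's *noise* level (irreducible
uncertainty) and the per-trial probability of a mean jump is its *hazard*
(volatility, reducible uncertainty).  The default environment orders the three
characters as high-noise/low-volatility, low-noise/high-volatility and
intermediate on both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatternConfig",
    "PatternState",
    "EnvironmentConfig",
    "default_environment",
    "step_pattern",
    "sample_location",
    "generate_outcome_sequence",
]

#: margin kept between a freshly drawn hiding mean and the screen edges so the
#: bulk of the Gaussian stays on-screen (heavy truncation would distort the
#: nominal noise level)
EDGE_MARGIN = 0.1

PATTERN_LABELS = ("high_noise_low_vol", "low_noise_high_vol", "intermediate")


@dataclass(frozen=True)
class PatternConfig:
    """Noise/volatility parameters of one character's hiding pattern."""

    noise_sd: float
    hazard: float
    mean_init: float | str = "random"
    label: str = "intermediate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.mean_init != "random" and not 0.0 <= float(self.mean_init) <= 1.0:
            raise ValueError(f"mean_init must be in [0, 1] or 'random', got {self.mean_init}")


@dataclass
class PatternState:
    """Latent state of one hiding pattern."""

    current_mean: float
    trials_since_change: int = 0


@dataclass(frozen=True)
class EnvironmentConfig:
    """Full task environment: one pattern per character.

    ``character_assignment`` maps character ids (1, 2, 3 by default) to the
    three pattern labels; which on-screen character carries which pattern was
    counterbalanced in the study, so the mapping is configurable.
    """

    patterns: dict[str, PatternConfig] = field(default_factory=dict)
    character_assignment: dict[int, str] = field(
        default_factory=lambda: {1: "high_noise_low_vol", 2: "low_noise_high_vol", 3: "intermediate"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.patterns) != set(PATTERN_LABELS):
            raise ValueError(f"patterns must contain exactly the labels {PATTERN_LABELS}")
        if sorted(self.character_assignment.values()) != sorted(PATTERN_LABELS):
            raise ValueError("character_assignment must use each pattern label exactly once")

    def pattern_for(self, character_id: int) -> PatternConfig:
        try:
            return self.patterns[self.character_assignment[character_id]]
        except KeyError as exc:
            raise KeyError(f"unknown character id {character_id!r}") from exc

    @property
    def characters(self) -> tuple[int, ...]:
        return tuple(sorted(self.character_assignment))


def default_environment(seed: int = 0) -> EnvironmentConfig:
    """Default three-character environment.

    Noise SDs (0.12, 0.04, 0.08 screen widths) and hazards (0.04, 0.25, 0.12)
    order the characters as described above while keeping each pattern
    learnable within a ~35-trial session.
    """
    return EnvironmentConfig(
        patterns={
            "high_noise_low_vol": PatternConfig(0.12, 0.04, label="high_noise_low_vol"),
            "low_noise_high_vol": PatternConfig(0.04, 0.25, label="low_noise_high_vol"),
            "intermediate": PatternConfig(0.08, 0.12, label="intermediate"),
        },
        seed=seed,
    )


def _draw_mean(rng: np.random.Generator) -> float:
    return float(rng.uniform(EDGE_MARGIN, 1.0 - EDGE_MARGIN))


def init_pattern_state(config: PatternConfig, rng: np.random.Generator) -> PatternState:
    mean = _draw_mean(rng) if config.mean_init == "random" else float(config.mean_init)
    return PatternState(current_mean=mean, trials_since_change=0)


def step_pattern(
    state: PatternState, config: PatternConfig, rng: np.random.Generator
) -> tuple[PatternState, bool]:
    """Advance the latent mean one trial; returns (new state, changed flag)."""
    if rng.random() < config.hazard:
        return PatternState(current_mean=_draw_mean(rng), trials_since_change=0), True
    return replace(state, trials_since_change=state.trials_since_change + 1), False


def sample_location(
    state: PatternState, config: PatternConfig, rng: np.random.Generator
) -> float:
    """Draw a hiding location ~ N(mean, noise_sd^2) truncated to [0, 1].

    Truncation is by rejection, not clipping: clipping would put point masses
    at the screen edges and bias prediction errors.
    """
    if config.noise_sd == 0.0:
        return state.current_mean
    while True:
        x = rng.normal(state.current_mean, config.noise_sd)
        if 0.0 <= x <= 1.0:
            return float(x)


def generate_outcome_sequence(
    config: EnvironmentConfig,
    character: int,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    mean_schedule: list[float] | None = None,
) -> list[tuple[float, float, bool]]:
    """Simulate ``n_trials`` hiding events for one character.

    Returns a list of (latent_mean, location, changed) tuples.  The first
    trial never counts as a changepoint.  ``mean_schedule`` overrides the
    hazard process with an explicit sequence of latent means (for hand-crafted
    schedules).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    pattern = config.pattern_for(character)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    out: list[tuple[float, float, bool]] = []
    if mean_schedule is not None:
        if len(mean_schedule) != n_trials:
            raise ValueError("mean_schedule length must equal n_trials")
        state = PatternState(current_mean=float(mean_schedule[0]))
        for t, mu in enumerate(mean_schedule):
            changed = t > 0 and mu != state.current_mean
            state = PatternState(current_mean=float(mu), trials_since_change=0 if changed else state.trials_since_change + 1)
            out.append((state.current_mean, sample_location(state, pattern, rng), changed))
        return out

    state = init_pattern_state(pattern, rng)
    for t in range(n_trials):
        if t > 0:
            state, changed = step_pattern(state, pattern, rng)
        else:
            changed = False
        out.append((state.current_mean, sample_location(state, pattern, rng), changed))
    return out
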