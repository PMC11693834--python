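"""Reduced-Bayesian changepoint observer.

Turns a sequence of (predicted, actual) hiding locations into the trial-wise
quantities the downstream decision analyses need: signed and unsigned
prediction error (PE), learning progress (LP = trial-to-trial decrease in PE),
changepoint probability Omega, adaptive learning rate alpha, relative
uncertainty tau, and the PE/LP the observer *expects* on the next trial, plus
a novelty (negative familiarity) score per character.

The observer approximates full Bayesian changepoint inference (which tracks a
posterior over run lengths) with a single belief B about the current hiding
mean and a single relative uncertainty

    tau = Var(mean belief) / (Var(mean belief) + noise variance) in [0, 1].

On each outcome it computes the posterior probability Omega that the latest
outcome came from a freshly re-drawn mean (a two-hypothesis Bayes rule with a
uniform outcome density under "changepoint"), sets the learning rate

    alpha = Omega + (1 - Omega) * tau,

updates the belief by a delta rule B' = B + alpha * delta, and propagates tau
through the Omega-weighted mixture of the "changepoint" branch (uncertainty
resets high) and the "no changepoint" branch (conjugate Gaussian shrinkage).

By default the filter is conditioned on the participant's own predictions:
the belief carried into each update is the participant's current prediction,
so the delta-rule output is the model's forecast of the participant's next
prediction.  Autonomous agents instead run the filter on their own belief
(``anchor="belief"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LearnerConfig",
    "CharacterBelief",
    "LearnerState",
    "ChangepointLearner",
    "prediction_error",
    "learning_progress",
    "changepoint_probability",
    "learning_rate",
    "update_belief",
    "update_uncertainty",
    "expected_absolute_error",
    "novelty",
    "process_session",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_TAU_CAP = 0.975  # keeps the implied belief variance finite


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the observer.

    hazard_belief
        Subjective per-trial changepoint probability, one value for all
        characters (observers are not told the true volatility levels).
    noise_sd
        Assumed outcome noise SD in screen widths; fixed rather than estimated
        online to keep the filter identifiable on ~35-trial sessions.
    tau_reset
        Relative uncertainty after a certain changepoint (Omega = 1).  0.5
        corresponds to belief variance equal to the noise variance, i.e. the
        state of having seen a single outcome from the new regime.
    tau_init
        Relative uncertainty before the first outcome with a character.
    ema_decay
        Decay of the exponential moving average of PE used as the "current
        error level" in expected LP; 0.5 gives a two-to-three-trial memory.
    domain_width
        Width of the outcome space (1.0 for the normalised hedge).
    anchor
        "prediction": belief is re-anchored to the participant's prediction
        each trial (model conditioned on behaviour).  "belief": the filter's
        own belief persists (autonomous agent mode).
    """

    hazard_belief: float = 0.1
    noise_sd: float = 0.08
    tau_reset: float = 0.5
    tau_init: float = 0.5
    ema_decay: float = 0.5
    domain_width: float = 1.0
    anchor: str = "prediction"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard_belief <= 1.0:
            raise ValueError("hazard_belief must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.anchor not in ("prediction", "belief"):
            raise ValueError("anchor must be 'prediction' or 'belief'")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def prediction_error(predicted: float, actual: float) -> tuple[float, float]:
    """Signed error delta = actual - predicted and its magnitude PE = |delta|."""
    for name, v in (("predicted", predicted), ("actual", actual)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} location {v} outside [0, 1]")
    delta = actual - predicted
    return delta, abs(delta)


def learning_progress(prev_pe: float | None, pe: float) -> float | None:
    """LP = previous PE - current PE; positive when performance improves.

    Returns None when there is no previous PE (first trial with a character).
    """
    if prev_pe is None or (isinstance(prev_pe, float) and math.isnan(prev_pe)):
        return None
    return prev_pe - pe


def changepoint_probability(
    delta: float,
    predictive_sd: float,
    hazard_belief: float,
    domain_width: float = 1.0,
) -> float:
    """Posterior probability that the outcome came from a re-drawn mean.

    Two-hypothesis Bayes rule: under "changepoint" the outcome is uniform on
    the domain (density 1/width); under "no changepoint" it is Gaussian around
    the current belief with SD ``predictive_sd``.
    """
    if predictive_sd <= 0:
        raise ValueError("predictive_sd must be > 0")
    h = hazard_belief
    if h == 0.0:
        return 0.0
    if h == 1.0:
        return 1.0
    u = 1.0 / domain_width
    gauss = math.exp(-0.5 * (delta / predictive_sd) ** 2) / (
        predictive_sd * math.sqrt(2.0 * math.pi)
    )
    return h * u / (h * u + (1.0 - h) * gauss)


def learning_rate(omega: float, tau: float) -> float:
    """alpha = Omega + (1 - Omega) * tau, in [0, 1]."""
    return omega + (1.0 - omega) * tau


def update_belief(belief: float, delta: float, alpha: float) -> float:
    """Delta-rule update B' = B + alpha * delta, projected into [0, 1]."""
    return min(1.0, max(0.0, belief + alpha * delta))


def update_uncertainty(
    tau: float,
    omega: float,
    delta: float,
    noise_sd: float,
    tau_reset: float = 0.5,
) -> float:
    """Propagate relative uncertainty through the changepoint mixture.

    With belief variance v = tau/(1-tau) * sigma_n^2, the no-changepoint branch
    shrinks it conjugately to v * sigma_n^2 / (v + sigma_n^2) = tau * sigma_n^2;
    the changepoint branch resets it to the variance implied by ``tau_reset``;
    and the spread between the two branch means (which differ by
    delta * (1 - tau)) adds Omega(1-Omega) * delta^2 * (1-tau)^2.
    """
    tau = min(tau, _TAU_CAP)
    var_n = noise_sd * noise_sd
    v_nc = tau * var_n
    v_cp = tau_reset / (1.0 - tau_reset) * var_n
    spread = omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
    v_new = omega * v_cp + (1.0 - omega) * v_nc + spread
    return min(v_new / (v_new + var_n), _TAU_CAP)


def expected_absolute_error(tau: float, noise_sd: float) -> float:
    """E|X - B| under the predictive Normal(B, sigma_tot^2).

    sigma_tot^2 = belief variance + noise variance; the mean absolute
    deviation of a centred Gaussian is sqrt(2/pi) * sigma_tot.
    """
    tau = min(tau, _TAU_CAP)
    var_n = noise_sd * noise_sd
    sigma_tot = math.sqrt(tau / (1.0 - tau) * var_n + var_n)
    return _SQRT_2_OVER_PI * sigma_tot


def novelty(pick_counts) -> np.ndarray:
    """Novelty as standardised negative familiarity.

    z-scores of (-pick_count) across the supplied sample (population SD);
    strictly decreasing in pick count.  Equal counts give all-zero scores.
    """
    neg = -np.asarray(pick_counts, dtype=float)
    sd = neg.std()
    if sd == 0.0:
        return np.zeros_like(neg)
    return (neg - neg.mean()) / sd


# ---------------------------------------------------------------------------
# stateful filter
# ---------------------------------------------------------------------------

@dataclass
class CharacterBelief:
    """Belief state the observer maintains for one character."""

    belief: float = 0.5
    tau: float = 0.5
    last_pe: float | None = None
    last_lp: float | None = None
    smoothed_pe: float | None = None
    pick_count: int = 0
    within_character_trial: int = 0

    @property
    def visited(self) -> bool:
        return self.within_character_trial > 0


@dataclass
class LearnerState:
    """Per-character beliefs for a whole session."""

    characters: dict[int, CharacterBelief] = field(default_factory=dict)

    def for_character(self, character_id: int) -> CharacterBelief:
        return self.characters.setdefault(character_id, CharacterBelief())


class ChangepointLearner:
    """Runs the reduced-Bayesian observer over a session, one trial at a time.

    State persists across leave/return visits to a character: switching away
    does not erase what was learned about it.
    """

    def __init__(self, config: LearnerConfig | None = None):
        self.config = config or LearnerConfig()
        self.state = LearnerState()

    def observe(self, character_id: int, predicted: float, actual: float) -> dict:
        """Update on one trial; returns the trial's derived estimates.

        ``expected_pe``/``expected_lp`` are the post-update forecasts for the
        *next* trial with this character.
        """
        cfg = self.config
        cb = self.state.for_character(character_id)

        delta, pe = prediction_error(predicted, actual)
        if not cb.visited:
            cb.belief = predicted
            cb.tau = cfg.tau_init
        pre_belief = predicted if cfg.anchor == "prediction" else cb.belief

        tau = min(cb.tau, _TAU_CAP)
        var_n = cfg.noise_sd**2
        predictive_sd = math.sqrt(tau / (1.0 - tau) * var_n + var_n)
        omega = changepoint_probability(delta, predictive_sd, cfg.hazard_belief, cfg.domain_width)
        alpha = learning_rate(omega, tau)

        lp = learning_progress(cb.last_pe, pe)
        new_belief = update_belief(pre_belief, delta, alpha)
        new_tau = update_uncertainty(tau, omega, delta, cfg.noise_sd, cfg.tau_reset)

        smoothed = pe if cb.smoothed_pe is None else (
            cfg.ema_decay * pe + (1.0 - cfg.ema_decay) * cb.smoothed_pe
        )
        exp_pe = expected_absolute_error(new_tau, cfg.noise_sd)
        exp_lp = smoothed - exp_pe

        cb.belief = new_belief
        cb.tau = new_tau
        cb.last_pe = pe
        cb.last_lp = lp
        cb.smoothed_pe = smoothed
        cb.pick_count += 1
        cb.within_character_trial += 1

        return {
            "delta": delta,
            "pe": pe,
            "lp": lp,
            "omega": omega,
            "alpha": alpha,
            "tau": new_tau,
            "belief": new_belief,
            "expected_pe": exp_pe,
            "expected_lp": exp_lp,
            "pick_count": cb.pick_count,
            "within_character_trial": cb.within_character_trial,
        }

    def predict(self, character_id: int) -> float:
        """Current point prediction for a character (belief, or 0.5 if unseen)."""
        cb = self.state.for_character(character_id)
        return cb.belief if cb.visited else 0.5

    def expectations(self, character_id: int) -> dict:
        """Forecast quantities used by choice policies, for one character.

        For an unvisited character the prior expectations apply (tau_init
        uncertainty, zero anticipated improvement).
        """
        cb = self.state.for_character(character_id)
        tau = cb.tau if cb.visited else self.config.tau_init
        exp_pe = expected_absolute_error(tau, self.config.noise_sd)
        smoothed = cb.smoothed_pe if cb.smoothed_pe is not None else exp_pe
        return {
            "expected_pe": exp_pe,
            "expected_lp": smoothed - exp_pe,
            "pick_count": cb.pick_count,
            "last_pe": cb.last_pe,
            "last_lp": cb.last_lp,
            "visited": cb.visited,
        }


# ---------------------------------------------------------------------------
# session-level driver
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("participant_id", "trial", "character_id", "predicted_loc", "actual_loc")

ESTIMATE_COLUMNS = (
    "delta", "pe", "lp", "omega", "alpha", "tau", "belief",
    "expected_pe", "expected_lp", "pick_count", "within_character_trial",
)


def process_session(trials: pd.DataFrame, config: LearnerConfig | None = None) -> pd.DataFrame:
    """Run the observer over one participant's session.

    ``trials`` must have columns participant_id, trial, character_id,
    predicted_loc, actual_loc with strictly increasing trial indices.  Returns
    the input joined with one row of estimates per trial (LP is NaN on each
    character's first trial).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    t = trials["trial"].to_numpy()
    if len(t) == 0:
        raise ValueError("empty session")
    if trials["participant_id"].nunique() > 1:
        raise ValueError("process_session expects a single participant")
    if not (np.diff(t) > 0).all():
        raise ValueError("trial indices must be strictly increasing (sorted, no duplicates)")

    learner = ChangepointLearner(config)
    rows = []
    for rec in trials.itertuples(index=False):
        est = learner.observe(int(rec.character_id), float(rec.predicted_loc), float(rec.actual_loc))
        rows.append(est)
    est_df = pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))
    est_df["lp"] = est_df["lp"].astype(float)  # None -> NaN
    out = trials.reset_index(drop=True).copy()
    for c in ESTIMATE_COLUMNS:
        out[c] = est_df[c].to_numpy()
    return out


def process_dataset(trials: pd.DataFrame, config: LearnerConfig | None = None) -> pd.DataFrame:
    """process_session applied per participant, preserving row order within each."""
    parts = [
        process_session(g, config)
        for _, g in trials.groupby("participant_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)
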