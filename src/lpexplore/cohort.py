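"""Simulated child cohorts with known ground truth.

Each simulated child runs the same reduced-Bayesian observer the analysis
uses (in autonomous mode: predictions are its own belief plus motor noise),
with a per-child *impairment multiplier* m that scales both its motor noise
and its subjective hazard rate — producing the continuum of learning
performance the analysis estimates as PE-over-trials slopes.  Stay-leave
decisions follow a logistic policy on the same covariates the analysis
computes (PE, LP, novelty, time, and performance interactions); after a
leave, the next character is chosen by a softmax on differential option
values (novelty, expected LP, expected PE).  Session length follows the study
rules (a per-trial quit probability after an initial engagement period, plus
a hard stop once any character has been played 35 times) or a fixed length
for controlled experiments.

Policy coefficients apply to covariates scaled by fixed reference
means/SDs (module constants calibrated to self-consistency on pilot runs of
the default policy and environment), so generating coefficients live on the
same per-SD scale as the fitted ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import choice_events_dataset, code_dataset
from .learner import ChangepointLearner, LearnerConfig
from .models import (
    ChoiceModel,
    LeaveStayModel,
    build_choice_table,
    compare_models,
    fit_performance_slopes,
)
from .task import EnvironmentConfig, default_environment, init_pattern_state, sample_location, step_pattern

__all__ = [
    "AgentPolicy",
    "GroundTruth",
    "simulate_child",
    "simulate_cohort",
    "recovery_experiment",
    "type1_calibration_experiment",
    "model_selection_experiment",
]


#: reference scales (mean, SD) used to standardise policy covariates inside
#: the generator; calibrated to self-consistency on 400-agent pilots under
#: the default policy and environment, then frozen (see docs/methods.md)
REFERENCE_SCALES: dict[str, tuple[float, float]] = {
    "pe": (0.131, 0.127),
    "lp": (0.006, 0.173),
    "novelty": (-9.75, 6.47),     # negative pick count of the current character
    "time": (21.1, 10.7),
    "d_novelty": (0.0, 5.69),
    "d_expected_lp": (0.0, 0.111),
    "d_expected_pe": (0.0, 0.0144),
    "d_lp": (0.0, 0.235),
    "d_pe": (0.0, 0.173),
}

#: study-condition decision coefficients (per-SD scale).  The stay-leave
#: main effects of novelty/LP are back-derived from the marginal-effect
#: pattern implied by the interaction structure; the choice coefficients are
#: the fitted magnitudes for novelty, expected LP and expected PE.
DEFAULT_LEAVE_COEF: dict[str, float] = {
    "intercept": -1.386,          # baseline leave probability ~0.20
    "pe": -0.01,
    "lp": 0.0,
    "novelty": 0.25,
    "time": -0.12,
    "performance": 0.0,
    "performance:pe": 0.0,
    "performance:lp": 0.49,
    "performance:novelty": 0.73,
}

DEFAULT_CHOICE_COEF: dict[str, float] = {
    "intercept": 0.0,
    "d_novelty": 0.30,
    "d_expected_lp": 0.35,
    "d_expected_pe": -0.21,
}


@dataclass(frozen=True)
class AgentPolicy:
    """Generating parameters of a simulated child."""

    learner: LearnerConfig = field(
        default_factory=lambda: LearnerConfig(anchor="belief")
    )
    motor_sd: float = 0.06
    leave_coef: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEAVE_COEF))
    choice_coef: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHOICE_COEF))
    choice_mode: str = "expectation"      # "expectation" | "history" | "random"
    heterogeneity_sd: float = 0.5         # SD of log impairment multiplier
    impair_learner: bool = True           # multiplier also mis-specifies hazard_belief
    leave_intercept_sd: float = 0.5       # per-child spread of the leave baseline (logit scale)
    session_rule: str = "study"           # "study" | "fixed"
    fixed_n_trials: int = 40
    quit_prob: float = 0.056              # per-trial after quit_after trials
    quit_after: int = 10
    hard_stop_per_character: int = 35
    max_trials: int = 120
    reference_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_SCALES)
    )

    def null(self) -> "AgentPolicy":
        """Same policy with every decision coefficient (except intercepts) zeroed."""
        lc = {k: (v if k == "intercept" else 0.0) for k, v in self.leave_coef.items()}
        cc = {k: 0.0 for k in self.choice_coef}
        return dataclasses.replace(self, leave_coef=lc, choice_coef=cc)

    def _scale(self, key: str, value: float) -> float:
        mean, sd = self.reference_scales[key]
        return (value - mean) / sd


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the fitted coefficients."""

    leave_coef: dict[str, float]
    choice_coef: dict[str, float]
    agents: pd.DataFrame              # participant_id, multiplier, perf_latent_z
    seed: int
    policy: AgentPolicy = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps({
            "leave_coef": self.leave_coef,
            "choice_coef": self.choice_coef,
            "seed": self.seed,
            "agents": self.agents.to_dict(orient="records"),
        }, indent=2)

    def performance_lookup(self) -> pd.Series:
        return self.agents.set_index("participant_id")["perf_latent_z"]


def _truncnorm(rng: np.random.Generator, loc: float, sd: float) -> float:
    if sd == 0.0:
        return min(1.0, max(0.0, loc))
    while True:
        x = rng.normal(loc, sd)
        if 0.0 <= x <= 1.0:
            return float(x)


def simulate_child(
    policy: AgentPolicy,
    env: EnvironmentConfig,
    seed,
    participant_id: str = "sim_001",
    multiplier: float | None = None,
    perf_latent_z: float = 0.0,
    leave_intercept_dev: float | None = None,
) -> pd.DataFrame:
    """Simulate one session; returns TrialRecord rows.

    ``multiplier`` m >= 0 scales motor noise and the subjective hazard rate
    (m > 1: noisier, over-volatile beliefs — worse learning).  When None it
    is drawn from LogNormal(0, heterogeneity_sd) and ``perf_latent_z`` is the
    corresponding standardised latent performance, log(m)/heterogeneity_sd.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if multiplier is None:
        if policy.heterogeneity_sd > 0:
            log_m = rng.normal(0.0, policy.heterogeneity_sd)
            multiplier = math.exp(log_m)
            perf_latent_z = log_m / policy.heterogeneity_sd
        else:
            multiplier = 1.0
            perf_latent_z = 0.0
    if leave_intercept_dev is None:
        leave_intercept_dev = (
            float(rng.normal(0.0, policy.leave_intercept_sd))
            if policy.leave_intercept_sd > 0 else 0.0
        )

    base = policy.learner
    agent_cfg = dataclasses.replace(
        base,
        hazard_belief=(
            min(0.9, max(5e-3, base.hazard_belief * multiplier))
            if policy.impair_learner else base.hazard_belief
        ),
        anchor="belief",
    )
    learner = ChangepointLearner(agent_cfg)
    motor_sd = policy.motor_sd * multiplier

    characters = list(env.characters)
    patterns = {c: init_pattern_state(env.pattern_for(c), rng) for c in characters}
    current = characters[rng.integers(len(characters))]
    counts = {c: 0 for c in characters}

    gl = policy.leave_coef
    gc = policy.choice_coef
    sc = policy._scale

    rows = []
    t = 0
    while t < policy.max_trials:
        t += 1
        pat_cfg = env.pattern_for(current)
        if counts[current] > 0:
            patterns[current], _ = step_pattern(patterns[current], pat_cfg, rng)
        actual = sample_location(patterns[current], pat_cfg, rng)
        predicted = _truncnorm(rng, learner.predict(current), motor_sd)
        est = learner.observe(current, predicted, actual)
        counts[current] += 1
        rows.append({
            "participant_id": participant_id,
            "trial": t,
            "character_id": current,
            "predicted_loc": round(predicted, 6),
            "actual_loc": round(actual, 6),
        })

        # session termination
        if policy.session_rule == "fixed":
            if t >= policy.fixed_n_trials:
                break
        else:
            if counts[current] >= policy.hard_stop_per_character:
                break
            if t >= policy.quit_after and rng.random() < policy.quit_prob:
                break

        # leave-stay decision (covariates available at the decision point)
        x_pe = sc("pe", est["pe"])
        x_lp = sc("lp", est["lp"] if est["lp"] is not None else 0.0)
        x_nov = sc("novelty", -counts[current])
        x_time = sc("time", t)
        lin = (
            gl["intercept"] + leave_intercept_dev
            + gl["pe"] * x_pe + gl["lp"] * x_lp + gl["novelty"] * x_nov
            + gl["time"] * x_time + gl["performance"] * perf_latent_z
            + perf_latent_z * (
                gl["performance:pe"] * x_pe
                + gl["performance:lp"] * x_lp
                + gl["performance:novelty"] * x_nov
            )
        )
        p_leave = 1.0 / (1.0 + math.exp(-lin))
        if rng.random() < p_leave:
            a, b = [c for c in characters if c != current]
            if policy.choice_mode == "random":
                current = a if rng.random() < 0.5 else b
            else:
                ea, eb = learner.expectations(a), learner.expectations(b)
                d_nov = (-(ea["pick_count"] - eb["pick_count"])) / policy.reference_scales["d_novelty"][1]
                if policy.choice_mode == "history":
                    d1 = ((ea["last_lp"] or 0.0) - (eb["last_lp"] or 0.0)) / policy.reference_scales["d_lp"][1]
                    d2 = ((ea["last_pe"] or 0.0) - (eb["last_pe"] or 0.0)) / policy.reference_scales["d_pe"][1]
                    lin_c = gc["intercept"] + gc["d_novelty"] * d_nov + gc.get("d_lp", 0.0) * d1 + gc.get("d_pe", 0.0) * d2
                else:
                    d_elp = (ea["expected_lp"] - eb["expected_lp"]) / policy.reference_scales["d_expected_lp"][1]
                    d_epe = (ea["expected_pe"] - eb["expected_pe"]) / policy.reference_scales["d_expected_pe"][1]
                    lin_c = (
                        gc["intercept"] + gc["d_novelty"] * d_nov
                        + gc["d_expected_lp"] * d_elp + gc["d_expected_pe"] * d_epe
                    )
                p_a = 1.0 / (1.0 + math.exp(-lin_c))
                current = a if rng.random() < p_a else b
    return pd.DataFrame(rows)


def simulate_cohort(
    n_children: int,
    policy: AgentPolicy | None = None,
    env: EnvironmentConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort; returns (trial log, ground truth).

    Deterministic given ``seed``.  Default cohort size elsewhere in the
    package is 87 children, the study's analysed sample size.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    policy = policy or AgentPolicy()
    env = env or default_environment()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_children)

    logs, agents = [], []
    for i, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        pid = f"sim_{i + 1:03d}"
        if policy.heterogeneity_sd > 0:
            log_m = rng.normal(0.0, policy.heterogeneity_sd)
            m = math.exp(log_m)
            pz = log_m / policy.heterogeneity_sd
        else:
            m, pz = 1.0, 0.0
        dev = (float(rng.normal(0.0, policy.leave_intercept_sd))
               if policy.leave_intercept_sd > 0 else 0.0)
        logs.append(simulate_child(policy, env, rng, pid, multiplier=m,
                                   perf_latent_z=pz, leave_intercept_dev=dev))
        agents.append({"participant_id": pid, "multiplier": m,
                       "perf_latent_z": pz, "leave_intercept_dev": dev})

    trials = pd.concat(logs, ignore_index=True)
    truth = GroundTruth(
        leave_coef=dict(policy.leave_coef),
        choice_coef=dict(policy.choice_coef),
        agents=pd.DataFrame(agents),
        seed=seed,
        policy=policy,
    )
    return trials, truth


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _analyse_cohort(trials, truth, analysis_config=None, use_true_performance=True,
                    choice_seed=0, min_events=10):
    """Shared estimate->code->fit pathway for the experiments below."""
    from .learner import process_dataset
    est = process_dataset(trials, analysis_config)
    est = code_dataset(est)
    events = choice_events_dataset(est)
    if use_true_performance:
        perf = truth.performance_lookup()
    else:
        perf = fit_performance_slopes(est).performance_lookup()
    ls = LeaveStayModel.from_estimates(est, perf).fit()
    table = build_choice_table(est, events, perf, seed=choice_seed)
    cm = ChoiceModel.from_choice_table(table, "expectation", min_events=min_events).fit()
    return est, events, table, perf, ls, cm


def type1_calibration_experiment(
    n_replicates: int = 500,
    n_children: int = 20,
    n_trials: int = 30,
    seed: int = 0,
    policy: AgentPolicy | None = None,
) -> dict:
    """False-positive calibration under a null decision policy.

    Simulates cohorts whose leave-stay and choice behaviour is independent of
    all covariates (coefficients zero), refits both models, and reports the
    rejection rate of non-intercept fixed effects at alpha = .05.
    """
    base = policy or AgentPolicy(session_rule="fixed", fixed_n_trials=n_trials)
    null_policy = base.null()
    rej_leave, rej_choice, failures = [], [], 0
    for r in range(n_replicates):
        trials, truth = simulate_cohort(n_children, null_policy, seed=seed + 7919 * r)
        try:
            _, _, _, _, ls, cm = _analyse_cohort(trials, truth, choice_seed=seed + r)
        except Exception:
            failures += 1
            continue
        for res, sink in ((ls, rej_leave), (cm, rej_choice)):
            pv = res.pvalues[1:]  # intercept is non-null by design
            sink.extend((pv < 0.05).tolist())
    return {
        "leave_stay_rejection_rate": float(np.mean(rej_leave)) if rej_leave else np.nan,
        "choice_rejection_rate": float(np.mean(rej_choice)) if rej_choice else np.nan,
        "n_replicates": n_replicates,
        "n_failed": failures,
    }


def recovery_experiment(
    n_replicates: int = 100,
    n_children: int = 100,
    n_trials: int = 40,
    seed: int = 0,
    policy: AgentPolicy | None = None,
    coefficients: tuple[str, ...] = ("d_novelty", "d_expected_lp", "d_expected_pe"),
) -> pd.DataFrame:
    """Parameter recovery for the exploratory-choice coefficients.

    Simulates cohorts under the expectation-driven policy, refits the choice
    model, and reports per-coefficient estimate, SE, and whether the
    generating value lies within 2 SEs, one row per replicate x coefficient.
    Zero replicates yield an empty report.
    """
    policy = policy or AgentPolicy(session_rule="fixed", fixed_n_trials=n_trials)
    rows = []
    for r in range(n_replicates):
        trials, truth = simulate_cohort(n_children, policy, seed=seed + 104729 * (r + 1))
        try:
            _, _, _, _, ls, cm = _analyse_cohort(trials, truth, choice_seed=seed + r)
        except Exception as exc:
            rows.append({"replicate": r, "term": "<failed>", "error": f"{type(exc).__name__}: {exc}"})
            continue
        frame = cm.to_frame().set_index("term")
        for term in coefficients:
            true_val = truth.choice_coef.get(term, 0.0)
            b, se = frame.loc[term, "beta"], frame.loc[term, "se"]
            rows.append({
                "replicate": r,
                "term": term,
                "true": true_val,
                "estimate": float(b),
                "se": float(se),
                "bias": float(b - true_val),
                "within_2se": bool(abs(b - true_val) <= 2 * se),
            })
    cols = ["replicate", "term", "true", "estimate", "se", "bias", "within_2se"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def model_selection_experiment(
    n_cohorts: int = 100,
    n_children: int = 87,
    n_trials: int = 40,
    seed: int = 0,
    policy: AgentPolicy | None = None,
) -> dict:
    """Expectation vs history choice-model comparison on expectation-driven cohorts.

    Reports the fraction of cohorts in which the expectation-based model has
    the lower AIC (and BIC), the qualitative analogue of the study's
    information-criterion comparison.  The default generator is the
    correctly-specified best case: agents' decision covariates come from the
    same learner configuration the analysis refits (heterogeneity acts on
    motor noise only), so the comparison isolates the expectation-vs-history
    question rather than learner mis-specification.
    """
    policy = policy or AgentPolicy(session_rule="fixed", fixed_n_trials=n_trials,
                                   impair_learner=False)
    pref_aic, pref_bic, failures = [], [], 0
    for r in range(n_cohorts):
        trials, truth = simulate_cohort(n_children, policy, seed=seed + 15485863 * (r + 1))
        try:
            est, events, table, perf, _, _ = _analyse_cohort(trials, truth, choice_seed=seed + r)
            # same response vector for both fits: keep events complete for both sets
            both = table.dropna(subset=[
                "d_novelty", "d_expected_lp", "d_expected_pe", "d_lp", "d_pe", "performance",
            ])
            fit_e = ChoiceModel.from_choice_table(both, "expectation").fit()
            fit_h = ChoiceModel.from_choice_table(both, "history").fit()
            comp = compare_models(fit_e, fit_h)
        except Exception:
            failures += 1
            continue
        pref_aic.append(comp["preferred_by_aic"] == "expectation")
        pref_bic.append(comp["preferred_by_bic"] == "expectation")
    return {
        "expectation_preferred_by_aic": float(np.mean(pref_aic)) if pref_aic else np.nan,
        "expectation_preferred_by_bic": float(np.mean(pref_bic)) if pref_bic else np.nan,
        "n_cohorts": n_cohorts,
        "n_failed": failures,
    }
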