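"""Decision models: performance slopes, leave-stay GLMM, exploratory-choice GLMM.

The layer mirrors the analysis plan of the task: (1) a linear mixed model of
PE over within-character trials gives each participant a *performance slope*
(negative = successful learning); (2) a logistic mixed model predicts per-trial
leave-stay decisions from PE, LP, novelty and time, with performance entering
in interaction; (3) a logistic mixed model on differential predictors
(chosen minus unchosen option) explains which character is selected after a
leave, contrasting expectation-based (expected LP / expected PE) against
history-based (LP / PE) accounts via AIC/BIC.

All continuous predictors are z-scored across the analysis sample before
fitting, so coefficients and odds ratios are per-SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import MixedLogit, MixedLogitResults

__all__ = [
    "fit_performance_slopes",
    "PerformanceResults",
    "LeaveStayModel",
    "ChoiceModel",
    "build_choice_table",
    "marginal_effects",
    "compute_vif",
    "compare_models",
    "zscore",
]


def zscore(x) -> np.ndarray:
    """Standardise with the population SD; constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


# ---------------------------------------------------------------------------
# performance slopes
# ---------------------------------------------------------------------------

@dataclass
class PerformanceResults:
    """Group-level fit and per-participant PE-over-trials slopes."""

    scores: pd.DataFrame          # participant_id, slope
    fixed_slope: float
    fixed_slope_se: float
    tvalue: float
    pvalue: float
    random_slope_sd: float
    method: str                   # "mixed" or "ols_fallback"
    model_result: object = field(default=None, repr=False)

    def performance_lookup(self) -> pd.Series:
        return self.scores.set_index("participant_id")["slope"]


def fit_performance_slopes(estimates: pd.DataFrame) -> PerformanceResults:
    """PE ~ within_character_trial with by-participant random slopes.

    The per-participant performance score is the fixed slope plus the
    empirical-Bayes slope deviation.  If the mixed fit is singular or fails,
    falls back to per-participant least-squares slopes.
    """
    df = estimates[["participant_id", "pe", "within_character_trial"]].dropna()
    counts = df.groupby("participant_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"participants with fewer than 2 trials: {bad}")

    try:
        model = sm.MixedLM.from_formula(
            "pe ~ within_character_trial",
            groups="participant_id",
            re_formula="~within_character_trial",
            data=df,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        re_cov = res.cov_re
        slope_var = float(re_cov.iloc[1, 1])
        fe = float(res.params["within_character_trial"])
        rows = []
        for pid, re in res.random_effects.items():
            rows.append({"participant_id": pid, "slope": fe + float(re.iloc[1])})
        scores = pd.DataFrame(rows)
        return PerformanceResults(
            scores=scores,
            fixed_slope=fe,
            fixed_slope_se=float(res.bse["within_character_trial"]),
            tvalue=float(res.tvalues["within_character_trial"]),
            pvalue=float(res.pvalues["within_character_trial"]),
            random_slope_sd=float(np.sqrt(max(slope_var, 0.0))),
            method="mixed",
            model_result=res,
        )
    except Exception:
        rows = []
        for pid, g in df.groupby("participant_id"):
            b = np.polyfit(g["within_character_trial"], g["pe"], 1)[0]
            rows.append({"participant_id": pid, "slope": float(b)})
        scores = pd.DataFrame(rows)
        s = scores["slope"].to_numpy()
        se = s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan
        t = s.mean() / se if se and se > 0 else np.nan
        return PerformanceResults(
            scores=scores,
            fixed_slope=float(s.mean()),
            fixed_slope_se=float(se),
            tvalue=float(t),
            pvalue=float(2 * stats.norm.sf(abs(t))) if np.isfinite(t) else np.nan,
            random_slope_sd=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            method="ols_fallback",
        )


# ---------------------------------------------------------------------------
# leave-stay model
# ---------------------------------------------------------------------------

LEAVE_STAY_PREDICTORS = ("pe", "lp", "novelty", "time")


class LeaveStayModel:
    """Logistic mixed model of per-trial leave (1) vs stay (0) decisions.

    Formula (all continuous predictors z-scored):

        leave ~ pe + lp + novelty + time + performance
                + performance:pe + performance:lp + performance:novelty
                + (1 | participant)

    ``novelty`` is standardised negative familiarity (-pick count of the
    current character), ``time`` the session-level trial index, and
    ``performance`` each child's PE-over-trials slope.  Rows with undefined LP
    (each character's first trial) and the censored final trial are dropped
    listwise; the dropped counts are recorded.
    """

    def __init__(self, endog, exog, groups, exog_names, dropped: dict | None = None):
        self._mixed = MixedLogit(endog, exog, groups, exog_names)
        self.dropped = dropped or {}

    @classmethod
    def from_estimates(
        cls,
        estimates: pd.DataFrame,
        performance: pd.Series | dict,
        include_performance_main: bool = True,
    ) -> "LeaveStayModel":
        df = estimates.copy()
        if "stay_leave" not in df.columns:
            from .coding import code_dataset
            df = code_dataset(df)
        n0 = len(df)
        df = df[df["stay_leave"].notna()]
        n_censored = n0 - len(df)
        n1 = len(df)
        df = df[df["lp"].notna()]
        n_missing_lp = n1 - len(df)
        if len(df) == 0:
            raise ValueError("no usable rows after dropping censored and missing-LP trials")

        perf = pd.Series(performance)
        perf_std = pd.Series(zscore(perf.to_numpy()), index=perf.index)
        p = df["participant_id"].map(perf_std)
        if p.isna().any():
            missing = sorted(df.loc[p.isna(), "participant_id"].unique().tolist())
            raise ValueError(f"no performance score for participants: {missing}")

        cols = {
            "pe": zscore(df["pe"]),
            "lp": zscore(df["lp"]),
            "novelty": zscore(-df["pick_count"].to_numpy(dtype=float)),
            "time": zscore(df["trial"]),
        }
        perf_v = p.to_numpy(dtype=float)
        names = ["intercept"] + list(cols)
        mats = [np.ones(len(df))] + [cols[c] for c in cols]
        if include_performance_main:
            names.append("performance")
            mats.append(perf_v)
        for c in ("pe", "lp", "novelty"):
            names.append(f"performance:{c}")
            mats.append(perf_v * cols[c])
        X = np.column_stack(mats)
        return cls(
            df["stay_leave"].to_numpy(), X, df["participant_id"].to_numpy(), names,
            dropped={"censored_final_trials": n_censored, "missing_lp": n_missing_lp},
        )

    @property
    def exog_names(self):
        return self._mixed.exog_names

    @property
    def exog(self):
        return self._mixed.exog

    def fit(self) -> MixedLogitResults:
        res = self._mixed.fit()
        res.dropped = self.dropped
        return res

    def vif(self) -> pd.Series:
        """VIFs of the fixed-effect predictors (intercept excluded)."""
        X = pd.DataFrame(self._mixed.exog, columns=self._mixed.exog_names)
        return compute_vif(X.drop(columns="intercept"))


# ---------------------------------------------------------------------------
# exploratory choice model
# ---------------------------------------------------------------------------

OPTION_VALUE_COLUMNS = ("expected_pe", "expected_lp", "pe", "lp", "pick_count")


def build_choice_table(
    estimates: pd.DataFrame,
    events: pd.DataFrame,
    performance: pd.Series | dict,
    seed: int = 0,
    include_excluded: bool = False,
) -> pd.DataFrame:
    """Per-event differential predictors for the choice model.

    For each leave event, both options' most recent learner quantities
    (expected PE, expected LP, last PE/LP, pick count) are looked up at the
    decision trial; the two options are put in a seeded random order and each
    differential predictor is value(option 1) - value(option 2); the response
    is 1 when option 1 was the one chosen.  Events whose chosen character was
    never visited before (no expectations exist) or whose alternative is
    unvisited are flagged and, by default, excluded.
    """
    rng = np.random.default_rng(seed)
    perf = pd.Series(performance)
    perf_std = pd.Series(zscore(perf.to_numpy()), index=perf.index)

    # per participant+character running state lookup
    state: dict = {}
    lookup: dict = {}
    est_sorted = estimates.sort_values(["participant_id", "trial"])
    for rec in est_sorted.itertuples(index=False):
        key = (rec.participant_id, rec.character_id)
        state[key] = {
            "expected_pe": rec.expected_pe,
            "expected_lp": rec.expected_lp,
            "pe": rec.pe,
            "lp": rec.lp,
            "pick_count": rec.pick_count,
        }
        lookup[(rec.participant_id, rec.trial)] = {
            c: dict(v) for (p, c), v in state.items() if p == rec.participant_id
        }

    rows = []
    for ev in events.itertuples(index=False):
        excluded = bool(ev.is_first_visit_to_chosen) or not bool(ev.alternative_visited)
        if excluded and not include_excluded:
            continue
        snap = lookup.get((ev.participant_id, ev.at_trial))
        if snap is None:
            continue
        opts = [ev.chosen_character, ev.alternative_character]
        if rng.random() < 0.5:
            opts = opts[::-1]
        o1, o2 = opts
        v1 = snap.get(o1, {})
        v2 = snap.get(o2, {})
        row = {
            "participant_id": ev.participant_id,
            "at_trial": ev.at_trial,
            "option1": o1,
            "option2": o2,
            "chose_option1": float(o1 == ev.chosen_character),
            "excluded": excluded,
            "time": ev.at_trial,
            "performance": float(perf_std.get(ev.participant_id, np.nan)),
        }
        for col in ("expected_pe", "expected_lp", "pe", "lp"):
            row[f"d_{col}"] = v1.get(col, np.nan) - v2.get(col, np.nan)
        row["d_novelty"] = -(v1.get("pick_count", np.nan) - v2.get("pick_count", np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


class ChoiceModel:
    """Logistic mixed model of which character is chosen after a leave.

    Expectation-based predictor set ("expectation"): differential novelty,
    expected LP and expected PE; history-based set ("history") replaces the
    expectations with the options' last observed LP and PE.  Both include
    time and performance interactions with the non-novelty predictors, the
    performance x novelty interaction, and participant random intercepts.
    """

    PREDICTOR_SETS = {
        "expectation": ("d_novelty", "d_expected_lp", "d_expected_pe"),
        "history": ("d_novelty", "d_lp", "d_pe"),
    }

    def __init__(self, endog, exog, groups, exog_names, n_events: int):
        self._mixed = MixedLogit(endog, exog, groups, exog_names)
        self.n_events = n_events

    @classmethod
    def from_choice_table(
        cls,
        table: pd.DataFrame,
        predictor_set: str = "expectation",
        include_interactions: bool = True,
        min_events: int = 20,
    ) -> "ChoiceModel":
        preds = cls.PREDICTOR_SETS[predictor_set]
        df = table.dropna(subset=[*preds, "performance"]).copy()
        if len(df) < min_events:
            raise ValueError(
                f"only {len(df)} usable choice events (< {min_events}); not enough to fit"
            )
        z = {p: zscore(df[p]) for p in preds}
        time_z = zscore(df["time"])
        perf = df["performance"].to_numpy(dtype=float)
        names = ["intercept", *preds]
        mats = [np.ones(len(df))] + [z[p] for p in preds]
        if include_interactions:
            for p in preds:
                if p != "d_novelty":
                    names.append(f"time:{p}")
                    mats.append(time_z * z[p])
            for p in preds:
                names.append(f"performance:{p}")
                mats.append(perf * z[p])
        X = np.column_stack(mats)
        return cls(df["chose_option1"].to_numpy(), X, df["participant_id"].to_numpy(),
                   names, n_events=len(df))

    @property
    def exog_names(self):
        return self._mixed.exog_names

    def fit(self) -> MixedLogitResults:
        return self._mixed.fit()


# ---------------------------------------------------------------------------
# diagnostics and comparisons
# ---------------------------------------------------------------------------

def marginal_effects(
    results: MixedLogitResults,
    predictors=("novelty", "lp"),
    moderator: str = "performance",
    at=(-1.0, 1.0),
) -> pd.DataFrame:
    """Link-scale slope of each predictor at fixed moderator levels.

    slope(level) = beta_main + level * beta_interaction, with delta-method
    (here exact, linear) standard errors from the fixed-effect covariance.
    """
    names = results.exog_names
    rows = []
    for pred in predictors:
        if pred not in names:
            raise ValueError(f"predictor {pred!r} not in model terms {names}")
        inter = f"{moderator}:{pred}"
        if inter not in names:
            inter = f"{pred}:{moderator}"
        if inter not in names:
            raise ValueError(f"model has no {moderator} x {pred} interaction")
        i, j = names.index(pred), names.index(inter)
        b, g = results.params[i], results.params[j]
        cov = results.cov_params
        for level in at:
            slope = b + level * g
            var = cov[i, i] + level**2 * cov[j, j] + 2 * level * cov[i, j]
            se = np.sqrt(var)
            q = stats.norm.ppf(0.975)
            rows.append({
                "predictor": pred,
                f"{moderator}_level": level,
                "slope": slope,
                "se": se,
                "z": slope / se,
                "p": 2 * stats.norm.sf(abs(slope / se)),
                "ci_low": slope - q * se,
                "ci_high": slope + q * se,
            })
    return pd.DataFrame(rows)


def compute_vif(X: pd.DataFrame, rank_tol: float = 1e-8) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) for each column of X.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    Xv = np.asarray(X, dtype=float)
    cols = list(X.columns)
    rank = np.linalg.matrix_rank(Xv, tol=rank_tol * max(1.0, np.abs(Xv).max()))
    if rank < Xv.shape[1]:
        # identify a collinear set via QR pivoting on correlations
        corr = np.corrcoef(Xv, rowvar=False)
        pairs = [
            (cols[i], cols[j])
            for i in range(len(cols)) for j in range(i + 1, len(cols))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {pairs or cols}")
    vifs = {}
    n = Xv.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(cols):
        yj = Xv[:, j]
        others = np.hstack([ones, np.delete(Xv, j, axis=1)])
        bhat, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ bhat
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        vifs[name] = 1.0 / (1.0 - min(r2, 1 - 1e-12))
    return pd.Series(vifs, name="vif")


def compare_models(fit_a: MixedLogitResults, fit_b: MixedLogitResults,
                   labels=("expectation", "history")) -> dict:
    """AIC/BIC comparison of two fits on the same response."""
    if fit_a.nobs != fit_b.nobs:
        raise ValueError(f"fits have different n ({fit_a.nobs} vs {fit_b.nobs}); not comparable")
    if not np.array_equal(fit_a.model.endog, fit_b.model.endog):
        raise ValueError("fits were computed on different response vectors")
    out = {
        labels[0]: {"aic": fit_a.aic, "bic": fit_a.bic, "loglik": fit_a.llf},
        labels[1]: {"aic": fit_b.aic, "bic": fit_b.bic, "loglik": fit_b.llf},
        "preferred_by_aic": labels[0] if fit_a.aic <= fit_b.aic else labels[1],
        "preferred_by_bic": labels[0] if fit_a.bic <= fit_b.bic else labels[1],
        "delta_aic": fit_a.aic - fit_b.aic,
        "delta_bic": fit_a.bic - fit_b.bic,
    }
    return out
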