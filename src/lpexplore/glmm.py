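"""Logistic mixed model with a participant random intercept.

Marginal likelihood is computed with the Laplace approximation: for each
group the scalar random effect is profiled out by an inner Newton solve, and
the integral is approximated by the Gaussian curvature at the mode (the same
approximation lme4's ``glmer`` uses by default).  Fixed-effect covariances
are conditional on the estimated random-intercept SD, Wald z statistics and
p-values follow, as do odds ratios with 95% CIs, log-likelihood, AIC and BIC.

This is the workhorse behind the leave-stay and exploratory-choice models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedLogit", "MixedLogitResults", "ConvergenceError", "SeparationError"]

_LOG_SIGMA_MIN = np.log(1e-4)
_LOG_SIGMA_MAX = np.log(25.0)


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimisation fails."""


class SeparationError(ConvergenceError):
    """Raised on (quasi-)complete separation: coefficients diverge."""


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x))
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = x[pos] + np.log1p(np.exp(-x[pos]))
    out[~pos] = np.log1p(np.exp(x[~pos]))
    return out


class MixedLogit:
    """Binomial GLMM: logit P(y=1) = X beta + u_group, u ~ N(0, sigma^2).

    Parameters
    ----------
    endog : (n,) array of 0/1 responses
    exog : (n, k) fixed-effects design matrix (include the intercept column)
    groups : (n,) group labels (participants)
    exog_names : optional column names for summaries
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_codes = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.nobs = len(self.endog)
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(self.exog.shape[1])]
        self.exog_names = list(exog_names)
        if self.exog.shape[0] != self.nobs or len(codes) != self.nobs:
            raise ValueError("endog, exog and groups must have matching lengths")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self._u = np.zeros(self.n_groups)  # warm start for the inner solve

    # -- inner problem: mode of the random effects given (beta, sigma) -------

    def _solve_modes(self, eta0: np.ndarray, sigma2: float) -> tuple[np.ndarray, np.ndarray]:
        """Newton solve for each group's random-effect mode (vectorised)."""
        y, g = self.endog, self.group_codes
        u = self._u.copy()
        for _ in range(50):
            eta = eta0 + u[g]
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = np.bincount(g, weights=y - p, minlength=self.n_groups) - u / sigma2
            hess = -np.bincount(g, weights=p * (1.0 - p), minlength=self.n_groups) - 1.0 / sigma2
            step = grad / hess
            # dampen huge first steps
            np.clip(step, -5.0, 5.0, out=step)
            u -= step
            if np.max(np.abs(step)) < 1e-11:
                break
        self._u = u
        eta = eta0 + u[g]
        p = 1.0 / (1.0 + np.exp(-eta))
        curv = np.bincount(g, weights=p * (1.0 - p), minlength=self.n_groups) + 1.0 / sigma2
        return u, curv

    def loglike(self, params: np.ndarray) -> float:
        """Laplace-approximate marginal log-likelihood at (beta, log sigma)."""
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = np.exp(2.0 * log_sigma)
        eta0 = self.exog @ beta
        u, curv = self._solve_modes(eta0, sigma2)
        eta = eta0 + u[self.group_codes]
        cond_ll = float(np.sum(self.endog * eta - _log1pexp(eta)))
        prior = -0.5 * float(np.sum(u * u)) / sigma2
        laplace = -0.5 * float(np.sum(np.log(sigma2 * curv)))
        return cond_ll + prior + laplace

    # -- outer optimisation --------------------------------------------------

    def fit(self, start_params=None, maxiter: int = 400) -> "MixedLogitResults":
        k = self.exog.shape[1]
        if start_params is None:
            start_params = np.zeros(k + 1)
            start_params[-1] = np.log(0.5)
        self._u = np.zeros(self.n_groups)

        def nll(params):
            return -self.loglike(params)

        bounds = [(None, None)] * k + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                nll, start_params, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
        params = res.x
        if np.max(np.abs(params[:-1])) > 20.0:
            raise SeparationError(
                "fixed-effect estimate exceeded |beta| > 20; likely complete separation. "
                f"terms: {self.exog_names}, params: {np.round(params[:-1], 2)}"
            )
        if not res.success and res.status != 1:  # status 1 = maxiter
            raise ConvergenceError(f"L-BFGS-B failed: {res.message}")

        # covariance of beta conditional on the variance parameter
        hess = self._numeric_hessian_beta(params)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular fixed-effects Hessian") from exc
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise ConvergenceError("non-positive variance estimate for a fixed effect")

        return MixedLogitResults(
            model=self,
            params=params[:-1].copy(),
            re_sd=float(np.exp(params[-1])),
            cov_params=cov,
            llf=float(-res.fun),
            converged=bool(res.success),
        )

    def _numeric_hessian_beta(self, params: np.ndarray) -> np.ndarray:
        """Central-difference Hessian of -loglike in beta at the optimum."""
        k = self.exog.shape[1]
        h = 1e-4 * np.maximum(1.0, np.abs(params[:k]))
        hess = np.empty((k, k))

        def f(beta):
            p = params.copy()
            p[:k] = beta
            return -self.loglike(p)

        beta0 = params[:k]
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = f(beta0 + ei + ej)
                fpm = f(beta0 + ei - ej)
                fmp = f(beta0 - ei + ej)
                fmm = f(beta0 - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        return 0.5 * (hess + hess.T)


class MixedLogitResults:
    """Estimates, uncertainties and information criteria for a MixedLogit fit."""

    def __init__(self, model, params, re_sd, cov_params, llf, converged):
        self.model = model
        self.params = params
        self.re_sd = re_sd
        self.cov_params = cov_params
        self.llf = llf
        self.converged = converged
        self.exog_names = model.exog_names
        self.nobs = model.nobs
        self.k_params = len(params) + 1  # fixed effects + random-intercept SD

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def odds_ratio_conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.exp(self.conf_int(alpha))

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.nobs) - 2.0 * self.llf

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        orci = self.odds_ratio_conf_int()
        return pd.DataFrame({
            "term": self.exog_names,
            "beta": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "p": self.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "odds_ratio": self.odds_ratios,
            "or_ci_low": orci[:, 0],
            "or_ci_high": orci[:, 1],
        })

    def to_dict(self) -> dict:
        return {
            "terms": self.to_frame().to_dict(orient="records"),
            "random_intercept_sd": self.re_sd,
            "loglik": self.llf,
            "k_params": self.k_params,
            "nobs": self.nobs,
            "n_groups": self.model.n_groups,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Mixed logistic regression (Laplace, random intercept per group)",
            f"  observations: {self.nobs}   groups: {self.model.n_groups}   "
            f"logLik: {self.llf:.2f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"  random-intercept SD: {self.re_sd:.3f}",
            "",
            f"{'term':<28}{'beta':>9}{'se':>8}{'z':>7}{'p':>8}{'OR':>8}{'OR 95% CI':>18}",
        ]
        for r in df.itertuples(index=False):
            lines.append(
                f"{r.term:<28}{r.beta:>9.3f}{r.se:>8.3f}{r.z:>7.2f}{r.p:>8.3g}"
                f"{r.odds_ratio:>8.2f}   [{r.or_ci_low:.2f}, {r.or_ci_high:.2f}]"
            )
        return "\n".join(lines)
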