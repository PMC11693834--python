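"""Independent reference computations used only to check the package.

These deliberately take different routes from the implementation: explicit
two-hypothesis posterior normalisation in log space for the changepoint
probability, and a full Bayesian run-length (changepoint) filter for the
relative-uncertainty trajectory.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# prior over a freshly drawn hiding mean: Gaussian moment-match of the
# uniform redraw on [0.1, 0.9]
MU0 = 0.5
S0SQ = 0.8**2 / 12.0


def bayes_changepoint_prob(delta: float, predictive_sd: float, hazard: float,
                           domain_width: float = 1.0) -> float:
    """Two-hypothesis Bayes: changepoint (uniform outcome) vs no changepoint."""
    if hazard == 0.0:
        return 0.0
    if hazard == 1.0:
        return 1.0
    log_cp = np.log(hazard) + np.log(1.0 / domain_width)
    log_nc = np.log1p(-hazard) + stats.norm.logpdf(delta, loc=0.0, scale=predictive_sd)
    m = max(log_cp, log_nc)
    return float(np.exp(log_cp - m) / (np.exp(log_cp - m) + np.exp(log_nc - m)))


def run_length_tau(xs, hazard: float, noise_sd: float, rmax: int = 300) -> np.ndarray:
    """Relative uncertainty of a full Bayesian run-length filter, per trial.

    Conjugate Normal prior N(MU0, S0SQ) on each freshly drawn mean; the
    reported tau is Var(mean)/(Var(mean) + noise variance) under the full
    run-length mixture, computed after updating on each observation.
    """
    var_n = noise_sd**2
    m = np.array([MU0])
    v = np.array([S0SQ])
    w = np.array([1.0])
    taus = []
    for x in xs:
        pred_sd = np.sqrt(v + var_n)
        like = np.exp(-0.5 * ((x - m) / pred_sd) ** 2) / (pred_sd * np.sqrt(2 * np.pi))
        cp_sd = np.sqrt(S0SQ + var_n)
        like_cp = np.exp(-0.5 * ((x - MU0) / cp_sd) ** 2) / (cp_sd * np.sqrt(2 * np.pi))
        w_grow = w * (1.0 - hazard) * like
        w_cp = np.sum(w * hazard) * like_cp
        v_post = 1.0 / (1.0 / v + 1.0 / var_n)
        m_post = v_post * (m / v + x / var_n)
        v0 = 1.0 / (1.0 / S0SQ + 1.0 / var_n)
        m0 = v0 * (MU0 / S0SQ + x / var_n)
        m = np.concatenate([[m0], m_post])
        v = np.concatenate([[v0], v_post])
        w = np.concatenate([[w_cp], w_grow])
        w /= w.sum()
        if len(w) > rmax:
            m, v, w = m[:rmax], v[:rmax], w[:rmax]
            w /= w.sum()
        mu_bar = np.sum(w * m)
        var_mu = np.sum(w * (v + m**2)) - mu_bar**2
        taus.append(var_mu / (var_mu + var_n))
    return np.asarray(taus)


def generate_volatile_sequence(rng: np.random.Generator, n: int, hazard: float,
                               noise_sd: float) -> list[float]:
    """Outcome sequence from the volatile-Gaussian generative process."""
    mu = rng.uniform(0.1, 0.9)
    xs = []
    for t in range(n):
        if t > 0 and rng.random() < hazard:
            mu = rng.uniform(0.1, 0.9)
        while True:
            x = rng.normal(mu, noise_sd)
            if 0.0 <= x <= 1.0:
                break
        xs.append(float(x))
    return xs
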