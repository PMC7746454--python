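"""ANCOVA estimation of the geometric-mean ratio in a 2x2 crossover.

With complete (possibly imputed) data, each subject contributes the log
period-difference of post-treatment times, Delta = log y1 - log y2,
regressed on the baseline difference D = log b1 - log b2 and the
sequence indicator Q (1 for AB, treatment A first):

    Delta = gamma0 + gamma1 * D + gamma2 * Q + eps,   eps ~ N(0, eta^2).

Since E[Delta | AB] - E[Delta | BA] = 2 log(theta), the ratio of
geometric means of event times under A relative to B is estimated by
log(theta-hat) = gamma2-hat / 2, with SE(gamma2-hat)/2 as its standard
error; H0: theta = 1 is the t test of gamma2 = 0 on n - 3 degrees of
freedom.  Two 95% intervals are reported: the exponentiated log-scale
interval, and the symmetric theta-scale interval theta-hat +/- z * SE
with the delta-method SE(theta-hat) = theta-hat * SE(log theta-hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .dataset import CrossoverDataset

__all__ = [
    "AncovaResult",
    "ThetaEstimate",
    "CrossoverAncova",
    "build_contrasts",
    "fit_ancova",
    "estimate_theta",
]


@dataclass(frozen=True)
class AncovaResult:
    """OLS fit of the crossover ANCOVA (intercept, D, Q)."""

    gamma: np.ndarray          # (gamma0, gamma1, gamma2)
    se_gamma: np.ndarray
    sigma2: float              # residual variance eta^2
    df: int                    # n - 3
    n: int


@dataclass(frozen=True)
class ThetaEstimate:
    """Inference for the geometric-mean ratio theta (A vs B)."""

    log_theta_hat: float
    se_log_theta: float
    theta_hat: float
    se_theta: float
    ci_log: tuple[float, float]
    ci_theta_symmetric: tuple[float, float]
    p_value: float
    p_value_normal: float
    alpha: float


def build_contrasts(ds: CrossoverDataset):
    """Per-subject (Delta, D, Q) from a complete dataset.

    Raises if any post-treatment time is still censored — impute first.
    """
    if not ds.is_complete:
        raise ValueError(
            f"{ds.n_censored} censored value(s) remain; run imputation "
            "before the ANCOVA"
        )
    f = ds.to_frame()
    delta = np.log(f["y1"].to_numpy(float)) - np.log(f["y2"].to_numpy(float))
    d = np.log(f["b1"].to_numpy(float)) - np.log(f["b2"].to_numpy(float))
    q = (f["sequence"] == "AB").to_numpy(float)
    return delta, d, q


def fit_ancova(delta, d, q) -> AncovaResult:
    """OLS of Delta on (1, D, Q) with classical standard errors."""
    delta = np.asarray(delta, float)
    d = np.asarray(d, float)
    q = np.asarray(q, float)
    n = delta.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects (3 parameters + 1 df)")
    if len(np.unique(q)) < 2:
        raise ValueError("both sequences must be represented")
    X = np.column_stack([np.ones(n), d, q])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError(
            "rank-deficient design (is the baseline difference constant?)"
        )
    res = sm.OLS(delta, X).fit()
    return AncovaResult(
        gamma=np.asarray(res.params, float),
        se_gamma=np.asarray(res.bse, float),
        sigma2=float(res.scale),
        df=int(res.df_resid),
        n=n,
    )


def estimate_theta(res: AncovaResult, alpha: float = 0.05) -> ThetaEstimate:
    """Geometric-mean-ratio inference from the fitted ANCOVA."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    log_theta = float(res.gamma[2]) / 2.0
    se_log = float(res.se_gamma[2]) / 2.0
    theta = float(np.exp(log_theta))
    se_theta = theta * se_log
    tcrit = stats.t.ppf(1 - alpha / 2, res.df)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    tstat = log_theta / se_log if se_log > 0 else np.inf * np.sign(log_theta)
    return ThetaEstimate(
        log_theta_hat=log_theta,
        se_log_theta=se_log,
        theta_hat=theta,
        se_theta=se_theta,
        ci_log=(log_theta - tcrit * se_log, log_theta + tcrit * se_log),
        ci_theta_symmetric=(theta - zcrit * se_theta, theta + zcrit * se_theta),
        p_value=float(2 * stats.t.sf(abs(tstat), res.df)),
        p_value_normal=float(2 * stats.norm.sf(abs(tstat))),
        alpha=alpha,
    )


class CrossoverAncova(BaseEstimator):
    """Estimator interface around the crossover ANCOVA.

    ``fit`` accepts a complete :class:`CrossoverDataset` (or an
    ``(Delta, D, Q)`` triple) and exposes the usual fitted attributes.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided level of the confidence intervals.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        if isinstance(X, CrossoverDataset):
            delta, d, q = build_contrasts(X)
        else:
            delta, d, q = X
        res = fit_ancova(delta, d, q)
        est = estimate_theta(res, alpha=self.alpha)
        self.ancova_ = res
        self.gamma_ = res.gamma
        self.se_gamma_ = res.se_gamma
        self.sigma2_ = res.sigma2
        self.df_ = res.df
        self.log_theta_ = est.log_theta_hat
        self.se_log_theta_ = est.se_log_theta
        self.theta_ = est.theta_hat
        self.se_theta_ = est.se_theta
        self.ci_log_ = est.ci_log
        self.ci_theta_symmetric_ = est.ci_theta_symmetric
        self.p_value_ = est.p_value
        self.p_value_normal_ = est.p_value_normal
        self.estimate_ = est
        return self
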