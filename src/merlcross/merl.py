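"""Median residual life (MERL) regression for right-censored times.

The median residual life at a reference time ``t0`` is

    m(t0) = median(T - t0 | T > t0),

the median remaining lifetime among survivors beyond ``t0``.  With
covariates ``x`` the model is log-linear,

    median(T - t0 | T > t0, x) = exp(x' beta(t0)),

so predicted median residuals are strictly positive.  Two fitting routes
are provided:

* ``parametric`` (default): a maximum-likelihood accelerated failure
  time (AFT) fit with right censoring — Weibull, exponential or
  log-normal — after which ``m(t0 | x) = S_x^{-1}(S_x(t0)/2) - t0`` with
  ``S_x`` the fitted conditional survivor.  This route extrapolates
  beyond an administrative cap ``tau``, which is essential when every
  censored subject sits exactly at ``tau`` and the risk set beyond it is
  empty.
* ``semiparametric``: direct minimisation of the inverse-probability-of-
  censoring-weighted (IPCW) median check loss of ``log(T - t0)`` among
  at-risk uncensored subjects, giving ``exp(x' beta)`` at the single
  reference time ``t0``.  Requires observed events beyond ``t0``, hence
  is suited to random (not administrative) censoring.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "CensoringSurvivor",
    "km_censoring_survivor",
    "MedianResidualLifeRegressor",
    "DegenerateRiskSetError",
    "fit_merl_semiparametric",
    "fit_merl_parametric",
    "predict_median_residual",
]

FAMILIES = ("weibull", "exponential", "lognormal")
LN2 = float(np.log(2.0))


class DegenerateRiskSetError(RuntimeError):
    """Too few observed events beyond t0 to identify the MERL equation."""


class CensoringSurvivor:
    """Right-continuous step estimate of P(C > t) for the censoring time C."""

    def __init__(self, times: np.ndarray, probs: np.ndarray):
        self.times_ = np.asarray(times, float)
        self.probs_ = np.asarray(probs, float)

    def __call__(self, t) -> np.ndarray:
        """G-hat(t), evaluated right-continuously."""
        idx = np.searchsorted(self.times_, np.asarray(t, float), side="right")
        vals = np.concatenate([[1.0], self.probs_])[idx]
        return vals if np.ndim(t) else float(vals)

    def left(self, t) -> np.ndarray:
        """G-hat(t-), the left limit (IPCW weights use 1/G(t-))."""
        idx = np.searchsorted(self.times_, np.asarray(t, float), side="left")
        vals = np.concatenate([[1.0], self.probs_])[idx]
        return vals if np.ndim(t) else float(vals)


def km_censoring_survivor(times, events) -> CensoringSurvivor:
    """Kaplan-Meier estimate of the censoring-time survivor function.

    Event indicators are flipped: a censoring is the "event" here, and
    observed failures are the censored observations of C.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    km = KaplanMeierFitter()
    km.fit(times, event_observed=~events)
    sf = km.survival_function_
    t = sf.index.to_numpy(float)
    p = sf.iloc[:, 0].to_numpy(float)
    keep = t > 0
    return CensoringSurvivor(t[keep], p[keep])


# ---------------------------------------------------------------------------
# parametric AFT likelihoods
# ---------------------------------------------------------------------------
# Parameterisation: linear predictor mu_i = x_i' beta on the log-time scale.
#   weibull     : S(t|x) = exp(-(t/e^mu)^s), shape s > 0
#   exponential : weibull with s = 1
#   lognormal   : log T | x ~ N(mu, sigma^2)
# Internal parameter vector: (beta..., log s) resp. (beta..., log sigma).


def _weibull_negll_grad(params, Xmat, logt, delta, fix_shape):
    k = Xmat.shape[1]
    beta = params[:k]
    s = 1.0 if fix_shape else np.exp(params[k])
    w = logt - Xmat @ beta
    sw = np.clip(s * w, -700, 700)
    e = np.exp(sw)
    ll = np.sum(delta * (np.log(s) + s * w - logt)) - np.sum(e)
    # d(-ll)/dbeta_j = -s * sum_i (e_i - delta_i) x_ij
    gbeta = -s * (Xmat * (e - delta)[:, None]).sum(axis=0)
    if fix_shape:
        return -ll, gbeta
    glogs = np.sum(delta * (1.0 + s * w)) - s * np.sum(e * w)
    return -ll, np.concatenate([gbeta, [-glogs]])


def _lognormal_negll(params, Xmat, logt, delta):
    k = Xmat.shape[1]
    beta, sigma = params[:k], np.exp(params[k])
    z = (logt - Xmat @ beta) / sigma
    ll = np.sum(delta * (stats.norm.logpdf(z) - np.log(sigma) - logt))
    ll += np.sum((1 - delta) * stats.norm.logsf(z))
    return -ll


def _converged(res) -> bool:
    # BFGS can report "precision loss" with the gradient already at
    # machine-level zero; judge by the achieved gradient norm.
    if res.success:
        return True
    jac = getattr(res, "jac", None)
    if jac is None:
        return False
    return bool(np.max(np.abs(jac)) <= 1e-5 * (1.0 + abs(res.fun)))


def _fit_aft(Xmat, times, delta, family, tol, maxiter):
    """Return (beta, aux, converged). aux = shape (weibull) / sigma (lognormal)."""
    logt = np.log(times)
    # start: OLS of log t on X, shape/sigma from residual spread
    beta0, *_ = np.linalg.lstsq(Xmat, logt, rcond=None)
    resid = logt - Xmat @ beta0
    spread = max(float(np.std(resid)), 1e-2)

    if family in ("weibull", "exponential"):
        fix = family == "exponential"
        x0 = beta0 if fix else np.concatenate([beta0, [np.log(1.0 / spread)]])
        res = optimize.minimize(
            _weibull_negll_grad,
            x0,
            args=(Xmat, logt, delta, fix),
            jac=True,
            method="BFGS",
            options={"gtol": tol, "maxiter": maxiter},
        )
        k = Xmat.shape[1]
        beta = res.x[:k]
        aux = 1.0 if fix else float(np.exp(res.x[k]))
        return beta, aux, _converged(res)
    if family == "lognormal":
        x0 = np.concatenate([beta0, [np.log(spread)]])
        res = optimize.minimize(
            _lognormal_negll,
            x0,
            args=(Xmat, logt, delta),
            method="BFGS",
            options={"gtol": tol, "maxiter": maxiter},
        )
        k = Xmat.shape[1]
        return res.x[:k], float(np.exp(res.x[k])), _converged(res)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class MedianResidualLifeRegressor(BaseEstimator):
    """Log-linear regression for the conditional median residual life.

    Parameters
    ----------
    route : {"parametric", "semiparametric"}, default "parametric"
        Fitting route (see module docstring).
    family : {"weibull", "exponential", "lognormal"}, default "weibull"
        AFT family of the parametric route.
    t0 : float, default 0.0
        Reference time of the semiparametric route (the parametric route
        predicts at any ``t0``).
    min_events : int, default 5
        Minimum observed events beyond ``t0`` the semiparametric route
        requires before declaring the risk set degenerate.
    fallback : bool, default True
        On Weibull non-convergence, refit as exponential with a warning.
    tol : float, default 1e-8
        Optimizer gradient tolerance.
    maxiter : int, default 2000
        Optimizer iteration cap.

    Attributes
    ----------
    coef_ : ndarray, (n_features + 1,)
        Intercept followed by covariate coefficients on the log scale.
    coef_names_ : list of str
    shape_ : float
        Weibull shape (1 for exponential) or log-normal sigma.
    converged_ : bool
    n_at_risk_, n_events_used_ : int
    """

    def __init__(
        self,
        route: str = "parametric",
        family: str = "weibull",
        t0: float = 0.0,
        min_events: int = 5,
        fallback: bool = True,
        tol: float = 1e-8,
        maxiter: int = 2000,
    ):
        self.route = route
        self.family = family
        self.t0 = t0
        self.min_events = min_events
        self.fallback = fallback
        self.tol = tol
        self.maxiter = maxiter

    # -- helpers -------------------------------------------------------
    def _prepare_X(self, X):
        if X is None:
            return np.empty((0, 0)), []
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(float), list(X.columns)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X, [f"x{i}" for i in range(X.shape[1])]

    def fit(self, X, y):
        """Fit the model.

        Parameters
        ----------
        X : array-like or DataFrame of shape (n, p), or None
            Covariates (no intercept column; one is added).
        y : pair (times, events) or structured array with fields
            ``time`` and ``event``.
        """
        times, events = _unpack_survival(y)
        Xmat, names = self._prepare_X(X)
        n = times.shape[0]
        if Xmat.size == 0:
            Xmat = np.empty((n, 0))
        if Xmat.shape[0] != n:
            raise ValueError("X and y lengths differ")
        if np.any(times <= 0):
            raise ValueError("times must be strictly positive")
        self.coef_names_ = ["intercept"] + names
        design = np.column_stack([np.ones(n), Xmat])

        if self.route == "parametric":
            if events.sum() < 1:
                raise ValueError("parametric fit needs at least one observed event")
            if n < design.shape[1] + 2:
                raise ValueError(
                    f"need at least {design.shape[1] + 2} subjects for "
                    f"{design.shape[1]} parameters"
                )
            family = self.family
            beta, aux, ok = _fit_aft(design, times, events.astype(float),
                                     family, self.tol, self.maxiter)
            if not ok and family == "weibull" and self.fallback:
                warnings.warn(
                    "Weibull AFT did not converge; falling back to exponential",
                    RuntimeWarning,
                )
                family = "exponential"
                beta, aux, ok = _fit_aft(design, times, events.astype(float),
                                         family, self.tol, self.maxiter)
            if not ok:
                raise RuntimeError("parametric MERL fit failed to converge")
            self.family_ = family
            self.coef_ = beta
            self.shape_ = aux
            self.converged_ = ok
            self.n_at_risk_ = n
            self.n_events_used_ = int(events.sum())
            return self

        if self.route == "semiparametric":
            t0 = float(self.t0)
            ghat = km_censoring_survivor(times, events)
            use = (times > t0) & events
            self.n_at_risk_ = int((times > t0).sum())
            self.n_events_used_ = int(use.sum())
            if self.n_events_used_ < max(self.min_events, design.shape[1]):
                raise DegenerateRiskSetError(
                    f"only {self.n_events_used_} observed events beyond t0={t0:g}; "
                    "the semiparametric MERL equation is unidentified — "
                    "use the parametric route"
                )
            r = np.log(times[use] - t0)
            A = design[use]
            w = 1.0 / np.maximum(ghat.left(times[use]), 1e-12)
            if A.shape[1] == 1:
                # intercept only: the weighted-L1 minimizer is the
                # weighted median of the residual lifetimes.  For an
                # even split the minimizing set is an interval; take the
                # midpoint of the two central order statistics, the
                # summary-median convention.
                self.coef_ = np.array([np.log(_weighted_median(times[use] - t0, w))])
                self.converged_ = True
            else:
                # start at weighted least squares, polish with simplex
                # on the weighted L1 (median check) loss
                beta0 = np.linalg.lstsq(A * np.sqrt(w)[:, None], r * np.sqrt(w),
                                        rcond=None)[0]

                def loss(b):
                    return float(np.sum(w * np.abs(r - A @ b)))

                res = optimize.minimize(
                    loss, beta0, method="Nelder-Mead",
                    options={"xatol": self.tol ** 0.5, "fatol": self.tol ** 0.5,
                             "maxiter": self.maxiter, "maxfev": self.maxiter},
                )
                self.coef_ = res.x
                self.converged_ = bool(res.success)
            self.shape_ = None
            self.family_ = None
            return self

        raise ValueError(f"unknown route {self.route!r}")

    def predict(self, X, t0: float | None = None) -> np.ndarray:
        """Predicted median residual life m(t0 | x) for each row of X."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit before predict")
        t0 = float(self.t0 if t0 is None else t0)
        if t0 < 0:
            raise ValueError("t0 must be nonnegative")
        Xmat, names = self._prepare_X(X)
        if Xmat.ndim == 2 and Xmat.shape[1] != len(self.coef_names_) - 1:
            raise ValueError(
                f"expected {len(self.coef_names_) - 1} covariates "
                f"({self.coef_names_[1:]}), got {Xmat.shape[1]}"
            )
        if isinstance(X, pd.DataFrame) and names != self.coef_names_[1:]:
            raise ValueError(
                f"covariate names {names} do not match fit {self.coef_names_[1:]}"
            )
        design = np.column_stack([np.ones(len(Xmat)), Xmat])
        mu = design @ self.coef_

        if self.route == "semiparametric":
            if not np.isclose(t0, float(self.t0)):
                raise ValueError(
                    f"semiparametric fit is specific to t0={self.t0:g}; "
                    f"cannot predict at t0={t0:g}"
                )
            return np.exp(mu)

        return _parametric_mrl(self.family_, mu, self.shape_, t0)


def _parametric_mrl(family, mu, aux, t0):
    """m(t0|x) = S^{-1}(S(t0)/2) - t0 for the fitted AFT family."""
    scale = np.exp(mu)
    if family == "exponential":
        return LN2 * scale  # memoryless: constant in t0
    if family == "weibull":
        s = aux
        return scale * ((t0 / scale) ** s + LN2) ** (1.0 / s) - t0
    if family == "lognormal":
        sigma = aux
        if t0 == 0:
            return scale  # exp(mu) is the unconditional median
        logs_t0 = stats.norm.logsf((np.log(t0) - mu) / sigma)
        if np.any(logs_t0 < np.log(1e-300)):
            raise FloatingPointError("conditional survivor numerically 0 at t0")
        # S(u) = S(t0)/2  =>  z = Phi^{-1}(1 - S(t0)/2)
        z = -special.ndtri(np.exp(logs_t0 - LN2))
        return np.exp(mu + sigma * z) - t0
    raise ValueError(family)


def _weighted_median(values, weights):
    """Weighted median; equal-weight halves resolve to the midpoint."""
    order = np.argsort(values)
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if np.isclose(cum[i], half) and i + 1 < len(v):
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def _unpack_survival(y):
    """Accept (times, events) pairs or a structured survival array."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        tname = "time" if "time" in names else names[1]
        ename = "event" if "event" in names else names[0]
        return np.asarray(y[tname], float), np.asarray(y[ename], bool)
    times, events = y
    return np.asarray(times, float), np.asarray(events, bool)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_merl_semiparametric(times, events, X, t0, **kw) -> MedianResidualLifeRegressor:
    """IPCW median-check-loss fit of the log-linear MERL model at ``t0``."""
    return MedianResidualLifeRegressor(route="semiparametric", t0=t0, **kw).fit(
        X, (times, events)
    )


def fit_merl_parametric(times, events, X, family="weibull", **kw) -> MedianResidualLifeRegressor:
    """Maximum-likelihood AFT fit usable for MERL prediction at any t0."""
    return MedianResidualLifeRegressor(route="parametric", family=family, **kw).fit(
        X, (times, events)
    )


def predict_median_residual(fit: MedianResidualLifeRegressor, t0, x) -> np.ndarray:
    """Median residual life at ``t0`` for covariate row(s) ``x``."""
    x = np.atleast_2d(np.asarray(x, float)) if not isinstance(x, pd.DataFrame) else x
    return fit.predict(x, t0=t0)
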