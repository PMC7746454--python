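"""Sequential median-residual-life imputation of censored crossover times.

Censored post-treatment times are completed one period at a time.  For
period 1 a single MERL model is fitted to all subjects pooled across
sequences, with the period-1 treatment indicator (1 = treatment A),
optionally age, and the period-1 baseline as covariates.  Each censored
``y1`` is replaced by its censoring time ``t0`` plus the predicted
median residual life ``m(t0 | x)``.  Period 2 is then completed the same
way, additionally conditioning on the completed period-1 outcome.

Under administrative censoring every ``t0`` equals the follow-up cap
``tau`` and no events are observed beyond it, so the default route is
the parametric (Weibull AFT) fit, which extrapolates the conditional
survivor past ``tau``; imputed times therefore exceed ``tau``, as they
must.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import CrossoverDataset
from .merl import MedianResidualLifeRegressor

__all__ = [
    "ImputationConfig",
    "ImputedDataset",
    "CrossoverImputer",
    "impute_period1",
    "impute_period2",
    "impute_dataset",
]


#: default covariate lists of the period-specific MERL models; ``age`` is
#: dropped automatically when absent, ``y1`` is the completed period-1
#: outcome.  A ``log_`` prefix puts a time-valued covariate on the log
#: scale — advisable when baselines are unbounded, since a
#: linear-in-time exponent extrapolates explosively at large values.
PERIOD1_COVARIATES = ("treatment", "age", "b1")
PERIOD2_COVARIATES = ("treatment", "age", "b2", "y1")

#: arm-pooled, log-scale covariate lists used by the simulation harness:
#: an arm-specific imputation term injects shared estimation noise into
#: one arm's completed values and inflates the type-I error of the
#: ANCOVA (see the methods note).
POOLED_PERIOD1_COVARIATES = ("log_b1",)
POOLED_PERIOD2_COVARIATES = ("log_b2", "log_y1")


@dataclass
class ImputationConfig:
    """Configuration of the sequential imputation.

    route : "parametric" or "semiparametric"; family : AFT family of the
    parametric route; use_age : True / False / "auto" (include age when
    every subject has one); include_b1 : also condition period 2 on the
    period-1 baseline; period1_covariates / period2_covariates : override
    the model covariate lists entirely.
    """

    route: str = "parametric"
    family: str = "weibull"
    use_age: bool | str = "auto"
    include_b1: bool = False
    min_events: int = 5
    period1_covariates: tuple[str, ...] | None = None
    period2_covariates: tuple[str, ...] | None = None
    extra: dict = field(default_factory=dict)


class ImputedDataset(CrossoverDataset):
    """A completed crossover dataset plus an audit of every imputation.

    ``audit`` has one row per originally censored value: subject, period,
    censoring time ``t0``, predicted median residual ``median_residual``
    and the final ``imputed_time = t0 + median_residual``.
    """

    def __init__(self, frame, tau, audit: pd.DataFrame, fits: dict):
        # the source frame was validated on entry and imputation only
        # replaces censored times by larger positive ones
        super().__init__(frame, tau=tau, validate=False)
        self.audit = audit.reset_index(drop=True)
        self.fits = fits

    def __repr__(self) -> str:
        return (
            f"ImputedDataset(n={len(self)}, tau={self.tau:g}, "
            f"imputed={len(self.audit)})"
        )


AUDIT_COLUMNS = ["subject_id", "period", "t0", "median_residual", "imputed_time"]


def _resolve_use_age(ds: CrossoverDataset, cfg: ImputationConfig) -> bool:
    if cfg.use_age == "auto":
        return ds.has_age
    if cfg.use_age and not ds.has_age:
        raise ValueError("use_age=True but some subjects have no age")
    return bool(cfg.use_age)


def _covariate_list(period: int, cfg: ImputationConfig, use_age: bool
                    ) -> tuple[str, ...]:
    if period == 1:
        names = cfg.period1_covariates or PERIOD1_COVARIATES
    else:
        names = cfg.period2_covariates
        if names is None:
            names = PERIOD2_COVARIATES
            if cfg.include_b1:
                names = names[:-1] + ("b1", names[-1])
    if not use_age:
        names = tuple(n for n in names if n not in ("age", "log_age"))
    return tuple(names)


def _design(frame: pd.DataFrame, period: int, cfg: ImputationConfig,
            use_age: bool) -> pd.DataFrame:
    """Covariate matrix for the period model.

    The treatment indicator is 1 when the subject receives treatment A in
    that period: sequence AB in period 1, BA in period 2.  ``y1`` refers
    to the (completed) period-1 post-treatment outcome.  A ``log_``
    prefix log-transforms the named column.
    """
    treated_seq = "AB" if period == 1 else "BA"
    cols = {}
    for name in _covariate_list(period, cfg, use_age):
        base, log = (name[4:], True) if name.startswith("log_") else (name, False)
        if base == "treatment":
            cols[name] = (frame["sequence"] == treated_seq).astype(float)
            continue
        if base not in frame.columns:
            raise ValueError(f"unknown covariate {name!r}")
        v = frame[base].astype(float)
        cols[name] = np.log(v) if log else v
    return pd.DataFrame(cols, index=frame.index)


def _impute_period(frame: pd.DataFrame, period: int, cfg: ImputationConfig,
                   use_age: bool) -> tuple[pd.DataFrame, pd.DataFrame,
                                           MedianResidualLifeRegressor | None]:
    ycol, dcol = f"y{period}", f"delta{period}"
    censored = ~frame[dcol].to_numpy(bool)
    empty_audit = pd.DataFrame(columns=AUDIT_COLUMNS)
    if not censored.any():
        return frame, empty_audit, None
    if frame[dcol].sum() < 1:
        raise ValueError(f"no observed events in period {period}")

    X = _design(frame, period, cfg, use_age)
    times = frame[ycol].to_numpy(float)
    events = frame[dcol].to_numpy(bool)

    rows = []
    out = frame.copy()
    completed = times.copy()
    if cfg.route == "semiparametric":
        # one fit per distinct censoring time (the model is t0-specific)
        fit = None
        for t0 in np.unique(times[censored]):
            fit = MedianResidualLifeRegressor(
                route="semiparametric", t0=float(t0),
                min_events=cfg.min_events, **cfg.extra,
            ).fit(X, (times, events))
            sel = np.flatnonzero(censored & np.isclose(times, t0))
            m = fit.predict(X.iloc[sel], t0=float(t0))
            completed[sel] = t0 + m
            for sid, mi in zip(frame["subject_id"].to_numpy()[sel], m):
                rows.append((sid, period, float(t0), float(mi), float(t0 + mi)))
    else:
        fit = MedianResidualLifeRegressor(
            route="parametric", family=cfg.family, **cfg.extra,
        ).fit(X, (times, events))
        cens_idx = np.flatnonzero(censored)
        for t0 in np.unique(times[cens_idx]):
            sel = cens_idx[np.isclose(times[cens_idx], t0)]
            m = fit.predict(X.iloc[sel], t0=float(t0))
            completed[sel] = t0 + m
            for sid, mi in zip(frame["subject_id"].to_numpy()[sel], m):
                rows.append((sid, period, float(t0), float(mi), float(t0 + mi)))
    out[ycol] = completed
    out[dcol] = True
    audit = pd.DataFrame(rows, columns=AUDIT_COLUMNS)
    return out, audit, fit


class CrossoverImputer(BaseEstimator, TransformerMixin):
    """Completes censored post-treatment times of a crossover trial.

    A transformer over :class:`CrossoverDataset`: ``transform`` fits the
    period-specific MERL models on the dataset itself (single
    deterministic imputation, as in most complete-case substitutes) and
    returns an :class:`ImputedDataset` whose audit lists every completed
    value.  Parameters mirror :class:`ImputationConfig`.
    """

    def __init__(self, route: str = "parametric", family: str = "weibull",
                 use_age: bool | str = "auto", include_b1: bool = False,
                 min_events: int = 5,
                 period1_covariates: tuple[str, ...] | None = None,
                 period2_covariates: tuple[str, ...] | None = None):
        self.route = route
        self.family = family
        self.use_age = use_age
        self.include_b1 = include_b1
        self.min_events = min_events
        self.period1_covariates = period1_covariates
        self.period2_covariates = period2_covariates

    def _config(self) -> ImputationConfig:
        return ImputationConfig(
            route=self.route, family=self.family, use_age=self.use_age,
            include_b1=self.include_b1, min_events=self.min_events,
            period1_covariates=self.period1_covariates,
            period2_covariates=self.period2_covariates,
        )

    def fit(self, ds: CrossoverDataset, y=None):
        result = self.transform(ds)
        self.period1_fit_ = result.fits.get(1)
        self.period2_fit_ = result.fits.get(2)
        return self

    def transform(self, ds: CrossoverDataset) -> ImputedDataset:
        cfg = self._config()
        use_age = _resolve_use_age(ds, cfg)
        frame = ds.to_frame()
        frame, audit1, fit1 = _impute_period(frame, 1, cfg, use_age)
        frame, audit2, fit2 = _impute_period(frame, 2, cfg, use_age)
        audit = pd.concat([audit1, audit2], ignore_index=True)
        return ImputedDataset(frame, ds.tau, audit, {1: fit1, 2: fit2})

    def fit_transform(self, ds: CrossoverDataset, y=None) -> ImputedDataset:
        result = self.transform(ds)
        self.period1_fit_ = result.fits.get(1)
        self.period2_fit_ = result.fits.get(2)
        return result


# -- functional wrappers ----------------------------------------------------


def impute_period1(ds: CrossoverDataset, cfg: ImputationConfig | None = None
                   ) -> CrossoverDataset:
    """Complete censored period-1 outcomes; period 2 left untouched."""
    cfg = cfg or ImputationConfig()
    use_age = _resolve_use_age(ds, cfg)
    frame, audit, fit = _impute_period(ds.to_frame(), 1, cfg, use_age)
    return ImputedDataset(frame, ds.tau, audit, {1: fit})


def impute_period2(ds: CrossoverDataset, cfg: ImputationConfig | None = None
                   ) -> ImputedDataset:
    """Complete censored period-2 outcomes (period 1 must be complete)."""
    cfg = cfg or ImputationConfig()
    if not ds.to_frame()["delta1"].all():
        raise ValueError("period 1 must be completed before period 2")
    use_age = _resolve_use_age(ds, cfg)
    frame, audit, fit = _impute_period(ds.to_frame(), 2, cfg, use_age)
    prior = ds.audit if isinstance(ds, ImputedDataset) else \
        pd.DataFrame(columns=AUDIT_COLUMNS)
    audit = pd.concat([prior, audit], ignore_index=True)
    fits = dict(getattr(ds, "fits", {}))
    fits[2] = fit
    return ImputedDataset(frame, ds.tau, audit, fits)


def impute_dataset(ds: CrossoverDataset, cfg: ImputationConfig | None = None
                   ) -> ImputedDataset:
    """Sequentially complete both periods (period 1 first, then period 2)."""
    cfg = cfg or ImputationConfig()
    imp = CrossoverImputer(route=cfg.route, family=cfg.family,
                           use_age=cfg.use_age, include_b1=cfg.include_b1,
                           min_events=cfg.min_events,
                           period1_covariates=cfg.period1_covariates,
                           period2_covariates=cfg.period2_covariates)
    return imp.transform(ds)
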