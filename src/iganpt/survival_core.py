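"""Core time-to-event estimators shared by every validation stage.

Thin, contract-enforcing wrappers around lifelines: the Kaplan-Meier
product-limit estimator with exponential-Greenwood (log(-log)-scale) 95%
bands, Cox proportional-hazards fitting with Efron tie handling, and the
risk-group hazard-ratio / trend analysis.  The wrappers add the error
handling the pipeline relies on (empty samples, constant covariates,
monotone-likelihood detection under separation) and expose plain dataclasses
downstream code can serialize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "CoxFit",
    "GroupHazardResult",
    "kaplan_meier",
    "cox_fit",
    "group_hazard_ratios",
]

#: |coefficient| beyond which a Cox fit is treated as monotone-likelihood
#: (divergent) even when the optimizer nominally converged.
_MONOTONE_COEF_LIMIT = 8.0


@dataclass
class SurvivalSample:
    """Follow-up times (months), event indicators and optional covariates."""

    times: np.ndarray
    events: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.size and np.any(self.times <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0/1")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != self.times.size:
                raise ValueError("covariates must have one row per subject")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class KMCurve:
    """Product-limit estimate with pointwise 95% confidence bands."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def _step_value(self, values: np.ndarray, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(values[idx])

    def survival_at(self, t: float) -> float:
        return self._step_value(self.survival, t)

    def risk_at(self, t: float) -> float:
        """Observed risk 1 - S(t)."""
        return 1.0 - self.survival_at(t)

    def risk_ci_at(self, t: float) -> tuple:
        """95% CI for the observed risk at t (from the survival band)."""
        lo = 1.0 - self._step_value(self.ci_upper, t)
        hi = 1.0 - self._step_value(self.ci_lower, t)
        return (lo, hi)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron tie handling)."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    hazard_ratios: pd.DataFrame  # columns: hr, ci_lower, ci_upper
    p_values: pd.Series
    log_partial_likelihood: float
    converged: bool
    monotone_likelihood: bool = False

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance)), index=self.coefficients.index
        )


@dataclass
class GroupHazardResult:
    """Risk-group Cox analysis: indicator HRs vs the low-risk reference plus
    an ordinal-score trend test."""

    fit: CoxFit
    trend_coef: float
    trend_p: float
    reference: str = "low"
    missing_groups: tuple = ()


def kaplan_meier(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and 95% bands on the
    log(-log) scale (bands stay inside [0, 1])."""
    if sample.n == 0:
        raise ValueError("cannot fit Kaplan-Meier on an empty sample")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(sample.times, sample.events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index and sample.times.min() > 0 else kmf.event_table
    times = np.asarray(table.index, dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lower = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    upper = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    return KMCurve(
        times=times,
        survival=surv,
        ci_lower=lower,
        ci_upper=upper,
        n_risk=table["at_risk"].to_numpy(),
        n_event=table["observed"].to_numpy(),
    )


def _check_covariates(cov: pd.DataFrame):
    for col in cov.columns:
        if np.nanstd(cov[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"no variation in covariate {col!r}")


def cox_fit(sample: SurvivalSample) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) via lifelines' Newton
    solver; flags monotone likelihood (separation/divergence) instead of
    failing silently."""
    if sample.covariates is None or sample.covariates.shape[1] == 0:
        raise ValueError("cox_fit requires covariates")
    if sample.n_events < 1:
        raise ValueError("cox_fit requires at least one event")
    _check_covariates(sample.covariates)
    df = sample.covariates.copy()
    df["_duration"] = sample.times
    df["_event"] = sample.events
    cph = CoxPHFitter()
    converged = True
    monotone = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit_options = {"precision": 1e-9, "max_steps": 100}
        try:
            cph.fit(df, duration_col="_duration", event_col="_event",
                    fit_options=fit_options)
        except ConvergenceError:
            monotone = True
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_duration", event_col="_event",
                        fit_options=fit_options)
    for w in caught:
        msg = str(w.message).lower()
        if "convergence" in msg or "separation" in msg or "variance" in msg:
            monotone = True
    params = cph.params_
    if np.max(np.abs(params.to_numpy())) > _MONOTONE_COEF_LIMIT:
        monotone = True
    se = np.sqrt(np.diag(cph.variance_matrix_))
    def _exp(x):
        return np.exp(np.clip(x, -700.0, 700.0))

    hr = pd.DataFrame(
        {
            "hr": _exp(params.to_numpy()),
            "ci_lower": _exp(params.to_numpy() - 1.96 * se),
            "ci_upper": _exp(params.to_numpy() + 1.96 * se),
        },
        index=params.index,
    )
    return CoxFit(
        coefficients=params.copy(),
        covariance=pd.DataFrame(
            cph.variance_matrix_.to_numpy(), index=params.index, columns=params.index
        ),
        hazard_ratios=hr,
        p_values=cph.summary["p"].copy(),
        log_partial_likelihood=float(cph.log_likelihood_),
        converged=converged and not monotone,
        monotone_likelihood=monotone,
    )


def group_hazard_ratios(
    sample: SurvivalSample,
    labels: Sequence[str],
    order: Sequence[str] = ("low", "intermediate", "higher", "highest"),
) -> GroupHazardResult:
    """Cox fit on risk-group indicators (reference = first group present, by
    default 'low') and a trend test from a separate Cox fit on the ordinal
    group score (0, 1, 2, 3), Wald p-value."""
    labels = np.asarray(labels, dtype=object)
    if labels.size != sample.n:
        raise ValueError("labels must have one entry per subject")
    present = [g for g in order if (labels == g).any()]
    missing = tuple(g for g in order if g not in present)
    if len(present) < 2:
        raise ValueError("need at least two risk groups represented")
    if missing:
        warnings.warn(f"risk groups absent from the sample: {missing}", stacklevel=2)
    reference = present[0]
    indicators = pd.DataFrame(
        {g: (labels == g).astype(float) for g in present[1:]}
    )
    fit = cox_fit(SurvivalSample(sample.times, sample.events, indicators))
    score = np.array([order.index(g) for g in labels], dtype=float)
    trend_fit = cox_fit(
        SurvivalSample(sample.times, sample.events, pd.DataFrame({"score": score}))
    )
    return GroupHazardResult(
        fit=fit,
        trend_coef=float(trend_fit.coefficients["score"]),
        trend_p=float(trend_fit.p_values["score"]),
        reference=reference,
        missing_groups=missing,
    )
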