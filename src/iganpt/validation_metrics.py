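"""Discrimination, calibration and model-fit metrics for external validation
of a survival risk prediction model.

Implements the battery used to judge the IIgAN-PT on a validation cohort:

* :func:`chambless_c` -- time-dependent C-statistic (AUC) at a fixed horizon
  for censored data, built from Kaplan-Meier event-membership probabilities
  (Chambless-type estimator).  Equals plain pairwise concordance when no one
  is censored before the horizon.
* :func:`calibration_slope` -- the Cox coefficient of the linear predictor
  refitted on the validation cohort; 1 means the predicted risk spread is
  correct, < 1 means predictions are too extreme.
* :func:`royston_r2d` -- Royston-Sauerbrei D statistic on rank-normalized
  (Blom-scored) LPs and the derived explained variation R^2_D.
* :func:`ici` -- Integrated Calibration Index at a horizon: mean absolute
  difference between predicted risk and a smoothed observed risk obtained
  from a Cox model on a restricted cubic spline of cll(predicted).
* :func:`decile_calibration` / :func:`group_risk_comparison` -- grouped
  predicted-vs-observed (Kaplan-Meier) risk tables for calibration plots and
  risk-group bar charts.

All horizons are in months; the study's evaluation horizon is 60 months
(the 5-year risk, matching the cohort's median follow-up).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .survival_core import SurvivalSample, kaplan_meier, cox_fit

__all__ = [
    "ValidationReport",
    "RoystonD",
    "chambless_c",
    "calibration_slope",
    "royston_r2d",
    "r2d_from_d",
    "ici",
    "decile_calibration",
    "group_risk_comparison",
]

#: Royston-Sauerbrei scaling constant kappa = sqrt(8 / pi).
KAPPA = math.sqrt(8.0 / math.pi)

_RCS_QUANTILES = {3: (0.10, 0.50, 0.90), 4: (0.05, 0.35, 0.65, 0.95),
                  5: (0.05, 0.275, 0.50, 0.725, 0.95)}


class RoystonD(NamedTuple):
    d: float
    r2d: float
    se: float


@dataclass
class ValidationReport:
    """Everything one external-validation scenario produces."""

    scenario_id: str
    model_id: str
    variant: str
    horizon_months: float
    n: int
    n_events: int
    c_statistic: float
    calibration_slope: float
    ici: float
    d_statistic: float
    r2d: float
    decile_table: pd.DataFrame
    group_table: pd.DataFrame
    group_hazard_ratios: pd.DataFrame
    trend_p: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("decile_table", "group_table", "group_hazard_ratios"):
            d[key] = getattr(self, key).to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# discrimination


def _event_membership_probabilities(
    sample: SurvivalSample, horizon_months: float
) -> np.ndarray:
    """P(event by horizon | observed data) per subject, from the overall KM.

    1 for observed events at or before the horizon, 0 for subjects observed
    beyond the horizon, and the conditional KM probability
    ``1 - S(h) / S(c)`` for subjects censored at ``c <= h``.
    """
    km = kaplan_meier(sample)
    s_h = km.survival_at(horizon_months)
    p = np.zeros(sample.n)
    for i in range(sample.n):
        t, e = sample.times[i], sample.events[i]
        if t > horizon_months:
            p[i] = 0.0
        elif e == 1:
            p[i] = 1.0
        else:
            s_c = km.survival_at(t)
            p[i] = 0.0 if s_c <= 0 else 1.0 - s_h / s_c
    return p


def chambless_c(
    lps: Sequence[float], sample: SurvivalSample, horizon_months: float = 60.0
) -> float:
    """Time-dependent AUC at the horizon for censored survival data.

    Each subject contributes as a case with Kaplan-Meier-derived probability
    ``p_i`` of having the event by the horizon and as a control with
    probability ``1 - p_i``; the C-statistic is the probability-weighted
    proportion of marker-concordant case/control pairs (ties count 1/2).
    Equals 0.5 when the marker carries no information and exhaustive pairwise
    concordance when follow-up is complete through the horizon.
    """
    lps = np.asarray(lps, dtype=float)
    if lps.size != sample.n:
        raise ValueError("lps must have one value per subject")
    if horizon_months > sample.times.max():
        raise ValueError("horizon exceeds the maximum follow-up time")
    if not ((sample.events == 1) & (sample.times <= horizon_months)).any():
        raise ValueError("no events observed before the horizon")
    p = _event_membership_probabilities(sample, horizon_months)
    q = 1.0 - p
    order = np.argsort(lps, kind="mergesort")
    x, ps, qs = lps[order], p[order], q[order]
    # collapse to tie groups of the marker
    _, starts = np.unique(x, return_index=True)
    bounds = np.append(starts, x.size)
    num = 0.0
    p_above = ps.sum()
    for g in range(len(starts)):
        lo, hi = bounds[g], bounds[g + 1]
        pg, qg = ps[lo:hi], qs[lo:hi]
        p_above -= pg.sum()
        # controls in this tie group vs cases with strictly larger marker
        num += qg.sum() * p_above
        # within-group ties count 1/2 (excluding self-pairs)
        num += 0.5 * (pg.sum() * qg.sum() - float(np.dot(pg, qg)))
    den = p.sum() * q.sum() - float(np.dot(p, q))
    if den <= 0:
        raise ValueError("degenerate sample: no case/control pairs at the horizon")
    return float(num / den)


# ---------------------------------------------------------------------------
# calibration slope and model fit


def calibration_slope(lps: Sequence[float], sample: SurvivalSample) -> float:
    """Cox coefficient of the linear predictor as the sole covariate."""
    lps = np.asarray(lps, dtype=float)
    fit = cox_fit(
        SurvivalSample(sample.times, sample.events, pd.DataFrame({"lp": lps}))
    )
    return float(fit.coefficients["lp"])


def r2d_from_d(d: float) -> float:
    """Explained variation R^2_D implied by a D statistic."""
    z = d * d / (KAPPA * KAPPA)
    return z / (math.pi ** 2 / 6.0 + z)


def royston_r2d(lps: Sequence[float], sample: SurvivalSample) -> RoystonD:
    """Royston-Sauerbrei D and R^2_D.

    LPs are replaced by expected standard-normal order statistics (Blom
    scores, constant 3/8) scaled by 1/kappa; D is the Cox coefficient on that
    constructed covariate and R^2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2).
    Rank-based, hence invariant under increasing affine LP transforms.
    """
    lps = np.asarray(lps, dtype=float)
    if sample.n_events < 2:
        raise ValueError("royston_r2d requires at least two events")
    n = lps.size
    ranks = stats.rankdata(lps, method="average")
    blom = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    fit = cox_fit(
        SurvivalSample(sample.times, sample.events, pd.DataFrame({"z": blom / KAPPA}))
    )
    d = float(fit.coefficients["z"])
    return RoystonD(d=d, r2d=r2d_from_d(d), se=float(fit.standard_errors["z"]))


# ---------------------------------------------------------------------------
# ICI


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterization): the linear
    term plus k-2 nonlinear terms, linear beyond the boundary knots."""
    k = knots
    span2 = (k[-1] - k[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(len(k) - 2):
        t = (
            cube(x - k[j])
            - cube(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + cube(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(t / span2)
    return np.column_stack(cols)


def ici(
    predicted_risks: Sequence[float],
    sample: SurvivalSample,
    horizon_months: float = 60.0,
    n_knots: int = 3,
    return_smoothed: bool = False,
):
    """Integrated Calibration Index at the horizon.

    The observed risk is smoothed by regressing survival on a restricted
    cubic spline (default 3 knots at the 10th/50th/90th percentiles) of the
    complementary log-log of the predicted risk in a Cox model; the ICI is
    the mean absolute difference between each subject's smoothed observed
    risk at the horizon and their predicted risk.
    """
    pred = np.asarray(predicted_risks, dtype=float)
    if pred.size != sample.n:
        raise ValueError("predicted_risks must have one value per subject")
    if not ((sample.events == 1) & (sample.times <= horizon_months)).any():
        raise ValueError("no events observed before the horizon")
    if np.any(pred <= 0) or np.any(pred >= 1):
        warnings.warn(
            "predicted risks at 0 or 1 clipped to [1e-6, 1 - 1e-6]", stacklevel=2
        )
        pred = np.clip(pred, 1e-6, 1.0 - 1e-6)
    cll = np.log(-np.log(1.0 - pred))
    if n_knots not in _RCS_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(_RCS_QUANTILES)}")
    knots = np.quantile(cll, _RCS_QUANTILES[n_knots])
    if np.unique(knots).size < len(knots):
        basis = cll[:, None]  # knots collapse: fall back to the linear term
    else:
        basis = _rcs_basis(cll, knots)
    df = pd.DataFrame(basis, columns=[f"s{j}" for j in range(basis.shape[1])])
    if all(np.std(df[c]) == 0 for c in df.columns):
        raise ValueError("no variation in predicted risks")
    df["_duration"] = sample.times
    df["_event"] = sample.events
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_duration", event_col="_event")
    surv = cph.predict_survival_function(
        df.drop(columns=["_duration", "_event"]), times=[horizon_months]
    )
    smoothed = 1.0 - surv.iloc[0].to_numpy()
    value = float(np.mean(np.abs(smoothed - pred)))
    if return_smoothed:
        return value, smoothed
    return value


# ---------------------------------------------------------------------------
# grouped calibration tables


def decile_calibration(
    predicted_risks: Sequence[float],
    lps: Sequence[float],
    sample: SurvivalSample,
    horizon_months: float = 60.0,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Mean predicted vs Kaplan-Meier observed risk by LP decile.

    Groups use the same interpolated-quantile convention as the risk groups
    (cuts at position ``1 + (n - 1) p``); values equal to a cut fall in the
    lower group, so a tie-free n = 100 sample yields ten groups of ten.
    """
    pred = np.asarray(predicted_risks, dtype=float)
    lps = np.asarray(lps, dtype=float)
    if sample.n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} subjects for {n_groups} groups")
    cuts = np.quantile(lps, [i / n_groups for i in range(1, n_groups)])
    grp = np.digitize(lps, cuts, right=True)
    rows = []
    for g in range(n_groups):
        mask = grp == g
        if not mask.any():
            raise ValueError(f"decile group {g + 1} is empty (tied LPs?)")
        km = kaplan_meier(SurvivalSample(sample.times[mask], sample.events[mask]))
        lo, hi = km.risk_ci_at(horizon_months)
        rows.append(
            {
                "decile": g + 1,
                "n": int(mask.sum()),
                "mean_predicted_risk": float(pred[mask].mean()),
                "km_observed_risk": km.risk_at(horizon_months),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)


def group_risk_comparison(
    predicted_risks: Sequence[float],
    labels: Sequence[str],
    sample: SurvivalSample,
    horizon_months: float = 60.0,
    order: Sequence[str] = ("low", "intermediate", "higher", "highest"),
) -> pd.DataFrame:
    """Per risk group: n, events, mean predicted risk and KM observed risk
    (with 95% CI) at the horizon."""
    pred = np.asarray(predicted_risks, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if labels.size != sample.n or pred.size != sample.n:
        raise ValueError("labels/predicted_risks must match the sample size")
    rows = []
    for g in order:
        mask = labels == g
        if not mask.any():
            continue
        km = kaplan_meier(SurvivalSample(sample.times[mask], sample.events[mask]))
        lo, hi = km.risk_ci_at(horizon_months)
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "events": int(sample.events[mask].sum()),
                "mean_predicted_risk": float(pred[mask].mean()),
                "km_observed_risk": km.risk_at(horizon_months),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)
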