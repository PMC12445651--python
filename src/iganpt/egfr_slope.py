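"""Annualized eGFR slopes per risk group from longitudinal eGFR records.

Fits a single linear mixed-effects model (statsmodels MixedLM, REML) with a
random intercept and random slope per subject; fixed effects are time, the
risk-group x time interaction and baseline adjusters (age, sex, MAP, 24-h
urinary protein, MEST scores).  Each group's slope is the fixed time effect
plus its interaction term, with a 95% CI from the fixed-effect covariance.
Slopes are reported in mL/min/1.73 m^2 per year regardless of the time unit
used internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["SlopeEstimate", "fit_egfr_slopes", "DEFAULT_ADJUSTERS"]

DEFAULT_ADJUSTERS = (
    "age_years",
    "sex_male",
    "map_mmHg",
    "proteinuria_g_day",
    "mest_m",
    "mest_e",
    "mest_s",
    "mest_t",
)

_GROUP_ORDER = ("low", "intermediate", "higher", "highest")


@dataclass(frozen=True)
class SlopeEstimate:
    group: str
    slope: float  # mL/min/1.73 m^2 per year
    ci_lower: float
    ci_upper: float
    n_subjects: int
    random_slope_dropped: bool = False


def _prepare(
    long_records: pd.DataFrame,
    grouping: Mapping[str, str],
    covariates: Optional[pd.DataFrame],
    adjusters: Sequence[str],
) -> pd.DataFrame:
    df = long_records.copy()
    required = {"patient_id", "time_months", "egfr"}
    if not required.issubset(df.columns):
        raise ValueError(f"long_records must have columns {sorted(required)}")
    df["patient_id"] = df["patient_id"].astype(str)
    df["risk_group"] = df["patient_id"].map(
        {str(k): v for k, v in grouping.items()}
    )
    if df["risk_group"].isna().any():
        missing = df.loc[df["risk_group"].isna(), "patient_id"].unique()
        raise ValueError(f"grouping does not cover subjects: {missing[:5]}...")
    if covariates is not None and len(adjusters) > 0:
        cov = covariates.copy()
        cov.index = cov.index.astype(str)
        if "sex_male" in adjusters and "sex_male" not in cov.columns and "sex" in cov.columns:
            cov["sex_male"] = (cov["sex"] == "male").astype(float)
        for a in adjusters:
            if a not in cov.columns:
                raise ValueError(f"adjuster {a!r} missing from covariates")
            df[a] = df["patient_id"].map(cov[a]).astype(float)
    return df


def fit_egfr_slopes(
    long_records: pd.DataFrame,
    grouping: Mapping[str, str],
    covariates: Optional[pd.DataFrame] = None,
    adjusters: Sequence[str] = (),
    reml: bool = True,
    time_unit_months: float = 12.0,
) -> list:
    """Per-risk-group annualized eGFR slopes from a linear mixed model.

    Parameters
    ----------
    long_records
        Long-format eGFR data: columns ``patient_id``, ``time_months``
        (relative to biopsy), ``egfr``.
    grouping
        ``patient_id -> risk-group label`` (see
        :func:`iganpt.risk_engine.assign_risk_groups`).
    covariates
        Baseline adjusters indexed by ``patient_id``; required when
        ``adjusters`` is non-empty.  A ``sex`` column is converted to
        ``sex_male`` automatically.
    adjusters
        Fixed-effect adjuster column names (e.g. ``DEFAULT_ADJUSTERS``).
    time_unit_months
        Internal time unit of the fit; slopes are always rescaled to
        per-year.  Fitting in months (1.0) and in years (12.0) agree up to
        numerical tolerance.

    Subjects with fewer than 2 observations are dropped with a warning;
    fewer than half the subjects having >= 3 observations is an error.  A
    singular random-effect covariance triggers a refit with a random
    intercept only, flagged on every returned estimate.
    """
    df = _prepare(long_records, grouping, covariates, adjusters)
    counts = df.groupby("patient_id")["egfr"].size()
    few = counts[counts < 2].index
    if len(few) > 0:
        warnings.warn(
            f"dropping {len(few)} subject(s) with fewer than 2 eGFR observations",
            stacklevel=2,
        )
        df = df[~df["patient_id"].isin(few)]
    counts = df.groupby("patient_id")["egfr"].size()
    if counts.empty:
        raise ValueError("no subjects with >= 2 eGFR observations")
    if (counts >= 3).mean() < 0.5:
        raise ValueError("fewer than half the subjects have >= 3 eGFR observations")

    df = df.reset_index(drop=True)
    df["t"] = df["time_months"] / float(time_unit_months)
    present = [g for g in _GROUP_ORDER if (df["risk_group"] == g).any()]
    ref = present[0]
    df["risk_group"] = pd.Categorical(df["risk_group"], categories=present)

    rhs = [f"t * C(risk_group, Treatment(reference='{ref}'))"] + list(adjusters)
    formula = "egfr ~ " + " + ".join(rhs)

    dropped_slope = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["patient_id"], re_formula="~t")
        try:
            res = model.fit(reml=reml)
            singular = (
                not np.all(np.isfinite(res.cov_re.to_numpy()))
                or np.linalg.eigvalsh(res.cov_re.to_numpy()).min() <= 1e-10
            )
        except (np.linalg.LinAlgError, ValueError):
            res, singular = None, True
        if res is None or singular:
            dropped_slope = True
            model = smf.mixedlm(formula, df, groups=df["patient_id"], re_formula="1")
            res = model.fit(reml=reml)

    params = res.params
    cov = res.cov_params()
    scale = 12.0 / float(time_unit_months)  # convert to per-year

    def interaction_name(group: str) -> str:
        return f"t:C(risk_group, Treatment(reference='{ref}'))[T.{group}]"

    out = []
    for g in present:
        names = ["t"] if g == ref else ["t", interaction_name(g)]
        slope = sum(params[n] for n in names) * scale
        var = sum(cov.loc[a, b] for a in names for b in names) * scale**2
        se = float(np.sqrt(max(var, 0.0)))
        n_subj = int((df.drop_duplicates("patient_id")["risk_group"] == g).sum())
        out.append(
            SlopeEstimate(
                group=g,
                slope=float(slope),
                ci_lower=float(slope - 1.96 * se),
                ci_upper=float(slope + 1.96 * se),
                n_subjects=n_subj,
                random_slope_dropped=dropped_slope,
            )
        )
    return out
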