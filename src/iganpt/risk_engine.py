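"""Risk engine for the International IgA Nephropathy Prediction Tool (IIgAN-PT).

The IIgAN-PT is a Cox-model-based calculator of the risk of a composite
kidney outcome (50% decline in eGFR, or end-stage kidney disease) within
80 months, from clinicopathological data at biopsy (the "At-biopsy" model)
or at a 1-2 year post-biopsy landmark (the "Post-biopsy" model).  This
module evaluates the tool for individual patients:

* ``compute_linear_predictor`` -- the weighted sum of centered, transformed
  covariates (proteinuria, MAP, eGFR, age, MEST scores, medication flags and,
  in the "with race" variants, race indicators);
* ``predict_risk`` -- absolute risk at a horizon from the tool's baseline
  survival function, including the piecewise hazard applied to Chinese race
  at 36 months (a proportional-hazards violation in the published tool);
* ``remap_novel_drugs`` -- the study's recoding of novel therapies into the
  tool's historical medication variables (ERA/SGLT2i as RAS blockade;
  Nefecon, hydroxychloroquine and telitacicept as immunosuppression);
* ``assign_risk_groups`` -- the four LP-percentile risk groups
  (<16th, 16th-50th, 50th-84th, >84th);
* ``ckd_epi_egfr`` -- the 2009 CKD-EPI creatinine equation.

Model coefficients are never hard-coded: they are consumed as
:class:`CoefficientSet` objects loaded from JSON files (see
:func:`iganpt.io.load_coefficients`).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CohortRecord",
    "CoefficientSet",
    "CoefficientTerm",
    "RacePiecewise",
    "RiskPrediction",
    "RiskGrouping",
    "GROUP_LABELS",
    "GROUP_CUT_PERCENTILES",
    "NOVEL_DRUGS",
    "compute_linear_predictor",
    "predict_risk",
    "predict_cohort",
    "remap_novel_drugs",
    "assign_risk_groups",
    "ckd_epi_egfr",
]

RACES = ("chinese", "japanese", "white", "other")
SEXES = ("male", "female")

#: Canonical novel-therapy names.  ERA = endothelin receptor antagonist,
#: SGLT2i = sodium-glucose cotransporter-2 inhibitor, HCQ = hydroxychloroquine.
NOVEL_DRUGS = ("ERA", "SGLT2i", "Nefecon", "HCQ", "telitacicept")

_DRUG_ALIASES = {
    "era": "ERA",
    "eras": "ERA",
    "sglt2i": "SGLT2i",
    "sglt2": "SGLT2i",
    "nefecon": "Nefecon",
    "hcq": "HCQ",
    "hydroxychloroquine": "HCQ",
    "telitacicept": "telitacicept",
}

#: Drugs entered into the tool as renin-angiotensin system blockade /
#: as immunosuppression under the study's remapping.
_REMAP_TO_RASB = frozenset({"ERA", "SGLT2i"})
_REMAP_TO_IS = frozenset({"Nefecon", "HCQ", "telitacicept"})

GROUP_LABELS = ("low", "intermediate", "higher", "highest")
GROUP_CUT_PERCENTILES = (16, 50, 84)

#: Covariate names a CoefficientSet term may reference.
KNOWN_COVARIATES = frozenset(
    {
        "age_years",
        "sex",
        "egfr",
        "map_mmHg",
        "proteinuria_g_day",
        "mest_m",
        "mest_e",
        "mest_s",
        "mest_t",
        "race",
        "rasb_use",
        "is_use",
    }
)


def normalize_drug_name(name: str) -> str:
    """Map a drug name (case-insensitive, common aliases) to its canonical form."""
    key = str(name).strip().lower()
    if key not in _DRUG_ALIASES:
        raise ValueError(
            f"unknown novel drug {name!r}; expected one of {NOVEL_DRUGS}"
        )
    return _DRUG_ALIASES[key]


@dataclass(frozen=True)
class CohortRecord:
    """One patient: covariates at the model's time origin, treatment flags and
    the composite-outcome follow-up.

    Times are in months; eGFR in mL/min/1.73 m^2; proteinuria in g/day;
    MAP in mmHg.  ``event = 1`` means the composite outcome (50% eGFR decline
    or ESKD) occurred at ``followup_months``; otherwise follow-up was censored
    there.  ``egfr_series`` optionally carries longitudinal eGFR measurements
    as ``(time_months, egfr)`` pairs for slope analyses.
    """

    patient_id: str
    age_years: float
    sex: str
    egfr: float
    map_mmHg: float
    proteinuria_g_day: float
    mest_m: int
    mest_e: int
    mest_s: int
    mest_t: int
    race: str = "chinese"
    rasb_use: bool = False
    is_use: bool = False
    novel_drugs: frozenset = frozenset()
    followup_months: float = 60.0
    event: int = 0
    egfr_series: Optional[tuple] = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.race not in RACES:
            raise ValueError(f"race must be one of {RACES}, got {self.race!r}")
        if not self.egfr > 0:
            raise ValueError("egfr must be > 0")
        if self.proteinuria_g_day < 0:
            raise ValueError("proteinuria_g_day must be >= 0")
        if not self.followup_months > 0:
            raise ValueError("followup_months must be > 0")
        for name in ("mest_m", "mest_e", "mest_s"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.mest_t not in (0, 1, 2):
            raise ValueError("mest_t must be 0, 1 or 2")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        drugs = frozenset(normalize_drug_name(d) for d in self.novel_drugs)
        object.__setattr__(self, "novel_drugs", drugs)
        if self.egfr_series is not None:
            object.__setattr__(
                self,
                "egfr_series",
                tuple((float(t), float(g)) for t, g in self.egfr_series),
            )


@dataclass(frozen=True)
class CoefficientTerm:
    """One additive term of the linear predictor:
    ``coef * (transform(covariate) - center)``."""

    covariate: str
    transform: str
    center: float
    coef: float


@dataclass(frozen=True)
class RacePiecewise:
    """Piecewise (time-varying) log-hazard for one race: ``beta_early`` applies
    up to ``cutpoint_months`` after the time origin, ``beta_late`` afterwards."""

    race: str
    cutpoint_months: float
    beta_early: float
    beta_late: float


@dataclass(frozen=True)
class CoefficientSet:
    """A named, versioned container of IIgAN-PT model constants: LP terms,
    the optional piecewise race effect, and the baseline survival function
    S0(t) tabulated in months."""

    name: str
    model_id: str
    variant: str
    terms: tuple
    baseline_survival: tuple
    race_piecewise: Optional[RacePiecewise] = None
    provenance: str = ""

    def __post_init__(self):
        if self.model_id not in ("at_biopsy", "post_biopsy"):
            raise ValueError("model_id must be 'at_biopsy' or 'post_biopsy'")
        if self.variant not in ("with_race", "without_race"):
            raise ValueError("variant must be 'with_race' or 'without_race'")
        terms = tuple(
            t if isinstance(t, CoefficientTerm) else CoefficientTerm(**t)
            for t in self.terms
        )
        object.__setattr__(self, "terms", terms)
        for t in terms:
            if t.covariate not in KNOWN_COVARIATES:
                raise ValueError(f"unknown covariate {t.covariate!r} in terms")
        has_race_terms = any(t.covariate == "race" for t in terms)
        if self.race_piecewise is not None and not isinstance(
            self.race_piecewise, RacePiecewise
        ):
            object.__setattr__(
                self, "race_piecewise", RacePiecewise(**self.race_piecewise)
            )
        if self.variant == "without_race" and (
            has_race_terms or self.race_piecewise is not None
        ):
            raise ValueError("without_race variant must not carry race terms")
        if self.variant == "with_race" and not (
            has_race_terms or self.race_piecewise is not None
        ):
            raise ValueError("with_race variant must carry race terms")
        bs = tuple((float(t), float(s)) for t, s in self.baseline_survival)
        if len(bs) < 2:
            raise ValueError("baseline_survival needs at least two points")
        times = np.array([t for t, _ in bs])
        s0 = np.array([s for _, s in bs])
        if np.any(np.diff(times) <= 0):
            raise ValueError("baseline_survival times must be strictly increasing")
        if np.any(s0 <= 0) or np.any(s0 > 1):
            raise ValueError("baseline survival values must lie in (0, 1]")
        if np.any(np.diff(s0) > 0):
            raise ValueError("baseline survival must be non-increasing")
        object.__setattr__(self, "baseline_survival", bs)

    # -- baseline hazard ---------------------------------------------------
    @property
    def max_horizon_months(self) -> float:
        return self.baseline_survival[-1][0]

    def baseline_cumulative_hazard(self, t_months: float) -> float:
        """H0(t) = -ln S0(t), linearly interpolated between tabulated times.

        S0(0) = 1 is assumed when the table does not start at zero.
        """
        times = [pt for pt, _ in self.baseline_survival]
        haz = [-math.log(s) for _, s in self.baseline_survival]
        if times[0] > 0:
            times = [0.0] + times
            haz = [0.0] + haz
        if t_months < times[0] or t_months > times[-1]:
            raise ValueError(
                f"time {t_months} months outside the baseline survival span "
                f"[{times[0]}, {times[-1]}]"
            )
        return float(np.interp(t_months, times, haz))

    def baseline_survival_at(self, t_months: float) -> float:
        return math.exp(-self.baseline_cumulative_hazard(t_months))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "model_id": self.model_id,
            "variant": self.variant,
            "provenance": self.provenance,
            "terms": [dataclasses.asdict(t) for t in self.terms],
            "baseline_survival": [list(p) for p in self.baseline_survival],
        }
        if self.race_piecewise is not None:
            d["race_piecewise"] = dataclasses.asdict(self.race_piecewise)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        return cls(
            name=d.get("name", "unnamed"),
            model_id=d["model_id"],
            variant=d["variant"],
            terms=tuple(CoefficientTerm(**t) for t in d["terms"]),
            baseline_survival=tuple(tuple(p) for p in d["baseline_survival"]),
            race_piecewise=(
                RacePiecewise(**d["race_piecewise"])
                if d.get("race_piecewise")
                else None
            ),
            provenance=d.get("provenance", ""),
        )


@dataclass(frozen=True)
class RiskPrediction:
    patient_id: str
    linear_predictor: float
    horizon_months: float
    risk: float


@dataclass(frozen=True)
class RiskGrouping:
    """Assignment of patients to the four LP-percentile risk groups."""

    cut_values: tuple  # LP values at the 16th/50th/84th percentiles
    assignments: Mapping[str, str]  # patient_id -> label
    labels: tuple = GROUP_LABELS

    @property
    def group_counts(self) -> dict:
        counts = {g: 0 for g in self.labels}
        for lab in self.assignments.values():
            counts[lab] += 1
        return counts


# ---------------------------------------------------------------------------
# transforms


def _transform(spec: str, value, covariate: str) -> float:
    if spec == "identity":
        return float(value)
    if spec == "log":
        v = float(value)
        if v <= 0:
            raise ValueError(
                f"log transform of non-positive value {v} for covariate {covariate!r}"
            )
        return math.log(v)
    if spec == "bool":
        return 1.0 if value else 0.0
    if spec.startswith("eq:"):
        return 1.0 if str(value) == spec[3:] else 0.0
    raise ValueError(f"unknown transform_spec {spec!r} for covariate {covariate!r}")


def _covariate_value(record: CohortRecord, name: str):
    value = getattr(record, name, None)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing required covariate {name!r} for {record.patient_id!r}")
    return value


# ---------------------------------------------------------------------------
# operations


def compute_linear_predictor(record: CohortRecord, coeffs: CoefficientSet) -> float:
    """Linear predictor: sum over terms of ``coef * (transform(x) - center)``.

    Time-constant race terms are part of the sum; the piecewise race effect
    (a time-varying hazard) is applied inside :func:`predict_risk` instead.
    """
    lp = 0.0
    for term in coeffs.terms:
        value = _covariate_value(record, term.covariate)
        lp += term.coef * (_transform(term.transform, value, term.covariate) - term.center)
    return lp


def predict_risk(
    lp: float,
    record: CohortRecord,
    coeffs: CoefficientSet,
    horizon_months: float = 60.0,
) -> float:
    """Absolute risk of the composite outcome by ``horizon_months``.

    Without a piecewise race effect the usual Cox survival transform applies::

        risk = 1 - S0(h) ** exp(lp)

    When the set carries a piecewise effect that is active for the record's
    race, the cumulative hazard is accumulated segment-wise with the early
    coefficient up to the cutpoint and the late coefficient beyond it::

        risk = 1 - exp(-[H0(min(h, c)) * e^(lp + b_early)
                         + max(0, H0(h) - H0(c)) * e^(lp + b_late)])
    """
    if not math.isfinite(lp):
        raise ValueError("linear predictor must be finite")
    pw = coeffs.race_piecewise
    if pw is not None and record.race == pw.race:
        h_cut = coeffs.baseline_cumulative_hazard(
            min(horizon_months, pw.cutpoint_months)
        )
        h_total = coeffs.baseline_cumulative_hazard(horizon_months)
        h_cut_full = coeffs.baseline_cumulative_hazard(pw.cutpoint_months)
        late = max(0.0, h_total - h_cut_full)
        cum = h_cut * math.exp(lp + pw.beta_early) + late * math.exp(lp + pw.beta_late)
        return 1.0 - math.exp(-cum)
    s0 = coeffs.baseline_survival_at(horizon_months)
    return 1.0 - s0 ** math.exp(lp)


def predict_cohort(
    cohort: Iterable[CohortRecord],
    coeffs: CoefficientSet,
    horizon_months: float = 60.0,
) -> list:
    """Vector convenience: LP and risk for every record."""
    out = []
    for rec in cohort:
        lp = compute_linear_predictor(rec, coeffs)
        out.append(
            RiskPrediction(
                patient_id=rec.patient_id,
                linear_predictor=lp,
                horizon_months=horizon_months,
                risk=predict_risk(lp, rec, coeffs, horizon_months),
            )
        )
    return out


def remap_novel_drugs(record: CohortRecord) -> CohortRecord:
    """Recode novel therapies into the tool's historical medication variables.

    ERA or SGLT2i use sets ``rasb_use``; Nefecon, hydroxychloroquine or
    telitacicept use sets ``is_use``.  ``novel_drugs`` itself is unchanged and
    the input record is not mutated.  Idempotent.
    """
    rasb = record.rasb_use or bool(record.novel_drugs & _REMAP_TO_RASB)
    isu = record.is_use or bool(record.novel_drugs & _REMAP_TO_IS)
    return dataclasses.replace(record, rasb_use=rasb, is_use=isu)


def assign_risk_groups(
    lps: Sequence[float],
    patient_ids: Optional[Sequence[str]] = None,
) -> RiskGrouping:
    """Split patients into the tool's four risk groups on LP percentiles.

    Quantiles use linear interpolation at position ``1 + (n - 1) p`` on the
    order statistics.  Boundary rules: low if LP < Q16; intermediate if
    Q16 <= LP <= Q50; higher if Q50 < LP <= Q84; highest if LP > Q84.  On
    tie-free samples of sizes 677 and 566 this reproduces the published group
    counts (109/230/229/109 and 91/192/192/91) exactly.
    """
    lps = np.asarray(lps, dtype=float)
    n = lps.size
    if n < 4:
        raise ValueError(f"need at least 4 patients to form risk groups, got {n}")
    if not np.all(np.isfinite(lps)):
        raise ValueError("linear predictors must be finite")
    if np.all(lps == lps[0]):
        raise ValueError("all linear predictors identical: degenerate grouping")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    q16, q50, q84 = np.quantile(lps, [p / 100 for p in GROUP_CUT_PERCENTILES])
    if np.isin(lps, [q16, q50, q84]).sum() > 1 or np.unique(lps).size < n:
        warnings.warn(
            "ties among linear predictors; group counts may deviate from the "
            "tie-free percentile ideal",
            stacklevel=2,
        )
    labels = np.where(
        lps < q16,
        "low",
        np.where(lps <= q50, "intermediate", np.where(lps <= q84, "higher", "highest")),
    )
    assignments = dict(zip((str(p) for p in patient_ids), labels.tolist()))
    return RiskGrouping(cut_values=(float(q16), float(q50), float(q84)),
                        assignments=assignments)


def group_labels_for(lps: Sequence[float], grouping: RiskGrouping) -> np.ndarray:
    """Labels for ``lps`` under an existing grouping's cutpoints."""
    lps = np.asarray(lps, dtype=float)
    q16, q50, q84 = grouping.cut_values
    return np.where(
        lps < q16,
        "low",
        np.where(lps <= q50, "intermediate", np.where(lps <= q84, "higher", "highest")),
    )


# 2009 CKD-EPI creatinine equation constants, as tabulated in the original
# publication (sex-specific leading constants; no race coefficient).
_CKD_EPI = {
    "female": (144.0, 0.7, -0.329),
    "male": (141.0, 0.9, -0.411),
}


def ckd_epi_egfr(scr_umol_L: float, age_years: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine in umol/L.

    2009 CKD-EPI creatinine equation without the race coefficient; creatinine
    is converted to mg/dL by dividing by 88.4.
    """
    if scr_umol_L <= 0 or age_years <= 0:
        raise ValueError("serum creatinine and age must be positive")
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    base, kappa, alpha = _CKD_EPI[sex]
    ratio = (scr_umol_L / 88.4) / kappa
    return base * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age_years
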