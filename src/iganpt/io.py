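"""Reading and writing the pipeline's text formats.

Cohorts travel as one-row-per-patient CSV (novel drugs ';'-joined in a
single column), longitudinal eGFR as long-format CSV, and coefficient sets
as JSON.  Shipped coefficient sets are addressed by name; anything else by
path.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .risk_engine import CohortRecord, CoefficientSet
from .synthetic_cohort import cohort_to_frame

__all__ = [
    "load_coefficients",
    "builtin_coefficient_sets",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_egfr_long_csv",
]

_COHORT_COLUMNS = [
    "patient_id",
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
    "novel_drugs",
    "followup_months",
    "event",
]


def builtin_coefficient_sets() -> list:
    """Names of the coefficient sets shipped with the package."""
    root = resources.files("iganpt").joinpath("data")
    return sorted(p.name[: -len(".json")] for p in root.iterdir() if p.name.endswith(".json"))


def load_coefficients(name_or_path: Union[str, Path]) -> CoefficientSet:
    """Load a :class:`CoefficientSet` from a JSON file or a builtin name."""
    path = Path(name_or_path)
    if path.suffix == ".json" and path.exists():
        text = path.read_text()
    else:
        res = resources.files("iganpt").joinpath("data", f"{name_or_path}.json")
        if not res.is_file():
            raise FileNotFoundError(
                f"no coefficient file {name_or_path!r}; builtin sets: "
                f"{builtin_coefficient_sets()}"
            )
        text = res.read_text()
    return CoefficientSet.from_dict(json.loads(text))


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_cohort_csv(path: Union[str, Path]) -> list:
    """Read a cohort CSV into a list of :class:`CohortRecord`."""
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - {"novel_drugs"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        drugs = row.get("novel_drugs", "")
        if pd.isna(drugs):
            drugs = ""
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                egfr=float(row["egfr"]),
                map_mmHg=float(row["map_mmHg"]),
                proteinuria_g_day=float(row["proteinuria_g_day"]),
                mest_m=int(row["mest_m"]),
                mest_e=int(row["mest_e"]),
                mest_s=int(row["mest_s"]),
                mest_t=int(row["mest_t"]),
                race=str(row["race"]),
                rasb_use=_parse_bool(row["rasb_use"]),
                is_use=_parse_bool(row["is_use"]),
                novel_drugs=frozenset(d for d in str(drugs).split(";") if d),
                followup_months=float(row["followup_months"]),
                event=int(row["event"]),
            )
        )
    return records


def write_cohort_csv(cohort: Iterable[CohortRecord], path: Union[str, Path]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_egfr_long_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Long-format eGFR records: patient_id, time_months, egfr."""
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "egfr"}
    if not required.issubset(df.columns):
        raise ValueError(f"eGFR CSV must have columns {sorted(required)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
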