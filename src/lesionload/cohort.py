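"""Cohort table: the per-patient statistical substrate.

The packaged reference cohort transcribes the published characteristics
table of 50 chronic left-hemisphere stroke patients with aphasia:
demographics, speech fluency (Words/min and CIUs/min, where a Correct
Information Unit is an intelligible, accurate, relevant and informative
word), naming (15-item Boston Naming Test short form, 0..15), total
lesion volume, and lesion loads against five canonical maps (AF, fGM,
combined AF+fGM, EMC, UF), all in cc.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "LOAD_COLUMNS",
    "OUTCOME_COLUMNS",
    "CohortTable",
    "load_cohort",
    "load_reference_cohort",
    "validate_cohort",
]

#: columns every cohort CSV must provide (the analysis substrate)
REQUIRED_COLUMNS = [
    "patient_id",
    "gender",
    "age_years",
    "months_post_stroke",
    "bnt",
    "words_per_min",
    "cius_per_min",
    "lesion_volume_cc",
    "af_ll_cc",
    "fgm_ll_cc",
    "af_fgm_ll_cc",
    "emc_ll_cc",
    "uf_ll_cc",
]

#: neuropsych descriptors that may be missing ("N/A") and never block analyses
OPTIONAL_COLUMNS = ["ravens", "word_discrimination_pct", "commands_pct", "word_repetition_pct"]

LOAD_COLUMNS = ["af_ll_cc", "fgm_ll_cc", "af_fgm_ll_cc", "emc_ll_cc", "uf_ll_cc"]
OUTCOME_COLUMNS = ["cius_per_min", "words_per_min", "bnt"]

_NUMERIC_REQUIRED = [c for c in REQUIRED_COLUMNS if c not in ("patient_id", "gender")]


@dataclass(frozen=True)
class CohortTable:
    """A validated cohort as a pandas DataFrame plus convenience accessors."""

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def record(self, patient_id: str) -> pd.Series:
        hit = self.df[self.df["patient_id"] == str(patient_id)]
        if hit.empty:
            raise KeyError(f"no patient {patient_id!r} in cohort")
        return hit.iloc[0]


def load_cohort(path: str | Path) -> CohortTable:
    """Load a cohort CSV (UTF-8, one header row, "N/A" = missing).

    Required outcome/load columns must be present and numeric; optional
    neuropsych columns may be missing or "N/A".
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"patient_id": str}, na_values=["N/A"], keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty or has no header") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns: {missing}")
    for col in _NUMERIC_REQUIRED:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad) > 0:
            raise SchemaError(
                f"{path}: non-numeric value {raw.loc[bad[0], col]!r} "
                f"in required column {col!r}, row {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(raw.index[coerced.isna()][0]) + 2
            raise SchemaError(f"{path}: missing value in required column {col!r}, row {row}")
        raw[col] = coerced
    for col in OPTIONAL_COLUMNS:
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return CohortTable(raw.reset_index(drop=True))


def load_reference_cohort() -> CohortTable:
    """The packaged 50-patient reference cohort."""
    with resources.as_file(resources.files("lesionload.data") / "table1.csv") as p:
        return load_cohort(p)


def validate_cohort(cohort: CohortTable) -> list[str]:
    """Check per-record invariants; return one message per violation.

    Rules: unique patient ids; CIUs/min <= Words/min (a CIU is a counted
    word); BNT in 0..15; lesion volume > 0; each single-map lesion load
    in [0, lesion volume]. The combined AF+fGM load is only required to
    be <= af_ll + fgm_ll + rounding slack, since the combined map caps
    probabilities at 1.
    """
    df = cohort.df
    out: list[str] = []
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
    for d in dupes:
        out.append(f"duplicate patient_id {d!r}")
    for _, r in df.iterrows():
        pid = r["patient_id"]
        if r["cius_per_min"] > r["words_per_min"]:
            out.append(f"patient {pid}: cius_per_min {r['cius_per_min']} > words_per_min {r['words_per_min']}")
        if not (0 <= r["bnt"] <= 15 and float(r["bnt"]).is_integer()):
            out.append(f"patient {pid}: bnt {r['bnt']} outside 0..15")
        if not r["lesion_volume_cc"] > 0:
            out.append(f"patient {pid}: lesion_volume_cc {r['lesion_volume_cc']} not > 0")
        for col in ("af_ll_cc", "fgm_ll_cc", "emc_ll_cc", "uf_ll_cc"):
            if not 0 <= r[col] <= r["lesion_volume_cc"]:
                out.append(
                    f"patient {pid}: {col} {r[col]} outside [0, lesion volume {r['lesion_volume_cc']}]"
                )
        if r["af_fgm_ll_cc"] < 0:
            out.append(f"patient {pid}: af_fgm_ll_cc {r['af_fgm_ll_cc']} negative")
        if r["months_post_stroke"] < 0 or r["age_years"] <= 0:
            out.append(f"patient {pid}: implausible age/months ({r['age_years']}, {r['months_post_stroke']})")
    return out
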