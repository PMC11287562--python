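"""Cohort containers and CSV interchange.

One row per woman.  Event ages (breast cancer, death, bilateral
risk-reducing mastectomy, RRSO) are optional; absent events are empty
cells in CSV and ``None``/NaN in memory.  QRF levels are stored in wide
columns named ``qrf_<factor>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: CSV columns in canonical order (QRF columns are appended dynamically).
BASE_COLUMNS = [
    "id", "country", "baseline_age", "gene", "prs_raw", "prs_z", "fh_score",
    "bc_age", "bc_is_dcis", "death_age", "mastectomy_age", "rrso_age",
    "last_followup_age", "included_in_subcohort",
]


@dataclass
class RiskFactorProfile:
    """One woman's predictors: PV gene, PRS, QRF levels, FH burden."""

    gene: str
    prs_raw: float
    prs_z: float
    qrf_levels: dict[str, str] = field(default_factory=dict)
    fh_score: int = 0

    def __post_init__(self) -> None:
        if self.fh_score < 0:
            raise InvalidParameterError("fh_score must be non-negative")


@dataclass
class CohortRecord:
    """Profile plus baseline age, raw event history and study metadata."""

    id: str
    country: str
    baseline_age: float
    profile: RiskFactorProfile
    last_followup_age: float
    bc_age: float | None = None
    bc_is_dcis: bool = False
    death_age: float | None = None
    mastectomy_age: float | None = None
    rrso_age: float | None = None
    included_in_subcohort: bool = True

    def __post_init__(self) -> None:
        if self.last_followup_age < self.baseline_age:
            raise InvalidParameterError(
                f"record {self.id}: last_followup_age < baseline_age")
        for name in ("bc_age", "death_age", "mastectomy_age", "rrso_age"):
            v = getattr(self, name)
            if v is not None and v < self.baseline_age:
                raise InvalidParameterError(
                    f"record {self.id}: {name} precedes baseline_age")


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records into the canonical wide cohort table."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "country": r.country,
            "baseline_age": r.baseline_age, "gene": r.profile.gene,
            "prs_raw": r.profile.prs_raw, "prs_z": r.profile.prs_z,
            "fh_score": r.profile.fh_score,
            "bc_age": r.bc_age, "bc_is_dcis": r.bc_is_dcis,
            "death_age": r.death_age, "mastectomy_age": r.mastectomy_age,
            "rrso_age": r.rrso_age,
            "last_followup_age": r.last_followup_age,
            "included_in_subcohort": r.included_in_subcohort,
        }
        for f, lvl in r.profile.qrf_levels.items():
            row[f"qrf_{f}"] = lvl
        rows.append(row)
    frame = pd.DataFrame(rows)
    qrf_cols = sorted(c for c in frame.columns if c.startswith("qrf_"))
    return frame[BASE_COLUMNS + qrf_cols]


def frame_to_records(frame: pd.DataFrame) -> list[CohortRecord]:
    qrf_cols = [c for c in frame.columns if c.startswith("qrf_")]

    def _opt(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) \
            else float(v)

    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        profile = RiskFactorProfile(
            gene=d["gene"], prs_raw=float(d["prs_raw"]),
            prs_z=float(d["prs_z"]),
            qrf_levels={c[len("qrf_"):]: d[c] for c in qrf_cols},
            fh_score=int(d["fh_score"]))
        records.append(CohortRecord(
            id=str(d["id"]), country=str(d["country"]),
            baseline_age=float(d["baseline_age"]), profile=profile,
            last_followup_age=float(d["last_followup_age"]),
            bc_age=_opt(d["bc_age"]), bc_is_dcis=bool(d["bc_is_dcis"]),
            death_age=_opt(d["death_age"]),
            mastectomy_age=_opt(d["mastectomy_age"]),
            rrso_age=_opt(d["rrso_age"]),
            included_in_subcohort=bool(d["included_in_subcohort"])))
    return records


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("bc_is_dcis", "included_in_subcohort"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame


def qrf_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c.startswith("qrf_")]
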