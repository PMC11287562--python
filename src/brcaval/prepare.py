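"""Eligibility filters, censoring hierarchy and 5-year outcome derivation.

Follow-up runs from the baseline age to the earliest of: BC diagnosis
(invasive or DCIS), bilateral risk-reducing mastectomy, last follow-up,
death, baseline plus (landmark + horizon) years, or age 80.  Ties are
broken in that listing order (RRSO, when censoring at RRSO is requested,
sits after mastectomy).  Only a BC/DCIS diagnosis that is the earliest
endpoint yields an event; under the DCIS-as-unaffected sensitivity policy
a DCIS diagnosis censors at the diagnosis age instead.

Eligibility requires: younger than 74 at entry; no cancer or bilateral
mastectomy history before baseline; more than 1 year of (censored)
follow-up; complete PRS and QRF data.  The exclusion log records the
first failing rule per woman.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import qrf_columns
from .errors import InvalidParameterError

AGE_LIMIT = 74.0          # must be younger than this at study entry
MAX_AGE = 80.0            # administrative age cap
DEFAULT_LANDMARK = 1.0    # years past entry before risks start
DEFAULT_HORIZON = 5.0     # risk-prediction horizon in years

#: exclusion reason codes, in the order the rules are applied
REASONS = ("age", "prior-event", "follow-up", "missing-data",
           "pre-landmark exit")


def derive_follow_up(baseline_age: float, *, bc_age=None, bc_is_dcis=False,
                     mastectomy_age=None, rrso_age=None, death_age=None,
                     last_followup_age: float,
                     dcis_policy: str = "affected",
                     censor_at_rrso: bool = False,
                     admin_years: float = DEFAULT_LANDMARK + DEFAULT_HORIZON,
                     max_age: float = MAX_AGE) -> tuple[float, str]:
    """Exit age and event type for one woman.

    Returns ``(exit_age, event)`` with ``event`` in {"BC", "censored"}.
    """
    if dcis_policy not in ("affected", "censor"):
        raise InvalidParameterError(f"unknown dcis_policy {dcis_policy!r}")
    inf = np.inf
    candidates = [
        inf if bc_age is None else float(bc_age),
        inf if mastectomy_age is None else float(mastectomy_age),
        inf if (rrso_age is None or not censor_at_rrso) else float(rrso_age),
        float(last_followup_age),
        inf if death_age is None else float(death_age),
        baseline_age + admin_years,
        max_age,
    ]
    k = int(np.argmin(candidates))  # first minimum: listing-order tie-break
    exit_age = candidates[k]
    is_bc = k == 0 and (not bc_is_dcis or dcis_policy == "affected")
    return exit_age, ("BC" if is_bc else "censored")


def derive_follow_up_frame(frame: pd.DataFrame,
                           dcis_policy: str = "affected",
                           censor_at_rrso: bool = False,
                           admin_years: float = DEFAULT_LANDMARK
                           + DEFAULT_HORIZON,
                           max_age: float = MAX_AGE) -> pd.DataFrame:
    """Vectorized :func:`derive_follow_up` over a cohort table."""
    if dcis_policy not in ("affected", "censor"):
        raise InvalidParameterError(f"unknown dcis_policy {dcis_policy!r}")

    def _col(name):
        if name in frame.columns:
            return frame[name].to_numpy(dtype=float)
        return np.full(len(frame), np.nan)

    baseline = frame["baseline_age"].to_numpy(dtype=float)
    rrso = _col("rrso_age") if censor_at_rrso else np.full(len(frame), np.nan)
    cand = np.column_stack([
        _col("bc_age"), _col("mastectomy_age"), rrso,
        frame["last_followup_age"].to_numpy(dtype=float), _col("death_age"),
        baseline + admin_years, np.full(len(frame), max_age)])
    cand = np.where(np.isnan(cand), np.inf, cand)
    k = np.argmin(cand, axis=1)
    exit_age = cand[np.arange(len(frame)), k]
    dcis = frame["bc_is_dcis"].to_numpy(dtype=bool) \
        if "bc_is_dcis" in frame.columns else np.zeros(len(frame), bool)
    is_bc = (k == 0) & (~dcis | (dcis_policy == "affected"))
    reasons = np.array(["bc", "mastectomy", "rrso", "last_followup",
                        "death", "admin", "age80"])
    return pd.DataFrame({
        "exit_age": exit_age,
        "event": np.where(is_bc, "BC", "censored"),
        "exit_reason": reasons[k]}, index=frame.index)


def apply_eligibility(frame: pd.DataFrame,
                      dcis_policy: str = "affected",
                      censor_at_rrso: bool = False,
                      admin_years: float = DEFAULT_LANDMARK + DEFAULT_HORIZON,
                      max_age: float = MAX_AGE
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four eligibility filters.

    Returns the retained rows (with derived ``exit_age``/``event``
    columns) and an exclusion log ``(id, reason)`` naming the first
    failing rule per woman.
    """
    fu = derive_follow_up_frame(frame, dcis_policy, censor_at_rrso,
                                admin_years, max_age)
    baseline = frame["baseline_age"].to_numpy(dtype=float)

    def _before_baseline(col):
        if col not in frame.columns:
            return np.zeros(len(frame), bool)
        v = frame[col].to_numpy(dtype=float)
        return ~np.isnan(v) & (v < baseline)

    missing = frame["prs_z"].isna().to_numpy()
    for col in qrf_columns(frame):
        missing |= frame[col].isna().to_numpy()

    reason = np.full(len(frame), "", dtype=object)
    checks = [
        ("age", baseline >= AGE_LIMIT),
        ("prior-event", _before_baseline("bc_age")
         | _before_baseline("mastectomy_age")),
        ("follow-up",
         (fu["exit_age"].to_numpy() - baseline) <= 1.0),
        ("missing-data", missing),
    ]
    for code, mask in checks:
        reason[(reason == "") & mask] = code
    excluded = reason != ""
    exclusions = pd.DataFrame({"id": frame.loc[excluded, "id"].to_numpy(),
                               "reason": reason[excluded]})
    retained = frame.loc[~excluded].copy()
    retained[["exit_age", "event", "exit_reason"]] = fu.loc[~excluded]
    return retained.reset_index(drop=True), exclusions.reset_index(drop=True)


def classify_outcome(baseline_age: float, exit_age: float, event: str,
                     landmark: float = DEFAULT_LANDMARK,
                     horizon: float = DEFAULT_HORIZON) -> bool:
    """True iff a BC event falls inside the landmarked horizon window."""
    if exit_age <= baseline_age + landmark:
        raise InvalidParameterError(
            "exit at or before the landmark; drop the record upstream "
            "(reason 'pre-landmark exit')")
    return bool(event == "BC"
                and exit_age <= baseline_age + landmark + horizon)


@dataclass
class PreparedCohort:
    """Eligible women with derived follow-up, outcome and landmark time."""

    frame: pd.DataFrame       # eligible rows + exit_age/event/outcome_5y
    exclusions: pd.DataFrame  # (id, reason) for every excluded woman
    landmark: float
    horizon: float

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, prepared_path, exclusions_path=None) -> None:
        self.frame.to_csv(prepared_path, index=False)
        if exclusions_path is not None:
            self.exclusions.to_csv(exclusions_path, index=False)


def prepare_cohort(frame: pd.DataFrame,
                   dcis_policy: str = "affected",
                   censor_at_rrso: bool = False,
                   landmark: float = DEFAULT_LANDMARK,
                   horizon: float = DEFAULT_HORIZON,
                   max_age: float = MAX_AGE) -> PreparedCohort:
    """Eligibility + censoring + outcome derivation in one pass.

    Women exiting at or before the landmark are excluded (reason
    "pre-landmark exit") rather than carried with a false outcome.
    """
    if landmark < 0 or horizon <= 0:
        raise InvalidParameterError("landmark must be >= 0, horizon > 0")
    retained, exclusions = apply_eligibility(
        frame, dcis_policy, censor_at_rrso,
        admin_years=landmark + horizon, max_age=max_age)
    baseline = retained["baseline_age"].to_numpy(dtype=float)
    exit_age = retained["exit_age"].to_numpy(dtype=float)
    pre_landmark = exit_age <= baseline + landmark
    if pre_landmark.any():
        extra = pd.DataFrame({
            "id": retained.loc[pre_landmark, "id"].to_numpy(),
            "reason": "pre-landmark exit"})
        exclusions = pd.concat([exclusions, extra], ignore_index=True)
        retained = retained.loc[~pre_landmark].reset_index(drop=True)
        baseline = baseline[~pre_landmark]
        exit_age = exit_age[~pre_landmark]
    event = retained["event"].to_numpy()
    retained["outcome_5y"] = (event == "BC") & \
        (exit_age <= baseline + landmark + horizon)
    retained["time_from_landmark"] = exit_age - baseline - landmark
    return PreparedCohort(frame=retained, exclusions=exclusions,
                          landmark=landmark, horizon=horizon)
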