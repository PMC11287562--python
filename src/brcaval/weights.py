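"""Inverse-probability sampling weights for non-random subcohort inclusion.

Subcohort membership (e.g. having PRS and questionnaire data) may depend
on the outcome: incident cases are more likely to have been genotyped.
A logistic model of inclusion with exactly six terms — intercept,
baseline age, follow-up duration, incident BC status, BC-by-age and
BC-by-follow-up interactions — is fitted per country group (small
countries pooled), and each included woman is weighted by the inverse of
her fitted inclusion probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FittingError, SchemaError

TERMS = ("intercept", "age", "followup", "bc", "bc_age", "bc_followup")

#: Country pooling used by default: Austria, Germany and Poland combined.
DEFAULT_GROUPING = {
    "UK": "UK", "France": "France", "Netherlands": "Netherlands",
    "Germany": "AT-DE-PL", "Austria": "AT-DE-PL", "Poland": "AT-DE-PL",
}

POOLED_LABEL = "pooled"


@dataclass
class WeightModel:
    """Fitted per-group inclusion logits and the weighting policy."""

    coefficients: dict[str, np.ndarray]   # group -> 6-vector (TERMS order)
    grouping: dict[str, str]              # country -> group label
    floor: float = 0.01                   # fitted-probability floor
    standard_errors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.floor < 1.0:
            raise SchemaError("probability floor must be in (0, 1)")

    def group_of(self, country: str) -> str:
        try:
            return self.grouping[country]
        except KeyError:
            raise SchemaError(f"country {country!r} not mapped to a "
                              "weighting group") from None

    def to_dict(self) -> dict:
        return {"terms": list(TERMS),
                "coefficients": {g: v.tolist()
                                 for g, v in self.coefficients.items()},
                "grouping": dict(self.grouping), "floor": self.floor}


def _design(frame: pd.DataFrame) -> np.ndarray:
    age = frame["baseline_age"].to_numpy(dtype=float)
    fu = (frame["exit_age"] - frame["baseline_age"]).to_numpy(dtype=float)
    bc = (frame["event"] == "BC").to_numpy(dtype=float)
    return np.column_stack([np.ones_like(age), age, fu, bc,
                            bc * age, bc * fu])


def assign_groups(frame: pd.DataFrame, grouping: dict[str, str] | None,
                  min_group_size: int) -> pd.Series:
    """Country -> group labels, pooling groups below ``min_group_size``."""
    countries = frame["country"].astype(str)
    if grouping is None:
        groups = countries.copy()
    else:
        unmapped = set(countries.unique()) - set(grouping)
        if unmapped:
            raise SchemaError(f"countries {sorted(unmapped)} not mapped "
                              "to a weighting group")
        groups = countries.map(grouping)
    sizes = groups.value_counts()
    small = sizes.index[sizes < min_group_size]
    if len(small):
        groups = groups.where(~groups.isin(small), POOLED_LABEL)
    return groups


def fit_inclusion_model(frame: pd.DataFrame,
                        grouping: dict[str, str] | None = None,
                        min_group_size: int = 200,
                        floor: float = 0.01) -> WeightModel:
    """Fit the six-term inclusion logistic per country group.

    ``frame`` must be the *full* eligible cohort (included and excluded
    women) with derived ``exit_age``/``event`` columns and the
    ``included_in_subcohort`` flag.  Groups below ``min_group_size`` are
    merged into a pooled group before fitting.
    """
    groups = assign_groups(frame, grouping, min_group_size)
    y_all = frame["included_in_subcohort"].to_numpy(dtype=float)
    x_all = _design(frame)
    coefficients: dict[str, np.ndarray] = {}
    standard_errors: dict[str, np.ndarray] = {}
    final_grouping: dict[str, str] = {}
    for country, g in zip(frame["country"].astype(str), groups):
        final_grouping[country] = g
    for g in sorted(groups.unique()):
        mask = (groups == g).to_numpy()
        y = y_all[mask]
        if y.min() == y.max():
            raise FittingError(
                f"inclusion flag is single-class in group {g!r}; "
                "the inclusion model cannot be fitted")
        try:
            res = sm.GLM(y, x_all[mask],
                         family=sm.families.Binomial()).fit()
        except Exception as exc:  # pragma: no cover - statsmodels detail
            raise FittingError(
                f"inclusion model failed in group {g!r}: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FittingError(
                f"inclusion model diverged in group {g!r} "
                "(possible separation)")
        coefficients[g] = np.asarray(res.params, dtype=float)
        standard_errors[g] = np.asarray(res.bse, dtype=float)
    return WeightModel(coefficients=coefficients, grouping=final_grouping,
                       floor=floor, standard_errors=standard_errors)


def compute_weights(model: WeightModel, frame: pd.DataFrame,
                    apply_floor: bool = True) -> pd.DataFrame:
    """Per-woman fitted inclusion probabilities and inverse weights.

    Returns a table (id, group, fitted_probability, weight) aligned with
    ``frame``; downstream analyses use the rows of included women.
    """
    groups = frame["country"].astype(str).map(model.group_of)
    x = _design(frame)
    p = np.empty(len(frame))
    for g in groups.unique():
        if g not in model.coefficients:
            raise SchemaError(f"no fitted coefficients for group {g!r}")
        mask = (groups == g).to_numpy()
        lp = x[mask] @ model.coefficients[g]
        p[mask] = 1.0 / (1.0 + np.exp(-lp))
    floored = np.maximum(p, model.floor) if apply_floor else p
    return pd.DataFrame({
        "id": frame["id"].to_numpy(), "group": groups.to_numpy(),
        "fitted_probability": p, "weight": 1.0 / floored})
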