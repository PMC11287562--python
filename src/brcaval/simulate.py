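"""Synthetic clinic-ascertained BRCA1/2 carrier cohorts.

The generator emulates the statistical structure a prospective carrier
validation study assumes: family-history-enriched ascertainment, a raw
polygenic score that is standard normal after standardization with the
published constants, multiplicative age-banded breast-cancer hazards,
independent competing/censoring events (death from the age-banded
mortality curve; mastectomy, RRSO and loss to follow-up at constant
rates), and outcome-dependent subcohort inclusion for exercising the
inverse-probability weighting scheme.

Every woman owns an RNG substream keyed by ``(seed, index)``, so runs are
bit-reproducible and growing the cohort never perturbs earlier women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortRecord, RiskFactorProfile, records_to_frame
from .engine import band_log_multiplier
from .errors import InvalidParameterError
from .hazard import FULL_VARIANT, HazardModel, default_hazard_model

#: Published standardization constants for the 313-SNP PRS.
PRS_MEAN = -0.424
PRS_SD = 0.611


def standardize_prs(raw: float, mean: float = PRS_MEAN,
                    sd: float = PRS_SD) -> float:
    """Standardize a raw polygenic score to SD units: (raw - mean) / sd."""
    if sd <= 0:
        raise InvalidParameterError("prs sd must be positive")
    return (raw - mean) / sd


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal baseline-age spec (years)."""

    mean: float = 40.0
    sd: float = 10.0
    min_age: float = 20.0
    max_age: float = 73.0


@dataclass(frozen=True)
class InclusionTruth:
    """Truth coefficients of the outcome-dependent inclusion logit.

    logit P(included) = intercept + age*baseline_age + followup*fu
                        + bc*Y + bc_age*Y*baseline_age + bc_followup*Y*fu
    with Y the incident-BC indicator and fu the censored follow-up span.
    """

    intercept: float = 2.2
    age: float = 0.0
    followup: float = 0.0
    bc: float = 0.0
    bc_age: float = 0.0
    bc_followup: float = 0.0

    def linear_predictor(self, baseline_age, followup, bc) -> np.ndarray:
        baseline_age = np.asarray(baseline_age, dtype=float)
        followup = np.asarray(followup, dtype=float)
        bc = np.asarray(bc, dtype=float)
        return (self.intercept + self.age * baseline_age
                + self.followup * followup + self.bc * bc
                + self.bc_age * bc * baseline_age
                + self.bc_followup * bc * followup)


def _default_qrf_frequencies() -> dict[str, dict[str, float]]:
    return {
        "parity": {"nulliparous": 0.3, "parous": 0.7},
        "oc_use": {"never": 0.4, "ever": 0.6},
        "bmi": {"normal": 0.5, "overweight": 0.3, "obese": 0.2},
        "alcohol": {"none": 0.5, "regular": 0.5},
    }


def _default_countries() -> dict[str, float]:
    return {"UK": 0.25, "Germany": 0.20, "France": 0.20,
            "Netherlands": 0.20, "Austria": 0.05, "Poland": 0.10}


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic cohort draw.

    Rates are per year.  ``fh_ascertainment_strength`` is the log-odds of
    cohort entry per affected first-degree relative; with a positive value
    the realized cohort is FH-enriched relative to the population
    Poisson(``fh_mean``) burden.
    """

    n_women: int
    seed: int
    prs_mean: float = PRS_MEAN
    prs_sd: float = PRS_SD
    hazard_model: HazardModel = field(default_factory=default_hazard_model)
    baseline_age_distribution: AgeDistribution = field(
        default_factory=AgeDistribution)
    fh_mean: float = 0.4
    fh_ascertainment_strength: float = 1.0
    fh_base_accept: float = 0.3
    inclusion_model_truth: InclusionTruth = field(
        default_factory=InclusionTruth)
    dropout_rate: float = 0.010
    mastectomy_rate: float = 0.012
    rrso_rate: float = 0.020
    dcis_fraction: float = 0.15
    max_followup_years: float = 8.0
    gene_frequencies: dict[str, float] = field(
        default_factory=lambda: {"BRCA1": 0.55, "BRCA2": 0.45})
    qrf_frequencies: dict[str, dict[str, float]] = field(
        default_factory=_default_qrf_frequencies)
    country_frequencies: dict[str, float] = field(
        default_factory=_default_countries)

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise InvalidParameterError("n_women must be positive")
        if self.prs_sd <= 0:
            raise InvalidParameterError("prs_sd must be positive")
        for name in ("dropout_rate", "mastectomy_rate", "rrso_rate",
                     "fh_mean"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.dcis_fraction <= 1.0:
            raise InvalidParameterError("dcis_fraction must be in [0, 1]")
        if not 0.0 < self.fh_base_accept <= 1.0:
            raise InvalidParameterError("fh_base_accept must be in (0, 1]")


# ---------------------------------------------------------------------------
# event-time sampling
# ---------------------------------------------------------------------------

def _piecewise_first_event(rates: np.ndarray, edges: np.ndarray,
                           start: float, target: float) -> float | None:
    """Age at which cumulative hazard from ``start`` reaches ``target``.

    Inverse-transform draw for a piecewise-constant hazard; ``None`` when
    the grid is exhausted (no event before the last edge).
    """
    k = int(np.searchsorted(edges, start, side="right") - 1)
    age = start
    acc = 0.0
    for j in range(k, rates.size):
        width = edges[j + 1] - age
        step = rates[j] * width
        if acc + step >= target:
            return age + (target - acc) / rates[j]
        acc += step
        age = edges[j + 1]
    return None


def simulate_event_times(profile: RiskFactorProfile, baseline_age: float,
                         model: HazardModel, rng: np.random.Generator, *,
                         dropout_rate: float, mastectomy_rate: float,
                         rrso_rate: float, dcis_fraction: float,
                         max_followup_years: float) -> dict:
    """Draw one woman's raw event history from the generator truth.

    The BC age comes from inverse-transform sampling of her individual
    piecewise-constant hazard (all factor groups on); death follows the
    age-banded mortality curve; mastectomy, RRSO and dropout are
    constant-rate exponentials.  A fixed draw order keeps substreams
    aligned across configurations.
    """
    if not model.min_age <= baseline_age < model.max_age:
        raise InvalidParameterError(
            f"baseline_age {baseline_age} outside model grid")
    lam = model.baseline_bc_incidence * np.exp(
        band_log_multiplier(profile, FULL_VARIANT, model))
    draws = rng.exponential(size=5)  # bc, death, mastectomy, rrso, dropout
    u_dcis = rng.uniform()
    bc_age = _piecewise_first_event(lam, model.age_edges, baseline_age,
                                    draws[0])
    death_age = _piecewise_first_event(model.competing_mortality,
                                       model.age_edges, baseline_age,
                                       draws[1])
    mast_age = (baseline_age + draws[2] / mastectomy_rate
                if mastectomy_rate > 0 else None)
    rrso_age = (baseline_age + draws[3] / rrso_rate
                if rrso_rate > 0 else None)
    dropout = draws[4] / dropout_rate if dropout_rate > 0 else math.inf
    return {
        "bc_age": bc_age,
        "bc_is_dcis": bool(bc_age is not None and u_dcis < dcis_fraction),
        "death_age": death_age,
        "mastectomy_age": mast_age,
        "rrso_age": rrso_age,
        "last_followup_age": baseline_age + min(dropout, max_followup_years),
    }


def _draw_categorical(rng: np.random.Generator,
                      freqs: dict[str, float]) -> str:
    labels = list(freqs)
    p = np.asarray([freqs[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _draw_baseline_age(rng: np.random.Generator,
                       dist: AgeDistribution) -> float:
    for _ in range(10_000):
        a = rng.normal(dist.mean, dist.sd)
        if dist.min_age <= a < dist.max_age:
            return float(a)
    raise InvalidParameterError("baseline age distribution rejects "
                                "essentially all draws")


def _draw_fh_score(rng: np.random.Generator,
                   config: SimulationConfig) -> int:
    """FH burden under FH-enriched ascertainment (rejection sampling)."""
    base_logit = math.log(config.fh_base_accept
                          / (1.0 - config.fh_base_accept + 1e-12)) \
        if config.fh_base_accept < 1.0 else math.inf
    for _ in range(100_000):
        fh = int(rng.poisson(config.fh_mean))
        logit = base_logit + config.fh_ascertainment_strength * fh
        p = 1.0 / (1.0 + math.exp(-logit)) if math.isfinite(logit) else 1.0
        if rng.uniform() < p:
            return fh
    raise InvalidParameterError("ascertainment acceptance never triggered")


def simulate_woman(i: int, config: SimulationConfig) -> CohortRecord:
    """Simulate one woman on her own ``(seed, i)`` RNG substream."""
    rng = np.random.default_rng([config.seed, i])
    country = _draw_categorical(rng, config.country_frequencies)
    gene = _draw_categorical(rng, config.gene_frequencies)
    baseline = _draw_baseline_age(rng, config.baseline_age_distribution)
    fh = _draw_fh_score(rng, config)
    prs_raw = float(rng.normal(config.prs_mean, config.prs_sd))
    qrf = {f: _draw_categorical(rng, freqs)
           for f, freqs in sorted(config.qrf_frequencies.items())}
    profile = RiskFactorProfile(
        gene=gene, prs_raw=prs_raw,
        prs_z=standardize_prs(prs_raw, config.prs_mean, config.prs_sd),
        qrf_levels=qrf, fh_score=fh)
    events = simulate_event_times(
        profile, baseline, config.hazard_model, rng,
        dropout_rate=config.dropout_rate,
        mastectomy_rate=config.mastectomy_rate,
        rrso_rate=config.rrso_rate,
        dcis_fraction=config.dcis_fraction,
        max_followup_years=config.max_followup_years)
    return CohortRecord(
        id=f"W{i:06d}", country=country, baseline_age=baseline,
        profile=profile, **events)


def simulate_cohort(config: SimulationConfig) -> list[CohortRecord]:
    """Generate the configured number of ascertained carriers."""
    return [simulate_woman(i, config) for i in range(config.n_women)]


def simulate_cohort_frame(config: SimulationConfig) -> pd.DataFrame:
    """Cohort as the canonical wide table (see :mod:`brcaval.cohort`)."""
    return records_to_frame(simulate_cohort(config))


# ---------------------------------------------------------------------------
# outcome-dependent subcohort inclusion
# ---------------------------------------------------------------------------

def simulate_subcohort_inclusion(frame: pd.DataFrame,
                                 truth: InclusionTruth,
                                 seed: int) -> pd.DataFrame:
    """Draw ``included_in_subcohort`` flags from the inclusion truth.

    Inclusion is Bernoulli with a logit linear in baseline age, censored
    follow-up duration and incident BC status plus the BC-by-age and
    BC-by-follow-up interactions, emulating non-random subcohort
    membership with respect to the outcome.
    """
    from .prepare import derive_follow_up_frame

    fu = derive_follow_up_frame(frame)
    followup = (fu["exit_age"] - frame["baseline_age"]).to_numpy()
    bc = (fu["event"] == "BC").to_numpy()
    lp = truth.linear_predictor(frame["baseline_age"].to_numpy(),
                                followup, bc)
    p = 1.0 / (1.0 + np.exp(-lp))
    rng = np.random.default_rng([seed, 104729])  # inclusion substream
    out = frame.copy()
    out["included_in_subcohort"] = rng.uniform(size=len(frame)) < p
    return out


def with_config(config: SimulationConfig, **changes) -> SimulationConfig:
    """Return a copy of the config with fields replaced."""
    return replace(config, **changes)
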