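"""Absolute-risk computation under the multiplicative hazard model.

The absolute (cumulative-incidence) risk of breast cancer between ages
``s`` and ``e``, conditional on being alive and BC-free at ``s`` and
treating all-cause mortality ``mu`` as the only competing event, is

    P(s, e) = int_s^e lambda(u) exp(-int_s^u [lambda(v) + mu(v)] dv) du.

With piecewise-constant hazards the integral has a closed form per age
band: a band with rates (lambda_k, mu_k) occupied for duration d_k
contributes S_k * lambda_k/(lambda_k+mu_k) * (1 - exp(-(lambda_k+mu_k) d_k)),
where S_k is the probability of reaching the band event-free.  All public
functions evaluate this closed form exactly (no quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RiskFactorProfile, qrf_columns
from .errors import InvalidParameterError
from .hazard import HazardModel, ModelVariant


# ---------------------------------------------------------------------------
# per-band individual hazards
# ---------------------------------------------------------------------------

def band_log_multiplier(profile: RiskFactorProfile, variant: ModelVariant,
                        model: HazardModel) -> np.ndarray:
    """Per-band log relative hazard of a profile under a variant."""
    out = np.zeros(model.n_bands)
    if variant.use_gene:
        try:
            out = out + model.log_rr_gene[profile.gene]
        except KeyError:
            raise InvalidParameterError(
                f"no PV relative hazard for gene {profile.gene!r}") from None
    if variant.use_prs:
        out = out + profile.prs_z * model.log_rr_prs_per_sd
    if variant.use_qrf:
        out = out + sum(model.qrf_log_rr(f, lvl)
                        for f, lvl in profile.qrf_levels.items())
    if variant.use_fh:
        out = out + profile.fh_score * model.log_rr_fh_per_relative
    return out


def band_hazards(frame: pd.DataFrame, model: HazardModel,
                 variant: ModelVariant) -> np.ndarray:
    """Vectorized (n_women, n_bands) BC hazard matrix for a cohort table."""
    n = len(frame)
    log_m = np.zeros((n, model.n_bands))
    if variant.use_gene:
        for gene, vec in model.log_rr_gene.items():
            mask = (frame["gene"] == gene).to_numpy()
            log_m[mask] += vec
        known = frame["gene"].isin(model.log_rr_gene).to_numpy()
        if not known.all():
            bad = frame.loc[~known, "gene"].iloc[0]
            raise InvalidParameterError(f"no PV relative hazard for gene {bad!r}")
    if variant.use_prs:
        log_m += frame["prs_z"].to_numpy()[:, None] * model.log_rr_prs_per_sd
    if variant.use_qrf:
        for col in qrf_columns(frame):
            factor = col[len("qrf_"):]
            lrr = frame[col].map(
                lambda lvl, f=factor: model.qrf_log_rr(f, lvl)).to_numpy()
            log_m += lrr[:, None]
    if variant.use_fh:
        log_m += (frame["fh_score"].to_numpy(dtype=float)[:, None]
                  * model.log_rr_fh_per_relative)
    return model.baseline_bc_incidence[None, :] * np.exp(log_m)


def hazard_at_age(profile: RiskFactorProfile, variant: ModelVariant,
                  model: HazardModel, age: float) -> float:
    """Individual per-year BC hazard at an age inside the model grid."""
    k = int(model.band_index(age))
    lam0 = model.baseline_bc_incidence[k]
    return float(lam0 * np.exp(band_log_multiplier(profile, variant, model)[k]))


# ---------------------------------------------------------------------------
# closed-form window integrals
# ---------------------------------------------------------------------------

def _window_integral(lam: np.ndarray, mu: np.ndarray, edges: np.ndarray,
                     start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Competing-risk cumulative incidence over [start, end) per woman.

    lam: (n, nb) cause-specific hazards; mu: (nb,) competing mortality.
    """
    a = np.maximum(start[:, None], edges[:-1][None, :])
    b = np.minimum(end[:, None], edges[1:][None, :])
    d = np.clip(b - a, 0.0, None)
    r = lam + mu[None, :]
    h_seg = r * d
    h_before = np.cumsum(h_seg, axis=1) - h_seg
    frac = np.divide(lam, r, out=np.zeros_like(lam), where=r > 0)
    contrib = np.exp(-h_before) * frac * (-np.expm1(-h_seg))
    return contrib.sum(axis=1)


def _window_survival(lam: np.ndarray, mu: np.ndarray, edges: np.ndarray,
                     start: np.ndarray, end: np.ndarray) -> np.ndarray:
    a = np.maximum(start[:, None], edges[:-1][None, :])
    b = np.minimum(end[:, None], edges[1:][None, :])
    d = np.clip(b - a, 0.0, None)
    return np.exp(-((lam + mu[None, :]) * d).sum(axis=1))


def _check_window(model: HazardModel, start: float, end: float,
                  clamp: bool) -> float:
    if not start < end:
        raise InvalidParameterError("start_age must be below end_age")
    if start < model.min_age:
        raise InvalidParameterError("start_age below the model age grid")
    if end > model.max_age:
        if not clamp:
            raise InvalidParameterError(
                f"end_age {end} exceeds max_age {model.max_age}; "
                "pass clamp=True to truncate")
        end = model.max_age
    return end


def absolute_risk(profile: RiskFactorProfile, variant: ModelVariant,
                  model: HazardModel, start_age: float, end_age: float,
                  clamp: bool = False) -> float:
    """Absolute BC risk in [start_age, end_age), conditional on being
    alive and BC-free at start_age."""
    end_age = _check_window(model, start_age, end_age, clamp)
    lam = (model.baseline_bc_incidence
           * np.exp(band_log_multiplier(profile, variant, model)))[None, :]
    return float(_window_integral(lam, model.competing_mortality,
                                  model.age_edges,
                                  np.array([start_age]),
                                  np.array([end_age]))[0])


def event_free_survival(profile: RiskFactorProfile, variant: ModelVariant,
                        model: HazardModel, start_age: float,
                        end_age: float, clamp: bool = False) -> float:
    """P(no BC and no death in [start_age, end_age) | event-free at start)."""
    end_age = _check_window(model, start_age, end_age, clamp)
    lam = (model.baseline_bc_incidence
           * np.exp(band_log_multiplier(profile, variant, model)))[None, :]
    return float(_window_survival(lam, model.competing_mortality,
                                  model.age_edges,
                                  np.array([start_age]),
                                  np.array([end_age]))[0])


# ---------------------------------------------------------------------------
# cohort-level prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Per-woman, per-variant fixed-horizon predicted risks."""

    risks: pd.DataFrame          # index: woman id; one column per variant
    horizon_start: pd.Series     # per-woman window start age
    horizon_end: pd.Series       # per-woman window end age
    landmark: float
    horizon: float

    def to_long_frame(self) -> pd.DataFrame:
        long = self.risks.reset_index().melt(
            id_vars="id", var_name="variant", value_name="risk")
        return long.sort_values(["variant", "id"], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def predict_cohort(prepared: pd.DataFrame, variants: list[ModelVariant],
                   model: HazardModel, landmark: float = 1.0,
                   horizon: float = 5.0,
                   predict_to_censoring: bool = False) -> PredictionSet:
    """Predict fixed-horizon risks for a prepared cohort table.

    The window for each woman is [baseline+landmark,
    baseline+landmark+horizon), clamped at the model's maximum age.  With
    ``predict_to_censoring`` women censored inside the window have the
    window truncated at their exit age, mirroring validation designs that
    predict healthy women's risks only to their censoring age.
    """
    if not variants:
        raise InvalidParameterError("variant list must not be empty")
    names = [v.name for v in variants]
    if len(set(names)) != len(names):
        raise InvalidParameterError("variant names must be unique")
    start = prepared["baseline_age"].to_numpy(dtype=float) + landmark
    end = np.minimum(start + horizon, model.max_age)
    if np.any(start >= model.max_age) or np.any(start < model.min_age):
        raise InvalidParameterError("a prediction window starts outside "
                                    "the model age grid")
    if predict_to_censoring:
        exit_age = prepared["exit_age"].to_numpy(dtype=float)
        censored = (prepared["event"] == "censored").to_numpy()
        if "exit_reason" in prepared.columns:
            # death is a competing risk the integral already marginalizes,
            # not a "healthy censoring": never truncate at death
            censored &= (prepared["exit_reason"] != "death").to_numpy()
        end = np.where(censored & (exit_age < end), exit_age, end)
        if np.any(end <= start):
            raise InvalidParameterError(
                "censoring at or before the landmark; drop pre-landmark "
                "exits before predicting")
    cols = {}
    for variant in variants:
        lam = band_hazards(prepared, model, variant)
        cols[variant.name] = _window_integral(
            lam, model.competing_mortality, model.age_edges, start, end)
    idx = pd.Index(prepared["id"], name="id")
    return PredictionSet(
        risks=pd.DataFrame(cols, index=idx),
        horizon_start=pd.Series(start, index=idx, name="horizon_start"),
        horizon_end=pd.Series(end, index=idx, name="horizon_end"),
        landmark=landmark, horizon=horizon)
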