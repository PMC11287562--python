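"""Multiplicative age-banded hazard models.

The breast-cancer (BC) hazard for a woman with risk-factor profile x at
age t is

    lambda(t | x) = lambda0(t) * RR_gene(t) * RR_PRS(t)^z * prod_f RR_qrf[f]
                    * RR_FH^fh

where lambda0 is a piecewise-constant baseline incidence on an age grid
(5-year bands by default), the pathogenic-variant (PV) and per-SD PRS
relative hazards are age-dependent, and questionnaire risk factors (QRFs)
and the family-history (FH) burden act as age-constant multipliers.
Competing mortality mu(t) is piecewise constant on the same grid.

A :class:`ModelVariant` switches individual factor groups on or off so the
same machinery yields the nested predictor family (age-only null, PV only,
PV+QRFs, PV+PRS, PV+QRFs+PRS, full model with FH).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidParameterError, SchemaError

GENES = ("BRCA1", "BRCA2")


@dataclass(frozen=True)
class ModelVariant:
    """Which factor groups enter the predictor."""

    name: str
    use_gene: bool = False
    use_prs: bool = False
    use_qrf: bool = False
    use_fh: bool = False


#: The nested predictor family evaluated by the validation pipeline.
DEFAULT_VARIANTS: tuple[ModelVariant, ...] = (
    ModelVariant("null"),
    ModelVariant("PV", use_gene=True),
    ModelVariant("PV+QRFs", use_gene=True, use_qrf=True),
    ModelVariant("PV+PRS", use_gene=True, use_prs=True),
    ModelVariant("PV+QRFs+PRS", use_gene=True, use_qrf=True, use_prs=True),
    ModelVariant("FH+QRFs+PRS+PV", use_gene=True, use_qrf=True,
                 use_prs=True, use_fh=True),
)

FULL_VARIANT = DEFAULT_VARIANTS[-1]


@dataclass
class HazardModel:
    """Piecewise-constant multiplicative hazard model.

    Parameters
    ----------
    age_edges
        Strictly increasing band edges in years; bands are half-open
        ``[age_edges[k], age_edges[k+1])``.  The last edge is the maximum
        age supported (risk windows are clamped there).
    baseline_bc_incidence
        Per-year baseline BC incidence per band (the age-only hazard).
    competing_mortality
        Per-year all-cause mortality per band; the only competing event
        inside the predictor.
    log_rr_gene
        Per-gene, per-band log relative hazard of the PV.
    log_rr_prs_per_sd
        Per-band log relative hazard per SD of the standardized PRS.
    log_rr_qrf
        factor name -> category label -> log relative hazard; reference
        categories carry 0.
    log_rr_fh_per_relative
        Log relative hazard per affected first-degree relative.
    """

    age_edges: np.ndarray
    baseline_bc_incidence: np.ndarray
    competing_mortality: np.ndarray
    log_rr_gene: dict[str, np.ndarray]
    log_rr_prs_per_sd: np.ndarray
    log_rr_qrf: dict[str, dict[str, float]] = field(default_factory=dict)
    log_rr_fh_per_relative: float = 0.0

    def __post_init__(self) -> None:
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.baseline_bc_incidence = np.asarray(self.baseline_bc_incidence,
                                                dtype=float)
        self.competing_mortality = np.asarray(self.competing_mortality,
                                              dtype=float)
        self.log_rr_prs_per_sd = np.asarray(self.log_rr_prs_per_sd,
                                            dtype=float)
        self.log_rr_gene = {g: np.asarray(v, dtype=float)
                            for g, v in self.log_rr_gene.items()}
        if self.age_edges.ndim != 1 or self.age_edges.size < 2:
            raise InvalidParameterError("age_edges needs at least two edges")
        if np.any(np.diff(self.age_edges) <= 0):
            raise InvalidParameterError("age_edges must strictly increase")
        nb = self.n_bands
        for label, vec in (("baseline_bc_incidence", self.baseline_bc_incidence),
                           ("competing_mortality", self.competing_mortality),
                           ("log_rr_prs_per_sd", self.log_rr_prs_per_sd)):
            if vec.shape != (nb,):
                raise InvalidParameterError(
                    f"{label} must have one entry per band ({nb})")
        if (self.baseline_bc_incidence < 0).any() or \
                (self.competing_mortality < 0).any():
            raise InvalidParameterError("rates must be non-negative")
        for g, vec in self.log_rr_gene.items():
            if vec.shape != (nb,):
                raise InvalidParameterError(
                    f"log_rr_gene[{g!r}] must have one entry per band ({nb})")

    @property
    def n_bands(self) -> int:
        return self.age_edges.size - 1

    @property
    def min_age(self) -> float:
        return float(self.age_edges[0])

    @property
    def max_age(self) -> float:
        return float(self.age_edges[-1])

    def band_index(self, age) -> np.ndarray:
        """Band index of each age; ages must lie in [min_age, max_age)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.min_age) or np.any(age >= self.max_age):
            raise InvalidParameterError(
                f"age outside model grid [{self.min_age}, {self.max_age})")
        return np.minimum(np.searchsorted(self.age_edges, age, side="right") - 1,
                          self.n_bands - 1)

    def qrf_log_rr(self, factor: str, level: str) -> float:
        try:
            table = self.log_rr_qrf[factor]
        except KeyError:
            raise SchemaError(f"unknown QRF factor {factor!r}") from None
        try:
            return float(table[level])
        except KeyError:
            raise SchemaError(
                f"unknown category {level!r} for QRF factor {factor!r}"
            ) from None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_edges"] = self.age_edges.tolist()
        d["baseline_bc_incidence"] = self.baseline_bc_incidence.tolist()
        d["competing_mortality"] = self.competing_mortality.tolist()
        d["log_rr_prs_per_sd"] = self.log_rr_prs_per_sd.tolist()
        d["log_rr_gene"] = {g: v.tolist() for g, v in self.log_rr_gene.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HazardModel":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HazardModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_hazard_model() -> HazardModel:
    """Reference hazard model on 5-year bands from 20 to 80.

    Baseline incidence approximates general-population breast-cancer rates;
    the PV relative hazards give carrier-level absolute risks (BRCA1 effect
    largest at young ages and declining, BRCA2 peaking in mid-life); the
    per-SD PRS effect attenuates with age.  QRF categories are a compact
    hormonal/reproductive/anthropometric set with modest effects; the FH
    multiplier applies per affected first-degree relative.
    """
    edges = np.arange(20.0, 85.0, 5.0)
    lam0 = np.array([2e-5, 1e-4, 3e-4, 6e-4, 1.2e-3, 1.9e-3,
                     2.2e-3, 2.5e-3, 3.0e-3, 3.5e-3, 4.0e-3, 4.2e-3])
    mu = np.array([4e-4, 5e-4, 6e-4, 8e-4, 1.2e-3, 1.8e-3,
                   2.8e-3, 4.5e-3, 7.0e-3, 1.1e-2, 1.8e-2, 3.0e-2])
    rr_brca1 = np.array([20., 20., 18., 15., 12., 8., 6., 5., 4., 3., 2.5, 2.])
    rr_brca2 = np.array([5., 6., 8., 10., 11., 10., 9., 8., 7., 6., 5., 4.])
    prs_rr = np.array([1.60, 1.60, 1.55, 1.50, 1.45, 1.40,
                       1.35, 1.32, 1.30, 1.28, 1.26, 1.25])
    qrf = {
        "parity": {"nulliparous": 0.0, "parous": np.log(0.9)},
        "oc_use": {"never": 0.0, "ever": np.log(1.1)},
        "bmi": {"normal": 0.0, "overweight": np.log(1.1),
                "obese": np.log(1.2)},
        "alcohol": {"none": 0.0, "regular": np.log(1.1)},
    }
    return HazardModel(
        age_edges=edges,
        baseline_bc_incidence=lam0,
        competing_mortality=mu,
        log_rr_gene={"BRCA1": np.log(rr_brca1), "BRCA2": np.log(rr_brca2)},
        log_rr_prs_per_sd=np.log(prs_rr),
        log_rr_qrf=qrf,
        log_rr_fh_per_relative=float(np.log(1.3)),
    )
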