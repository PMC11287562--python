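"""End-to-end validation runs: simulate/load -> prepare -> weigh ->
predict -> validate.

A :class:`RunConfig` captures every knob of a run; `run_validation`
executes the stages with stage-level logging of record counts, writes the
report (JSON + flat CSV mirroring the variant-by-subgroup layout), the
exclusion log, the weights table, per-woman predictions and a manifest
(config hash, seed, library versions), and returns the in-memory report.
Identical config and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import read_cohort_csv
from .engine import predict_cohort
from .errors import InvalidParameterError
from .hazard import DEFAULT_VARIANTS, HazardModel, ModelVariant, \
    default_hazard_model
from .metrics import DEFAULT_THRESHOLDS, ValidationReport, \
    evaluate_predictions
from .prepare import prepare_cohort
from .simulate import SimulationConfig, simulate_cohort_frame, \
    simulate_subcohort_inclusion
from .weights import compute_weights, fit_inclusion_model

log = logging.getLogger("brcaval")

_VARIANTS_BY_NAME = {v.name: v for v in DEFAULT_VARIANTS}


def variants_from_names(names) -> list[ModelVariant]:
    try:
        return [_VARIANTS_BY_NAME[n] for n in names]
    except KeyError as exc:
        raise InvalidParameterError(
            f"unknown variant {exc.args[0]!r}; known: "
            f"{sorted(_VARIANTS_BY_NAME)}") from None


@dataclass
class RunConfig:
    """Everything one validation run depends on."""

    seed: int = 0
    cohort_csv: str | None = None            # user cohort, or...
    simulation: SimulationConfig | None = None  # ...synthetic cohort
    hazard_model: HazardModel = field(default_factory=default_hazard_model)
    output_dir: str | None = None
    variant_names: tuple[str, ...] = tuple(v.name for v in DEFAULT_VARIANTS)
    landmark: float = 1.0
    horizon: float = 5.0
    dcis_policy: str = "affected"
    censor_at_rrso: bool = False
    predict_to_censoring: bool = False
    weighting: bool = True
    min_group_size: int = 200
    probability_floor: float = 0.01
    grouping: dict[str, str] | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_boot: int = 2000
    jackknife_groups: int = 50

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("simulation", "hazard_model")}
        payload["hazard_model"] = self.hazard_model.to_dict()
        if self.simulation is not None:
            sim = dict(self.simulation.__dict__)
            sim["hazard_model"] = self.simulation.hazard_model.to_dict()
            sim["baseline_age_distribution"] = \
                self.simulation.baseline_age_distribution.__dict__
            sim["inclusion_model_truth"] = \
                self.simulation.inclusion_model_truth.__dict__
            payload["simulation"] = sim
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if (config.cohort_csv is None) == (config.simulation is None):
        raise InvalidParameterError(
            "exactly one of cohort_csv and simulation must be set")
    if config.cohort_csv is not None:
        frame = read_cohort_csv(config.cohort_csv)
        log.info("loaded cohort: %d women from %s", len(frame),
                 config.cohort_csv)
        return frame
    frame = simulate_cohort_frame(config.simulation)
    frame = simulate_subcohort_inclusion(
        frame, config.simulation.inclusion_model_truth,
        seed=config.simulation.seed)
    log.info("simulated cohort: %d women (%d included in subcohort)",
             len(frame), int(frame["included_in_subcohort"].sum()))
    return frame


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute the full pipeline; write outputs when output_dir is set."""
    frame = _load_cohort(config)
    prepared = prepare_cohort(
        frame, dcis_policy=config.dcis_policy,
        censor_at_rrso=config.censor_at_rrso,
        landmark=config.landmark, horizon=config.horizon)
    log.info("eligibility: retained %d, excluded %d",
             prepared.n, len(prepared.exclusions))

    weight_table = None
    analysis = prepared.frame
    w = None
    if config.weighting:
        model = fit_inclusion_model(
            prepared.frame, grouping=config.grouping,
            min_group_size=config.min_group_size,
            floor=config.probability_floor)
        weight_table = compute_weights(model, prepared.frame)
        included = prepared.frame["included_in_subcohort"].to_numpy(bool)
        analysis = prepared.frame.loc[included].reset_index(drop=True)
        w = weight_table.loc[included, "weight"].to_numpy()
        log.info("weighting: %d groups, analysing %d included women "
                 "(sum of weights %.1f)", len(model.coefficients),
                 len(analysis), float(w.sum()))
    else:
        included = prepared.frame["included_in_subcohort"].to_numpy(bool)
        analysis = prepared.frame.loc[included].reset_index(drop=True)
        log.info("weighting off: analysing %d included women unweighted",
                 len(analysis))

    variants = variants_from_names(config.variant_names)
    predictions = predict_cohort(
        analysis, variants, config.hazard_model,
        landmark=config.landmark, horizon=config.horizon,
        predict_to_censoring=config.predict_to_censoring)
    log.info("predicted %d variants for %d women", len(variants),
             len(analysis))

    risks = predictions.risks.reset_index(drop=True)
    report = evaluate_predictions(
        analysis, risks, weights=w, thresholds=config.thresholds,
        n_boot=config.n_boot, jackknife_groups=config.jackknife_groups,
        seed=config.seed)
    report.metadata.update({
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_input": len(frame), "n_eligible": prepared.n,
        "n_analysed": len(analysis),
        "eo_ci_method": "log-normal, Poisson-type SE sqrt(sum w^2 y)/O",
        "versions": {"brcaval": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__}})

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=float)
        report.summary_frame().to_csv(out / "report.csv", index=False)
        prepared.exclusions.to_csv(out / "exclusions.csv", index=False)
        predictions.to_csv(out / "predictions.csv")
        if weight_table is not None:
            weight_table.to_csv(out / "weights.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config_hash": config.config_hash(),
                       "seed": config.seed,
                       "versions": report.metadata["versions"]}, fh,
                      indent=2)
    return report


def compare_variants(report: ValidationReport) -> pd.DataFrame:
    """Rank predictor variants by Harrell's C (subgroup 'all')."""
    frame = report.summary_frame()
    frame = frame[frame["subgroup"] == "all"].copy()
    if len(frame) < 2:
        raise InvalidParameterError("need at least two variants to compare")
    for flag in ("use_gene", "use_prs", "use_qrf", "use_fh"):
        frame[flag] = [getattr(_VARIANTS_BY_NAME.get(v, ModelVariant(v)),
                               flag) for v in frame["variant"]]
    return frame.sort_values(["C", "variant"],
                             ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
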