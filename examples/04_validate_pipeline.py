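"""End-to-end validation run and variant comparison.

Simulates a cohort, runs eligibility -> weighting -> prediction ->
weighted metrics for the nested predictor family, and prints the
variant ranking by Harrell's C together with the risk-stratification
table of the full model.
"""

import brcaval as bv

config = bv.RunConfig(
    seed=7,
    simulation=bv.SimulationConfig(
        n_women=8000, seed=7,
        inclusion_model_truth=bv.InclusionTruth(intercept=1.2, bc=1.0)),
    predict_to_censoring=True,
    n_boot=300, jackknife_groups=30)
report = bv.run_validation(config)

ranked = bv.compare_variants(report)
cols = ["variant", "EO_ratio", "slope", "AUC", "C"]
print("predictor variants ranked by Harrell's C "
      "(weighted, subgroup 'all'):")
print(ranked[cols].to_string(index=False,
                             float_format=lambda x: f"{x:.3f}"))
print()
print("E/O near 1 = good overall calibration; slope near 1 = risks "
      "correctly dispersed; AUC and C grow as informative factors "
      "(PV gene, PRS, QRFs, FH) enter the model.")
print()
strat = report.stratification
print("risk stratification under the full model:")
print(strat["table"][["threshold", "prop_below", "npv"]].to_string(
    index=False, float_format=lambda x: f"{x:.4f}"))
print(f"top-half case capture: {100 * strat['top_half_capture']:.1f}% "
      "of incident cancers occur in the half of carriers with the "
      "highest predicted risks")
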