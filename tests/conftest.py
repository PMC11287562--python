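import numpy as np
import pytest

import brcaval as bv


@pytest.fixture(scope="session")
def model():
    return bv.default_hazard_model()


@pytest.fixture(scope="session")
def profile():
    return bv.RiskFactorProfile(
        gene="BRCA1", prs_raw=0.187, prs_z=1.0,
        qrf_levels={"parity": "parous", "oc_use": "ever",
                    "bmi": "normal", "alcohol": "none"},
        fh_score=1)


def flat_model(lam: float, mu: float = 0.0, lo: float = 20.0,
               hi: float = 80.0) -> bv.HazardModel:
    """Single-band constant-hazard model for closed-form checks."""
    return bv.HazardModel(
        age_edges=np.array([lo, hi]),
        baseline_bc_incidence=np.array([lam]),
        competing_mortality=np.array([mu]),
        log_rr_gene={"BRCA1": np.zeros(1), "BRCA2": np.zeros(1)},
        log_rr_prs_per_sd=np.zeros(1),
        log_rr_qrf={"parity": {"nulliparous": 0.0, "parous": 0.0},
                    "oc_use": {"never": 0.0, "ever": 0.0},
                    "bmi": {"normal": 0.0, "overweight": 0.0, "obese": 0.0},
                    "alcohol": {"none": 0.0, "regular": 0.0}})


@pytest.fixture(scope="session")
def cohort_4k(model):
    """Medium synthetic cohort shared across tests."""
    config = bv.SimulationConfig(n_women=4000, seed=11)
    frame = bv.simulate_cohort_frame(config)
    return bv.simulate_subcohort_inclusion(
        frame, config.inclusion_model_truth, seed=11)
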