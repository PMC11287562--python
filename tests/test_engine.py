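"""Risk-engine unit and property tests: hazards, closed-form absolute
risks, window handling and the piecewise-consistency invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import brcaval as bv
from conftest import flat_model

NULL = bv.ModelVariant("null")
FULL = bv.FULL_VARIANT


def tiny_model(lam0=0.005):
    """Two-band model with hand-set relative hazards."""
    return bv.HazardModel(
        age_edges=np.array([20.0, 50.0, 80.0]),
        baseline_bc_incidence=np.array([lam0, lam0]),
        competing_mortality=np.array([0.0, 0.0]),
        log_rr_gene={"BRCA1": np.log([8.0, 8.0]),
                     "BRCA2": np.log([4.0, 4.0])},
        log_rr_prs_per_sd=np.log([1.5, 1.5]),
        log_rr_qrf={"bmi": {"normal": 0.0, "obese": np.log(1.2)}},
        log_rr_fh_per_relative=np.log(1.3))


def make_profile(**kw):
    base = dict(gene="BRCA1", prs_raw=0.0, prs_z=0.0,
                qrf_levels={"bmi": "normal"}, fh_score=0)
    base.update(kw)
    return bv.RiskFactorProfile(**base)


class TestHazardAtAge:
    def test_null_variant_is_baseline(self):
        m = tiny_model()
        for prof in (make_profile(), make_profile(gene="BRCA2", prs_z=2.0,
                                                  fh_score=3)):
            assert bv.hazard_at_age(prof, NULL, m, 40.0) == \
                pytest.approx(0.005, abs=0)

    def test_zero_prs_matches_prs_off(self):
        m = tiny_model()
        prof = make_profile(prs_z=0.0)
        on = bv.ModelVariant("g+p", use_gene=True, use_prs=True)
        off = bv.ModelVariant("g", use_gene=True)
        assert bv.hazard_at_age(prof, on, m, 35.0) == \
            bv.hazard_at_age(prof, off, m, 35.0)

    def test_hand_arithmetic_gene_times_prs(self):
        # 0.005 * 8 (gene) * 1.5 (one SD of PRS) = 0.06
        m = tiny_model()
        prof = make_profile(prs_z=1.0)
        v = bv.ModelVariant("gp", use_gene=True, use_prs=True)
        assert bv.hazard_at_age(prof, v, m, 40.0) == pytest.approx(
            0.06, rel=1e-12)

    def test_log_additivity_doubles(self):
        m = tiny_model()
        m2 = tiny_model()
        m2.log_rr_gene = {g: v + np.log(2.0)
                          for g, v in m.log_rr_gene.items()}
        prof = make_profile()
        v = bv.ModelVariant("g", use_gene=True)
        for age in (25.0, 45.0, 70.0):
            assert bv.hazard_at_age(prof, v, m2, age) == pytest.approx(
                2.0 * bv.hazard_at_age(prof, v, m, age), rel=1e-12)

    def test_age_outside_grid_raises(self):
        m = tiny_model()
        with pytest.raises(bv.InvalidParameterError):
            bv.hazard_at_age(make_profile(), NULL, m, 80.0)
        with pytest.raises(bv.InvalidParameterError):
            bv.hazard_at_age(make_profile(), NULL, m, 10.0)

    def test_unknown_qrf_category_raises(self):
        m = tiny_model()
        prof = make_profile(qrf_levels={"bmi": "unheard-of"})
        v = bv.ModelVariant("q", use_qrf=True)
        with pytest.raises(bv.SchemaError):
            bv.hazard_at_age(prof, v, m, 40.0)


class TestAbsoluteRisk:
    def test_constant_hazard_no_mortality(self):
        m = flat_model(0.02)
        r = bv.absolute_risk(make_profile(qrf_levels={}), NULL, m, 40, 45)
        assert r == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_constant_hazard_competing_mortality(self):
        m = flat_model(0.02, mu=0.01)
        r = bv.absolute_risk(make_profile(qrf_levels={}), NULL, m, 40, 45)
        expected = (0.02 / 0.03) * (1 - np.exp(-0.15))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_hazard_zero_risk(self):
        m = flat_model(0.0, mu=0.02)
        assert bv.absolute_risk(make_profile(qrf_levels={}), NULL, m,
                                30, 60) == 0.0

    def test_window_errors(self, model, profile):
        with pytest.raises(bv.InvalidParameterError):
            bv.absolute_risk(profile, FULL, model, 50, 50)
        with pytest.raises(bv.InvalidParameterError):
            bv.absolute_risk(profile, FULL, model, 76, 85)
        # clamping truncates instead
        r = bv.absolute_risk(profile, FULL, model, 76, 85, clamp=True)
        assert r == bv.absolute_risk(profile, FULL, model, 76, 80)

    def test_monotone_in_end_age(self, model, profile):
        ends = np.arange(41.0, 80.0, 2.7)
        risks = [bv.absolute_risk(profile, FULL, model, 40.0, e)
                 for e in ends]
        assert np.all(np.diff(risks) >= 0)

    def test_monotone_in_relative_hazard(self, model, profile):
        base = bv.absolute_risk(profile, FULL, model, 40, 45)
        bigger = bv.RiskFactorProfile(
            gene=profile.gene, prs_raw=profile.prs_raw, prs_z=2.0,
            qrf_levels=profile.qrf_levels, fh_score=profile.fh_score + 2)
        assert bv.absolute_risk(bigger, FULL, model, 40, 45) > base

    def test_risk_bounded_by_cumulative_hazard(self, model, profile):
        # 0 <= risk <= 1 - exp(-integral of lambda)
        s, e = 33.0, 71.0
        r = bv.absolute_risk(profile, FULL, model, s, e)
        grid = np.arange(s, e, 0.01)
        lam = np.array([bv.hazard_at_age(profile, FULL, model, a)
                        for a in grid])
        assert 0.0 <= r <= 1 - np.exp(-np.sum(lam * 0.01)) + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(21.0, 70.0), st.floats(0.5, 9.0), st.floats(0.1, 0.9))
    def test_chapman_kolmogorov(self, model, profile, start, span, frac):
        """risk(s,e) = risk(s,m) + surv(s,m) * risk(m,e) to 1e-12."""
        end = min(start + span, 80.0)
        mid = start + frac * (end - start)
        if mid <= start or mid >= end:
            return
        whole = bv.absolute_risk(profile, FULL, model, start, end)
        split = (bv.absolute_risk(profile, FULL, model, start, mid)
                 + bv.event_free_survival(profile, FULL, model, start, mid)
                 * bv.absolute_risk(profile, FULL, model, mid, end))
        assert whole == pytest.approx(split, abs=1e-12)

    def test_closed_form_matches_fine_grid_product_integral(self, model,
                                                            profile):
        s, e = 38.3, 52.9
        step = 0.001
        grid = s + step * np.arange(round((e - s) / step))
        lam = np.array([bv.hazard_at_age(profile, FULL, model, a)
                        for a in grid])
        k = model.band_index(grid)
        mu = model.competing_mortality[k]
        r = lam + mu
        h = r * step
        surv = np.exp(-(np.cumsum(h) - h))
        frac = np.divide(lam, r, out=np.zeros_like(lam), where=r > 0)
        oracle = float(np.sum(surv * frac * (-np.expm1(-h))))
        assert bv.absolute_risk(profile, FULL, model, s, e) == \
            pytest.approx(oracle, abs=1e-9)


@pytest.fixture(scope="module")
def prepared(model):
    rows = []
    for i, (age, exit_off, event) in enumerate(
            [(40.0, 6.0, "censored"), (40.0, 2.0, "censored"),
             (55.0, 3.0, "BC"), (30.0, 6.0, "censored")]):
        rows.append({"id": f"P{i}", "baseline_age": age,
                     "gene": "BRCA1", "prs_z": 0.0, "fh_score": 0,
                     "qrf_parity": "parous",
                     "exit_age": age + exit_off, "event": event})
    return pd.DataFrame(rows)


class TestPredictCohort:

    def test_censoring_truncation_shrinks_risk(self, prepared, model):
        full = bv.predict_cohort(prepared, [FULL], model)
        trunc = bv.predict_cohort(prepared, [FULL], model,
                                  predict_to_censoring=True)
        # woman 1 censored at baseline+2 (inside window)
        assert trunc.risks.iloc[1, 0] < full.risks.iloc[1, 0]
        # uncensored women unchanged
        assert trunc.risks.iloc[0, 0] == full.risks.iloc[0, 0]
        # the BC case keeps her full window (truncation is for censored)
        assert trunc.risks.iloc[2, 0] == full.risks.iloc[2, 0]

    def test_zero_prs_variants_identical(self, prepared, model):
        va = bv.ModelVariant("a", use_gene=True, use_prs=True)
        vb = bv.ModelVariant("b", use_gene=True)
        preds = bv.predict_cohort(prepared, [va, vb], model)
        np.testing.assert_allclose(preds.risks["a"], preds.risks["b"])

    def test_empty_variant_list_raises(self, prepared, model):
        with pytest.raises(bv.InvalidParameterError):
            bv.predict_cohort(prepared, [], model)

    def test_matches_scalar_absolute_risk(self, prepared, model):
        preds = bv.predict_cohort(prepared, [FULL], model)
        prof = bv.RiskFactorProfile(gene="BRCA1", prs_raw=0.0, prs_z=0.0,
                                    qrf_levels={"parity": "parous"},
                                    fh_score=0)
        expected = bv.absolute_risk(prof, FULL, model, 41.0, 46.0)
        assert preds.risks.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_long_export_round_trip(self, prepared, model, tmp_path):
        preds = bv.predict_cohort(prepared, list(bv.DEFAULT_VARIANTS),
                                  model)
        path = tmp_path / "preds.csv"
        preds.to_csv(path)
        # keep_default_na: the age-only variant is literally named "null"
        back = pd.read_csv(path, keep_default_na=False)
        assert set(back["variant"]) == {v.name for v in bv.DEFAULT_VARIANTS}
        assert len(back) == len(prepared) * len(bv.DEFAULT_VARIANTS)
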