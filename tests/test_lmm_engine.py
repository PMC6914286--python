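import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mediboot import (
    ContractError,
    InputError,
    ModelSpec,
    TrialDataset,
    difference_of_change,
    fit_lmm,
)
from mediboot.synthetic_trial import SyntheticSpec, generate

from conftest import complete_two_arm, make_dataset


def did_of_cell_means(ds, variable="y"):
    w = ds.wide([variable])
    cell = w.groupby(["arm", "timepoint"])[variable].mean()
    return (cell[1, 1] - cell[1, 0]) - (cell[0, 1] - cell[0, 0])


class TestDidOracle:
    def test_toy_interaction_equals_did(self, did_toy):
        fit = fit_lmm(did_toy, ModelSpec(outcome="y"))
        assert fit.converged
        assert fit.coefficients["group:time"].estimate == pytest.approx(3.0, abs=1e-8)

    def test_flat_data_zero_interaction(self, flat_toy):
        fit = fit_lmm(flat_toy, ModelSpec(outcome="y"))
        est = difference_of_change(fit)
        assert est.beta == pytest.approx(0.0, abs=1e-10)
        assert est.p_value == pytest.approx(1.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        st.lists(st.floats(-5, 5), min_size=12, max_size=12),
    )
    @settings(max_examples=20)
    def test_interaction_equals_did_on_any_balanced_data(self, cells, noise):
        # 3 complete subjects per arm; estimate must equal the DiD of the
        # four observed cell means whatever the variance components are.
        c00, c01, c10, c11 = cells
        vals, k = {}, 0
        for j in range(3):
            vals[f"c{j}"] = (0, c00 + noise[k], c01 + noise[k + 1])
            vals[f"e{j}"] = (1, c10 + noise[k + 2], c11 + noise[k + 3])
            k += 4
        ds = complete_two_arm(vals)
        fit = fit_lmm(ds, ModelSpec(outcome="y"))
        assert fit.coefficients["group:time"].estimate == pytest.approx(
            did_of_cell_means(ds), abs=1e-8
        )

    def test_parameter_recovery_large_n(self):
        ds = generate(SyntheticSpec(n_exercise=2000, n_control=2000,
                                    a_effect=-1.5, seed=21))
        fit = fit_lmm(ds, ModelSpec(outcome="mediator"))
        est = difference_of_change(fit)
        assert est.beta == pytest.approx(-1.5, abs=3 * est.se)


class TestModelStructure:
    def test_constant_shift_moves_only_intercept(self, did_toy):
        fit0 = fit_lmm(did_toy, ModelSpec(outcome="y"))
        shifted = TrialDataset(
            did_toy.data.assign(value=did_toy.data["value"] + 100.0),
            dict(did_toy.roles),
        )
        fit1 = fit_lmm(shifted, ModelSpec(outcome="y"))
        assert fit1.coefficients["intercept"].estimate == pytest.approx(
            fit0.coefficients["intercept"].estimate + 100.0, abs=1e-4
        )
        for term in ("group", "time", "group:time"):
            assert fit1.coefficients[term].estimate == pytest.approx(
                fit0.coefficients[term].estimate, abs=1e-4
            )

    def test_compound_symmetry_marginal_covariance(self):
        ds = generate(SyntheticSpec(seed=4))
        fit = fit_lmm(ds, ModelSpec(outcome="outcome"))
        V = fit.marginal_covariance()
        assert V[0, 0] == pytest.approx(V[1, 1])
        assert V[0, 1] == pytest.approx(fit.tau2)
        assert V[0, 0] == pytest.approx(fit.tau2 + fit.sigma2[0])

    def test_reml_and_ml_agree_on_balanced_complete_data(self):
        ds = generate(SyntheticSpec(dropout_per_arm=0, seed=13))
        reml = fit_lmm(ds, ModelSpec(outcome="outcome", method="reml"))
        ml = fit_lmm(ds, ModelSpec(outcome="outcome", method="ml"))
        for term in reml.coefficients:
            assert ml.coefficients[term].estimate == pytest.approx(
                reml.coefficients[term].estimate, abs=1e-6
            )

    def test_aic_requires_ml(self):
        ds = generate(SyntheticSpec(seed=4))
        reml = fit_lmm(ds, ModelSpec(outcome="outcome"))
        with pytest.raises(ContractError):
            _ = reml.aic
        ml = fit_lmm(ds, ModelSpec(outcome="outcome", method="ml"))
        assert np.isfinite(ml.aic)

    def test_heteroscedastic_mode_fits_and_matches_did(self):
        ds = generate(SyntheticSpec(seed=30, dropout_per_arm=0))
        cs = fit_lmm(ds, ModelSpec(outcome="outcome"))
        het = fit_lmm(
            ds, ModelSpec(outcome="outcome", covariance_mode="heteroscedastic_time")
        )
        assert het.converged
        # balanced complete: the interaction estimate is weight-invariant
        assert het.coefficients["group:time"].estimate == pytest.approx(
            cs.coefficients["group:time"].estimate, abs=1e-6
        )

    def test_wald_inference_is_normal_based(self, did_toy):
        fit = fit_lmm(did_toy, ModelSpec(outcome="y"))
        c = fit.coefficients["group:time"]
        assert c.p_value == pytest.approx(2 * stats.norm.sf(abs(c.estimate / c.se)))
        lo, hi = c.ci95
        assert lo < c.estimate < hi


class TestAgainstStatsmodels:
    """The dedicated solver must agree with an independent general-purpose
    mixed-model implementation on realistic (unbalanced) data."""

    @pytest.mark.parametrize("with_mediator", [False, True])
    def test_estimates_and_ses_match_mixedlm(self, with_mediator):
        smf = pytest.importorskip("statsmodels.formula.api")
        ds = generate(SyntheticSpec(seed=3))  # includes 1 dropout per arm
        spec = ModelSpec(
            outcome="outcome", mediator="mediator" if with_mediator else None
        )
        fit = fit_lmm(ds, spec)
        w = ds.wide(["mediator", "outcome"]).dropna(
            subset=["outcome"] + (["mediator"] if with_mediator else [])
        )
        w["gxt"] = w["arm"] * w["timepoint"]
        formula = "outcome ~ arm + timepoint + gxt"
        if with_mediator:
            formula += " + mediator"
        ref = smf.mixedlm(formula, w, groups=w["subject_id"]).fit(reml=True)
        name_map = {
            "intercept": "Intercept", "group": "arm", "time": "timepoint",
            "group:time": "gxt", "mediator": "mediator",
        }
        for term, c in fit.coefficients.items():
            assert c.estimate == pytest.approx(
                ref.params[name_map[term]], abs=1e-4
            ), term
            assert c.se == pytest.approx(ref.bse_fe[name_map[term]], rel=1e-3), term
        assert fit.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2[0] == pytest.approx(float(ref.scale), rel=1e-3)


class TestErrors:
    def test_unknown_variable(self, did_toy):
        with pytest.raises(InputError):
            fit_lmm(did_toy, ModelSpec(outcome="nope"))

    def test_unapplied_log_transform_rejected(self):
        ds = make_dataset(
            [(f"S{i}", i % 2, t, "crp", 1.0 + i + t)
             for i in range(6) for t in (0, 1)],
            roles={"crp": "outcome"},
            transforms={"crp": "log"},
        )
        with pytest.raises(ContractError, match="log transform"):
            fit_lmm(ds, ModelSpec(outcome="crp"))
        fit = fit_lmm(ds.apply_transforms(), ModelSpec(outcome="crp"))
        assert fit.converged

    def test_missing_group_time_term(self):
        ds = generate(SyntheticSpec(seed=4))
        fit = fit_lmm(
            ds,
            ModelSpec(outcome="outcome", mediator="mediator",
                      include_group_terms=False),
        )
        with pytest.raises(ContractError):
            difference_of_change(fit)
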