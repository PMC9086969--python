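"""Regression suite: closed-form oracles, an independent IRLS check, model
nesting and generator-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from conftest import attach_oracle_pgs
from pgscohort.riskmodels import (
    DataError,
    ParameterError,
    bonferroni_threshold,
    compare_prevalence_models,
    comparison_registry,
    cox_snell_r2,
    fh_pgs_association,
    fit_aod_model,
    fit_incidence_model,
    fit_logistic,
    fit_prediabetes_model,
    fit_severity_models,
    significance_report,
)
from pgscohort.synthetic_cohort import (
    PhenotypeParams,
    SimConfig,
    generate_cohort,
)


def irls_logistic(X, y, n_iter=60):
    """Independent iteratively-reweighted least-squares oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        beta = np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (W * z))
    return beta


class TestFitLogistic:
    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.repeat([1.0, 0.0], [200, 800])
        fit = fit_logistic(y, pd.DataFrame(index=range(1000)))
        assert fit.params["const"] == pytest.approx(np.log(0.25), abs=1e-6)

    def test_single_binary_predictor_equals_hand_log_or(self):
        # 2x2 table: exposed 20/80, unexposed 10/90 -> OR = 2.25
        y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(np.log(2.25), abs=1e-6)

    def test_agrees_with_independent_irls(self):
        rng = np.random.default_rng(17)
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = int(r.integers(200, 1000))
            X = r.normal(size=(n, 3))
            eta = 0.3 * X[:, 0] - 0.5 * X[:, 1]
            y = (r.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(y, pd.DataFrame(X, columns=list("abc")))
            Xc = np.column_stack([np.ones(n), X])
            ref = irls_logistic(Xc, y)
            assert np.allclose(fit.params.to_numpy(), ref, atol=1e-6)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(DataError):
            fit_logistic(np.ones(50), pd.DataFrame({"x": np.arange(50.0)}))

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert not fit.converged
        assert fit.diagnostic != ""

    def test_constant_column_rejected(self):
        with pytest.raises(DataError):
            fit_logistic(np.r_[np.ones(5), np.zeros(5)],
                         pd.DataFrame({"x": np.ones(10)}))


class TestCoxSnell:
    def test_equal_likelihoods_zero(self):
        assert cox_snell_r2(-50.0, -50.0, 100) == 0.0

    def test_hand_arithmetic(self):
        assert cox_snell_r2(-100.0, -90.0, 100) == pytest.approx(
            1 - np.exp(-0.2), abs=1e-12)

    def test_monotone_in_model_likelihood(self):
        vals = [cox_snell_r2(-100.0, ll, 100) for ll in (-99.0, -95.0, -80.0)]
        assert vals == sorted(vals)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            cox_snell_r2(-10.0, -5.0, 0)
        with pytest.raises(ParameterError):
            cox_snell_r2(-5.0, -10.0, 100)


class TestBonferroni:
    def test_study_threshold(self):
        thr = bonferroni_threshold(0.05, 28)
        assert f"{thr:.2g}" == "0.0018"

    def test_identity_and_hand_value(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)

    def test_registry_has_28_labelled_comparisons(self):
        reg = comparison_registry()
        assert len(reg) == len(set(reg)) == 28
        rep = significance_report({"fh~pgs_std": 1e-5})
        assert rep["significant"].sum() == 1
        assert (rep["threshold"] == 0.05 / 28).all()


class TestModelComparison:
    def test_table_shape_and_nesting(self, signal_sim):
        cohort, _, _, _ = signal_sim
        comp = compare_prevalence_models(cohort, seed=1, n_boot=100)
        assert set(comp.fits) == {"base", "fh_only", "pgs_only", "combined"}
        for term in ("female", "decade_of_age", "logbmi_std"):
            assert term in comp.fits["base"].params.index
        ll = {k: f.llf for k, f in comp.fits.items()}
        assert ll["combined"] >= ll["fh_only"] - 1e-6
        assert ll["combined"] >= ll["pgs_only"] - 1e-6
        assert min(ll["fh_only"], ll["pgs_only"]) >= ll["base"] - 1e-6
        r2 = comp.cox_snell
        assert r2["combined"] >= max(r2["fh_only"], r2["pgs_only"]) - 1e-9
        assert comp.split["n_train"] + comp.split["n_test"] == comp.fits["base"].n + comp.split["n_test"]

    def test_identical_training_rows_across_fits(self, signal_sim):
        cohort, _, _, _ = signal_sim
        comp = compare_prevalence_models(cohort, seed=2, n_boot=0)
        ns = {f.n for f in comp.fits.values()}
        assert len(ns) == 1

    def test_degenerate_pgs_collapses_onto_base(self, signal_sim):
        cohort, _, _, _ = signal_sim
        flat = cohort.copy()
        flat["pgs_std"] = 1.0
        comp = compare_prevalence_models(flat, seed=3, n_boot=0)
        assert comp.fits["pgs_only"].llf == pytest.approx(
            comp.fits["base"].llf, abs=1e-6)

    def test_minimum_size_guard(self, signal_sim):
        cohort, _, _, _ = signal_sim
        with pytest.raises(DataError):
            compare_prevalence_models(cohort.head(50), seed=0, n_boot=0)


class TestAssociations:
    def test_fh_pgs_or_positive_under_signal(self, signal_sim):
        cohort, _, _, _ = signal_sim
        fit = fh_pgs_association(cohort)
        assert np.exp(fit.params["pgs_std"]) > 1.0
        assert fit.pvalues["pgs_std"] < 0.0018

    def test_fh_pgs_or_null(self, null_sim):
        cohort, _, _, _ = null_sim
        fit = fh_pgs_association(cohort)
        lo, hi = np.exp(fit.conf_int.loc["pgs_std"])
        assert lo <= 1.0 <= hi

    def test_fh_or_invariant_to_affine_raw_rescale(self, signal_sim):
        cohort, _, _, _ = signal_sim
        shifted = cohort.copy()
        shifted["pgs_std"] = 3.0 * cohort["pgs_std"] + 7.0
        a = fh_pgs_association(cohort).params["pgs_std"]
        b = fh_pgs_association(shifted).params["pgs_std"]
        assert a == pytest.approx(b, abs=1e-8)

    def test_aod_model_sign_and_permutation_null(self, signal_sim):
        cohort, _, _, _ = signal_sim
        cases = cohort[cohort["t2d_status"] == "case"]
        fit = fit_aod_model(cases)
        assert fit.params["pgs_std"] < 0
        rng = np.random.default_rng(12)
        perm = cases.copy()
        perm["aod"] = rng.permutation(perm["aod"].to_numpy())
        pfit = fit_aod_model(perm)
        lo, hi = pfit.conf_int.loc["pgs_std"]
        assert lo <= 0.0 <= hi

    def test_aod_model_guards(self, signal_sim):
        cohort, _, _, _ = signal_sim
        with pytest.raises(DataError):
            fit_aod_model(cohort)  # contains controls

    def test_prediabetes_model_guard_and_signal(self, signal_sim):
        cohort, _, _, _ = signal_sim
        with pytest.raises(DataError):
            fit_prediabetes_model(cohort)
        controls = cohort[cohort["t2d_status"] == "control"]
        fit = fit_prediabetes_model(controls)
        assert np.exp(fit.params["pgs_std"]) > 1.0

    def test_incidence_window_filter(self, signal_sim):
        cohort, _, _, _ = signal_sim
        n0 = fit_incidence_model(cohort).n
        df = cohort.copy()
        followed = df["incident_t2d"].isin(["yes", "no"])
        fh_known = df["fh_t2d"].isin(["positive", "negative"])
        idx = df.index[followed & fh_known][:4]
        # 400 and 800 days stay inside (365, 730]... 800 does not: only 400
        # survives; 100 and 900 are dropped as well
        df.loc[idx, "followup_days"] = [100, 400, 800, 900]
        assert fit_incidence_model(df).n == n0 - 3

    def test_incidence_requires_events(self, signal_sim):
        cohort, _, _, _ = signal_sim
        quiet = cohort.copy()
        quiet.loc[quiet["incident_t2d"] == "yes", "incident_t2d"] = "no"
        with pytest.raises(DataError):
            fit_incidence_model(quiet)


@pytest.fixture(scope="module")
def severity_sim():
    # strong insulin signal, all other severity slopes null
    pp = PhenotypeParams(prevalence=0.2)
    pp.treatment_params = {"insulin": (0.25, 0.5, 0.0),
                           "metformin": (0.55, 0.0, 0.0),
                           "lifestyle_only": (0.25, 0.0, 0.0)}
    pp.complication_params = {"neuropathy": (0.15, 0.0, 0.08),
                              "nephropathy": (0.05, 0.0, 0.0),
                              "retinopathy": (0.06, 0.0, 0.0)}
    cfg = SimConfig(n=30_000, m_snps=150, n_causal=40, h2_snp=0.5,
                    c2_shared=0.0, seed=23, pheno=pp)
    cohort, _, _, truth = generate_cohort(cfg)
    cohort = attach_oracle_pgs(cohort, truth)
    return cohort[cohort["t2d_status"] == "case"], truth


class TestSeverity:
    def test_six_models_fit(self, severity_sim):
        cases, _ = severity_sim
        fits = fit_severity_models(cases)
        assert set(fits) == {"insulin", "metformin", "lifestyle_only",
                             "neuropathy", "nephropathy", "retinopathy"}
        assert "years_since_dx" in fits["neuropathy"].params.index
        assert "years_since_dx" not in fits["insulin"].params.index

    def test_selective_signal_recovery(self, severity_sim):
        # insulin is the only treatment with a liability slope: it should be
        # clearly significant while metformin stays null
        cases, truth = severity_sim
        oracle = cases.copy()
        liab = truth.table.set_index("participant_id").loc[
            cases["participant_id"], "liability"].to_numpy()
        oracle["pgs_std"] = (liab - liab.mean()) / liab.std()
        fits = fit_severity_models(oracle)
        assert fits["insulin"].pvalues["pgs_std"] < 0.0018
        assert np.exp(fits["insulin"].params["pgs_std"]) > 1.0
        lo, hi = np.exp(fits["metformin"].conf_int.loc["pgs_std"])
        assert lo <= 1.0 <= hi

    def test_duration_effect_positive(self, severity_sim):
        cases, _ = severity_sim
        fits = fit_severity_models(cases)
        assert fits["neuropathy"].params["years_since_dx"] > 0
        assert fits["neuropathy"].pvalues["years_since_dx"] < 0.0018

    def test_controls_rejected(self, signal_sim):
        cohort, _, _, _ = signal_sim
        with pytest.raises(DataError):
            fit_severity_models(cohort)
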