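"""NLME estimation: Laplace OFV, fitting, diagnostics, bootstrap, VPC."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from meropopk.estimation import (
    PARAM_NAMES,
    EstimationResult,
    _Batch,
    _laplace_batch,
    _subject_ofv_laplace,
    bootstrap,
    compare_nested,
    covariate_scan,
    cwres,
    eta_shrinkage,
    fit,
    ofv,
    ofv_quadrature,
    subjects_from_dataframe,
    vpc_pvc,
)
from meropopk.synthetic import StudyDesign, generate_cohort, generate_study


def toy_dataset(model, n_obs=3, seed=3):
    """Single-subject record with ``n_obs`` usable observations."""
    design = StudyDesign(n_subjects=1)
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(design, rng)
    df = generate_study(model, cohort, design, rng)
    obs_idx = df.index[
        (df.event_type == "observation") & (~df.below_lloq)
    ]
    keep = df.index.isin(obs_idx[:n_obs]) | (df.event_type == "dose")
    return df[keep]


class TestLaplaceOFV:
    @pytest.mark.parametrize("n_obs", [2, 3, 4])
    def test_matches_quadrature_oracle_one_eta(self, model, n_obs):
        """64-node adaptive Gauss-Hermite vs Laplace on 1-eta toy problems."""
        toy_model = model.with_updates(omega_vc=0.0, omega_vp=0.0)
        df = toy_dataset(toy_model, n_obs=n_obs)
        lap = ofv(toy_model, df)
        quad = ofv_quadrature(toy_model, df, n_nodes=64)
        assert abs(lap - quad) < 0.1

    def test_batched_engine_agrees_with_per_subject_reference(self, model, study8):
        """The vectorised all-subjects Newton must equal the independent
        per-subject scipy-BFGS Laplace path."""
        subjects, _ = subjects_from_dataframe(study8)
        total_batch, eta_batch, _ = _laplace_batch(model, _Batch(subjects))
        total_ref = 0.0
        for i, subj in enumerate(subjects):
            val, eta_ref, _ = _subject_ofv_laplace(subj, model)
            total_ref += val
            np.testing.assert_allclose(eta_batch[i], eta_ref, atol=1e-4)
        assert total_batch == pytest.approx(total_ref, abs=1e-3)

    def test_zero_omega_limit_is_naive_pooled(self, model):
        pooled = model.with_updates(omega_cl=0.0, omega_vc=0.0, omega_vp=0.0)
        df = toy_dataset(pooled, n_obs=4)
        subjects, _ = subjects_from_dataframe(df)
        subj = subjects[0]
        f = subj.predict(
            max(pooled.theta_cl * (1 + pooled.theta_cov * (subj.ce - pooled.ce_ref)), 0.01),
            pooled.vc, pooled.vp, pooled.q,
        )
        g2 = (pooled.sigma_prop * f**pooled.power) ** 2
        expected = float(np.sum(np.log(g2) + (subj.obs_conc - f) ** 2 / g2))
        assert ofv(pooled, df) == pytest.approx(expected, abs=1e-6)

    def test_unknown_method_rejected(self, model, study8):
        with pytest.raises(ValueError):
            ofv(model, study8, method="saem")


class TestFit:
    def test_freeing_a_parameter_never_raises_ofv(self, model, study8):
        """Nested-model monotonicity: OFV(theta2 free) <= OFV(theta2 fixed)."""
        fixed_common = ("vc", "q", "vp", "omega_vc", "omega_vp", "power")
        free_fit = fit(model, study8, fixed=fixed_common, maxiter=60)
        fixed_fit = fit(model, study8, fixed=fixed_common + ("theta_cov",), maxiter=60)
        assert free_fit.ofv <= fixed_fit.ofv + 1e-6

    def test_recovers_truth_from_perturbed_start(self, model):
        df = make_study(model, 26, seed=515)
        start = model.with_updates(
            theta_cl=4.0, theta_cov=0.003, vc=12.0, q=8.0, vp=6.0,
            omega_cl=0.5, omega_vc=0.3, omega_vp=0.3, sigma_prop=0.3,
        )
        res = fit(start, df, fixed=("power",), maxiter=150)
        assert res.estimates.theta_cl == pytest.approx(6.37, rel=0.20)

    def test_all_fixed_is_evaluation_only(self, model, study8):
        res = fit(model, study8, fixed=PARAM_NAMES)
        assert res.convergence["iterations"] == 0
        assert res.ofv == pytest.approx(ofv(model, study8), abs=1e-9)

    def test_unknown_fixed_name_rejected(self, model, study8):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit(model, study8, fixed=("not_a_param",))


class TestCompareNested:
    def test_forward_inclusion_threshold(self):
        out = compare_nested(100.0, 106.64, df=1)
        assert out["significant"]["forward p<0.01 (1 df)"]

    def test_boundary_is_strict(self):
        # delta exactly equal to the threshold is not significant
        out = compare_nested(0.0, 3.84, df=1)
        assert not out["significant"]["p<0.05 (1 df)"]

    def test_identical_models_not_significant(self):
        out = compare_nested(100.0, 100.0, df=1)
        assert out["delta_ofv"] == 0.0
        assert not any(out["significant"].values())

    def test_two_df_threshold(self):
        assert compare_nested(100.0, 106.0, df=2)["significant"]["p<0.05 (2 df)"]

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            compare_nested(1.0, 2.0, df=0)


class TestCovariateScan:
    def test_true_covariate_found_noise_covariate_not(self, model):
        df = make_study(model, 14, seed=88)
        noise_map = dict(
            zip(
                df.subject_id.unique(),
                np.random.default_rng(1).normal(100, 25, df.subject_id.nunique()),
            )
        )
        df = df.assign(cystatin_c=df.subject_id.map(noise_map))
        base = fit(
            model.with_updates(theta_cov=0.0), df,
            fixed=("theta_cov", "power"), maxiter=60,
        )
        table = covariate_scan(base, df, ["ce", "cystatin_c"], maxiter=40)
        row_ce = table.set_index("covariate").loc["ce"]
        row_noise = table.set_index("covariate").loc["cystatin_c"]
        assert row_ce["significant_forward"]
        assert row_noise["delta_ofv"] < row_ce["delta_ofv"]

    def test_constant_column_skipped_with_warning(self, model, study8, caplog):
        df = study8.assign(albumin=3.0)
        base = fit(model, study8, fixed=PARAM_NAMES)
        with caplog.at_level("WARNING"):
            table = covariate_scan(base, df, ["albumin"])
        assert table.empty
        assert "constant covariate" in caplog.text

    def test_missing_column_rejected(self, model, study8):
        base = fit(model, study8, fixed=PARAM_NAMES)
        with pytest.raises(ValueError, match="not in dataset"):
            covariate_scan(base, study8, ["bogus"])


class TestCWRES:
    def test_calibrated_under_true_model(self, model):
        """Under self-simulated data CWRES are ~N(0,1)."""
        df = make_study(model, 75, seed=42)
        res = fit(model, df, fixed=PARAM_NAMES)
        table = cwres(res, df)
        assert len(table) > 400
        assert abs(table["cwres"].mean()) < 0.1
        assert 0.8 <= table["cwres"].std() <= 1.2
        assert (table["cwres"].abs() <= 3).mean() >= 0.95

    def test_zero_residual_limit(self, model):
        quiet = model.with_updates(
            omega_cl=0.0, omega_vc=0.0, omega_vp=0.0, sigma_prop=0.0
        )
        df = make_study(quiet, 3, seed=5)
        # evaluate with a tiny-but-positive residual SD so weights exist
        eval_model = quiet.with_updates(sigma_prop=1e-3)
        res = fit(eval_model, df, fixed=PARAM_NAMES)
        table = cwres(res, df)
        assert table["cwres"].abs().max() < 1e-6


class TestShrinkage:
    def _result(self, model, ebe):
        return EstimationResult(
            estimates=model, ofv=0.0, se_rse={}, ebe=ebe, shrinkage={},
            convergence={},
        )

    def test_no_information_is_full_shrinkage(self, model):
        ebe = pd.DataFrame(np.zeros((5, 3)), columns=["eta_cl", "eta_vc", "eta_vp"])
        out = eta_shrinkage(self._result(model, ebe))
        assert out["eta_cl"] == pytest.approx(100.0)

    def test_sd_equal_omega_is_zero_shrinkage(self, model):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, 2000)
        draws = (draws - draws.mean()) / draws.std(ddof=0)
        ebe = pd.DataFrame(
            {
                "eta_cl": draws * model.omega_cl,
                "eta_vc": draws * model.omega_vc,
                "eta_vp": draws * model.omega_vp,
            }
        )
        out = eta_shrinkage(self._result(model, ebe))
        assert out["eta_cl"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_omega_reported_missing(self, model):
        m0 = model.with_updates(omega_vc=0.0)
        ebe = pd.DataFrame(np.zeros((3, 3)), columns=["eta_cl", "eta_vc", "eta_vp"])
        assert np.isnan(eta_shrinkage(self._result(m0, ebe))["eta_vc"])

    def test_needs_two_subjects(self, model):
        ebe = pd.DataFrame(np.zeros((1, 3)), columns=["eta_cl", "eta_vc", "eta_vp"])
        with pytest.raises(ValueError):
            eta_shrinkage(self._result(model, ebe))


class TestBootstrap:
    def test_zero_reps_rejected(self, model, study8):
        with pytest.raises(ValueError):
            bootstrap(study8, model, 0, np.random.default_rng(0))

    def test_fixed_seed_reproducible(self, model, study8):
        fixed = tuple(p for p in PARAM_NAMES if p not in ("theta_cl", "omega_cl"))
        a = bootstrap(study8, model, 2, np.random.default_rng(6), fixed=fixed, maxiter=25)
        b = bootstrap(study8, model, 2, np.random.default_rng(6), fixed=fixed, maxiter=25)
        pd.testing.assert_frame_equal(a, b)

    def test_point_estimate_inside_central_band(self, model, study8):
        fixed = tuple(p for p in PARAM_NAMES if p not in ("theta_cl", "omega_cl"))
        summary = bootstrap(
            study8, model, 6, np.random.default_rng(13), fixed=fixed, maxiter=25
        )
        assert summary.loc["theta_cl", "ci_lower"] < 6.37 * 1.5
        assert summary.loc["theta_cl", "ci_upper"] > 6.37 * 0.5


class TestVPC:
    def test_self_simulated_coverage(self, model):
        df = make_study(model, 40, seed=99)
        res = fit(model, df, fixed=PARAM_NAMES)
        out = vpc_pvc(res, df, n_sim=200, rng=np.random.default_rng(12))
        inside = (
            (out.observed_pctl["p50"] >= out.simulated_ci["p50_lo"])
            & (out.observed_pctl["p50"] <= out.simulated_ci["p50_hi"])
        )
        assert inside.mean() >= 0.8

    def test_percentiles_ordered(self, model):
        df = make_study(model, 20, seed=100)
        res = fit(model, df, fixed=PARAM_NAMES)
        out = vpc_pvc(res, df, n_sim=120, rng=np.random.default_rng(13))
        assert (out.observed_pctl["p10"] <= out.observed_pctl["p50"]).all()
        assert (out.observed_pctl["p50"] <= out.observed_pctl["p90"]).all()

    def test_too_few_replicates_rejected(self, model, study8):
        res = fit(model, study8, fixed=PARAM_NAMES)
        with pytest.raises(ValueError):
            vpc_pvc(res, study8, n_sim=1)
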