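"""SAEM estimator: M-step oracle, determinism, likelihood machinery, LRT."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from popkit import (
    Observation,
    PKDataset,
    PopulationModel,
    SAEMConfig,
    Subject,
    compare_error_models,
    conc_steady_state,
    estimate_loglik_is,
    fit_saem,
    loglik_conditional,
    logprior_eta,
    lrt,
)
from popkit.exceptions import EstimationError, ValidationError
from popkit.saem import _mstep_mu_omega, _Problem
from popkit.structural import StructuralParams


def rich_dataset(
    n_subjects=50,
    omega_sd=0.0,
    a=0.01,
    seed=0,
    theta=(0.32, 1.88, 1.20),
    times=(0.5, 1.0, 2.0, 4.0, 8.0, 24.0),
) -> PKDataset:
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n_subjects):
        eta = rng.normal(0.0, omega_sd, size=3) if omega_sd else np.zeros(3)
        psi = StructuralParams(
            theta[0] * math.exp(eta[0]), theta[1] * math.exp(eta[1]), theta[2] * math.exp(eta[2])
        )
        obs = []
        for t in times:
            c = conc_steady_state(psi, 75000.0, 24.0, t) + rng.normal(0.0, a)
            obs.append(Observation(t, max(c, 1e-6)))
        subs.append(Subject(id=f"s{i}", group="G", dose=75000.0, observations=obs))
    return PKDataset(subjects=subs, groups=("G",), reference="G")


class TestValidation:
    def test_empty_dataset(self):
        with pytest.raises((ValidationError, ValueError)):
            fit_saem(PKDataset(subjects=[]), None, SAEMConfig(k1=5, k2=5))

    def test_single_subject_rejected(self):
        ds = rich_dataset(n_subjects=1)
        with pytest.raises(ValidationError):
            fit_saem(ds, None, SAEMConfig(k1=5, k2=5))

    def test_single_time_point_non_identifiable(self):
        ds = rich_dataset(n_subjects=10, times=(2.0,))
        with pytest.raises(EstimationError, match="non-identifiable"):
            fit_saem(ds, None, SAEMConfig(k1=5, k2=5))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SAEMConfig(k1=0)
        with pytest.raises(ValidationError):
            SAEMConfig(proposal_scales=(0.0, 0.1, 0.1))
        with pytest.raises(ValidationError):
            SAEMConfig(blq_policy="nope")


class TestMStepOracle:
    def test_closed_form_matches_numerical_maximum(self):
        """On frozen phi draws, the GLS/moment M-step must equal direct
        numerical maximisation of the complete-data Gaussian layer."""
        rng = np.random.default_rng(4)
        ds, _ = _paper_like(seed=4)
        prob = _Problem(ds, SAEMConfig())
        n, q = prob.n, prob.q
        phi = prob.mean_phi(_mu_at_truth(prob)) + 0.3 * rng.standard_normal((n, 3))
        s2 = phi.T @ phi
        mu_hat, om_hat = _mstep_mu_omega(
            phi, s2, prob, np.zeros(q), np.eye(3), diagonal=False
        )

        def negloglik(x):
            mu = x[:q]
            L = np.zeros((3, 3))
            idx = q
            for i in range(3):
                for j in range(i + 1):
                    L[i, j] = x[idx] if i != j else math.exp(x[idx])
                    idx += 1
            om = L @ L.T
            resid = phi - prob.mean_phi(mu)
            w_inv = np.linalg.inv(om)
            _, logdet = np.linalg.slogdet(om)
            quad = np.einsum("ij,jk,ik->", resid, w_inv, resid)
            return 0.5 * (n * logdet + quad)

        L0 = np.linalg.cholesky(om_hat)
        x0 = np.concatenate(
            [mu_hat, [math.log(L0[0, 0]), L0[1, 0], math.log(L0[1, 1]),
                      L0[2, 0], L0[2, 1], math.log(L0[2, 2])]]
        )
        sol = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxfev": 20000})
        # closed form must already be the maximum to high accuracy
        assert negloglik(x0) <= sol.fun + 1e-6
        assert np.allclose(sol.x[:q], mu_hat, atol=1e-5)

    def test_additive_error_mstep_is_rms(self):
        from popkit.saem import _mstep_error

        r2 = np.array([1.0, 4.0, 9.0])
        a, b = _mstep_error("additive", r2, r2, r2, 1.0, 0.0)
        assert a == pytest.approx(math.sqrt(np.mean(r2)))
        assert b == 0.0

    def test_proportional_error_mstep(self):
        from popkit.saem import _mstep_error

        r2 = np.array([1.0, 4.0])
        f2 = np.array([25.0, 100.0])
        a, b = _mstep_error("proportional", r2, f2, r2 / f2, 0.0, 0.1)
        assert b == pytest.approx(math.sqrt(np.mean(r2 / f2)))

    def test_combined_error_mstep_maximises(self):
        from popkit.saem import _mstep_error

        rng = np.random.default_rng(0)
        f2 = rng.uniform(1.0, 900.0, size=200)
        var_true = 4.0 + 0.01 * f2
        r2 = var_true * rng.chisquare(1, size=200)
        a, b = _mstep_error("combined", r2, f2, r2 / f2, 1.0, 0.05)

        def nll(a_, b_):
            var = a_**2 + b_**2 * f2
            return np.sum(0.5 * np.log(var) + r2 / (2 * var))

        base = nll(a, b)
        for da in (-0.05, 0.05):
            for db in (-0.01, 0.01):
                assert base <= nll(a + da, b + db) + 1e-6


def _paper_like(seed):
    from popkit import default_paper_design, default_truth, simulate_study

    return simulate_study(default_paper_design(), default_truth(), seed)


def _mu_at_truth(prob):
    from popkit import default_truth

    tm = default_truth().model
    mu = np.zeros(prob.q)
    mu[0] = math.log(0.32)
    mu[prob.q - 2] = math.log(1.88)
    mu[prob.q - 1] = math.log(1.20)
    for i, g in enumerate(prob.nonref):
        mu[1 + i] = tm.beta[g]
    return mu


class TestFitRichData:
    def test_near_noiseless_identifiability(self):
        # 50 subjects x 6 rich times, no BSV, tiny noise: recovery within 1%
        ds = rich_dataset(n_subjects=50, omega_sd=0.0, a=0.01, seed=1)
        cfg = SAEMConfig(k1=100, k2=50, seed=1, compute_loglik=False)
        fit = fit_saem(ds, None, cfg)
        for est, true in zip(fit.model.theta, (0.32, 1.88, 1.20)):
            assert est == pytest.approx(true, rel=0.01)

    def test_nls_oracle_agreement(self):
        # independent oracle: direct pooled nonlinear least squares
        ds = rich_dataset(n_subjects=50, omega_sd=0.0, a=0.01, seed=1)

        y, t = [], []
        for s in ds.subjects:
            for o in s.observations:
                y.append(o.conc)
                t.append(o.time)
        y, t = np.array(y), np.array(t)

        def resid(x):
            p = StructuralParams(*np.exp(x))
            return y - conc_steady_state(p, 75000.0, 24.0, t)

        sol = optimize.least_squares(resid, np.log([0.4, 2.0, 1.0]))
        cfg = SAEMConfig(k1=100, k2=50, seed=1, compute_loglik=False)
        fit = fit_saem(ds, None, cfg)
        assert np.exp(sol.x) == pytest.approx(np.array(fit.model.theta), rel=0.01)

    def test_trajectories_shape_and_flags(self):
        ds = rich_dataset(n_subjects=20, omega_sd=0.1, a=0.5, seed=2)
        cfg = SAEMConfig(k1=40, k2=20, seed=3, compute_loglik=False)
        fit = fit_saem(ds, None, cfg)
        assert len(fit.trajectories) == 60
        assert fit.seed == 3
        for k, (lo, hi) in fit.ci95.items():
            point = {
                "cl_pop": fit.model.theta[0],
                "v_pop": fit.model.theta[1],
                "ka_pop": fit.model.theta[2],
            }.get(k)
            if point is not None:
                assert lo <= point <= hi


class TestSeedDeterminism:
    def test_identical_runs_bitwise(self):
        ds, _ = _paper_like(seed=9)
        cfg = SAEMConfig(k1=40, k2=20, seed=7, compute_loglik=False)
        f1 = fit_saem(ds, None, cfg)
        f2 = fit_saem(ds, None, cfg)
        pd.testing.assert_frame_equal(f1.trajectories, f2.trajectories)
        assert f1.model.theta == f2.model.theta
        assert np.array_equal(f1.model.omega, f2.model.omega)

    def test_different_seed_differs(self):
        ds, _ = _paper_like(seed=9)
        f1 = fit_saem(ds, None, SAEMConfig(k1=40, k2=20, seed=7, compute_loglik=False))
        f2 = fit_saem(ds, None, SAEMConfig(k1=40, k2=20, seed=8, compute_loglik=False))
        assert f1.model.theta != f2.model.theta


class TestAcceptanceRates:
    def test_mh_acceptance_adapts_into_band(self):
        ds, _ = _paper_like(seed=5)
        fit = fit_saem(ds, None, SAEMConfig(k1=150, k2=50, seed=5, compute_loglik=False))
        for r in fit.accept_rates:
            assert 0.2 <= r <= 0.5


class TestLoglikIS:
    def test_zero_omega_equals_conditional(self):
        ds = rich_dataset(n_subjects=4, omega_sd=0.0, a=1.0, seed=3)
        model = PopulationModel(
            theta=(0.32, 1.88, 1.20), beta={"G": 0.0}, omega=np.zeros((3, 3)),
            error_model="additive", error_params=(1.0, 0.0),
        )
        ll, se = estimate_loglik_is(ds, model, n_is_samples=50, seed=0)
        direct = sum(
            loglik_conditional(model, s, np.zeros(3), tau=24.0) for s in ds.subjects
        )
        assert ll == pytest.approx(direct, abs=1e-6)
        assert se == 0.0

    def test_1d_random_effect_matches_quadrature(self):
        model = PopulationModel(
            theta=(0.32, 1.88, 1.20), beta={"G": 0.0},
            omega=np.diag([0.09, 0.0, 0.0]),
            error_model="additive", error_params=(2.0, 0.0),
        )
        psi = StructuralParams(0.32, 1.88, 1.20)
        obs = [
            Observation(2.0, conc_steady_state(psi, 75000.0, 24.0, 2.0) * 1.15),
            Observation(8.0, conc_steady_state(psi, 75000.0, 24.0, 8.0) * 0.9),
        ]
        subs = [
            Subject(id="a", group="G", dose=75000.0, observations=obs),
            Subject(id="b", group="G", dose=75000.0,
                    observations=[Observation(4.0, 20.0)]),
        ]
        ds = PKDataset(subjects=subs, groups=("G",), reference="G")

        def marginal(s):
            def f(e):
                eta = np.array([e, 0.0, 0.0])
                return math.exp(
                    loglik_conditional(model, s, eta) + logprior_eta(model.omega, eta)
                )

            val, _ = integrate.quad(f, -2.5, 2.5, limit=200)
            return math.log(val)

        exact = sum(marginal(s) for s in subs)
        ll, se = estimate_loglik_is(ds, model, n_is_samples=4000, seed=1)
        assert ll == pytest.approx(exact, abs=max(3 * se, 1e-3))

    def test_mc_se_scaling(self):
        ds = rich_dataset(n_subjects=6, omega_sd=0.25, a=1.0, seed=6)
        model = PopulationModel(
            theta=(0.32, 1.88, 1.20), beta={"G": 0.0},
            omega=np.diag([0.09, 0.09, 0.09]),
            error_model="additive", error_params=(1.0, 0.0),
        )
        ses_small = [estimate_loglik_is(ds, model, 250, seed=s)[1] for s in range(8)]
        ses_big = [estimate_loglik_is(ds, model, 1000, seed=100 + s)[1] for s in range(8)]
        ratio = np.mean(ses_small) / np.mean(ses_big)
        assert ratio == pytest.approx(2.0, rel=0.35)  # sqrt(4) with MC slack


class TestLrt:
    class _F:
        def __init__(self, ll):
            self.loglik = ll

    def test_identical_fits(self):
        stat, p = lrt(self._F(-100.0), self._F(-100.0), df=3)
        assert stat == 0.0 and p == 1.0

    def test_chi2_survival_frozen(self):
        stat, p = lrt(self._F(-105.0), self._F(-100.0), df=3)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10.0, 3), rel=1e-12)
        assert p == pytest.approx(0.01857, abs=1e-4)

    def test_negative_stat_clamped(self):
        with pytest.warns(RuntimeWarning):
            stat, p = lrt(self._F(-100.0), self._F(-101.0), df=2)
        assert stat == 0.0 and p == 1.0


class TestCompareErrorModels:
    def test_table_deterministic(self):
        ds, _ = _paper_like(seed=31)
        cfg = SAEMConfig(k1=40, k2=20, seed=2, loglik_samples=100)
        t1 = compare_error_models(ds, None, cfg)
        t2 = compare_error_models(ds, None, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["error_model"]) == {"additive", "proportional", "combined"}
        assert t1["bic"].is_monotonic_increasing

    def test_additive_truth_wins_on_additive_data(self):
        ds, _ = _paper_like(seed=17)
        cfg = SAEMConfig(k1=100, k2=50, seed=3, loglik_samples=200)
        table = compare_error_models(ds, None, cfg)
        assert table.iloc[0]["error_model"] == "additive"

    def test_proportional_truth_wins_on_proportional_data(self):
        from popkit import TruthParams, default_paper_design, default_truth, simulate_study

        base = default_truth().model
        truth = TruthParams(
            model=PopulationModel(
                theta=base.theta, beta=dict(base.beta), omega=base.omega,
                error_model="proportional", error_params=(0.0, 0.2),
            )
        )
        ds, _ = simulate_study(default_paper_design(), truth, 23)
        cfg = SAEMConfig(k1=100, k2=50, seed=4, loglik_samples=200)
        table = compare_error_models(ds, None, cfg)
        assert table.iloc[0]["error_model"] == "proportional"
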