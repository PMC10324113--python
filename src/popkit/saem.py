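"""SAEM estimation of the population model from a sparse PK dataset.

The E-step runs component-wise Gaussian random-walk Metropolis-Hastings on
each subject's random effects, targeting the conditional posterior
(observation likelihood + multivariate-normal eta prior).  Complete-data
sufficient statistics are smoothed by stochastic approximation (step 1 during
the exploratory phase, 1/(k-k1) during smoothing) and the M-step is closed
form: generalised least squares of the sampled log-parameters on the
covariate design for the fixed effects, residual second moments for Omega,
and mean squared residuals for the additive error SD (proportional and
combined errors via an inner numerical optimisation).

Standard errors come from a stochastic approximation of the observed Fisher
information for the fixed effects (Louis' identity), accumulated during the
smoothing phase; the marginal log-likelihood is estimated afterwards by
per-subject importance sampling with a Student-t proposal centred at each
conditional mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .exceptions import EstimationError, ValidationError
from .popmodel import BLQ_POLICIES, PKDataset, PopulationModel
from .structural import _conc_ss_ng_l

__all__ = [
    "SAEMConfig",
    "FitResult",
    "fit_saem",
    "estimate_loglik_is",
    "compare_error_models",
    "lrt",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SAEMConfig:
    """Tuning knobs for the SAEM run.

    ``k1`` exploratory iterations (step size 1, proposal adaptation on),
    ``k2`` smoothing iterations (step 1/(k-k1), kernels frozen).
    """

    k1: int = 500
    k2: int = 800
    n_chains: int = 2
    n_sweeps: int = 3
    proposal_scales: tuple[float, float, float] = (0.4, 0.4, 0.4)
    step_exponent: float = 1.0
    seed: int = 0
    convergence_window: int = 25
    adapt_target: float = 0.35
    constrain_ka_gt_ke: bool = True
    blq_policy: str = "exclude"
    diagonal_omega: bool = False
    covariate_on_cl: bool = True
    compute_loglik: bool = True
    loglik_samples: int = 500

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ValidationError("k1 and k2 must both be >= 1")
        if self.n_chains < 1 or self.n_sweeps < 1:
            raise ValidationError("n_chains and n_sweeps must be >= 1")
        if any(s <= 0 for s in self.proposal_scales):
            raise ValidationError("proposal scales must be > 0")
        if self.blq_policy not in BLQ_POLICIES:
            raise ValidationError(f"blq_policy must be one of {BLQ_POLICIES}")


@dataclass
class FitResult:
    """SAEM output: estimates, uncertainty, likelihood and trajectories."""

    model: PopulationModel
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    loglik: float | None
    loglik_se: float | None
    trajectories: pd.DataFrame
    converged: bool
    seed: int
    config: SAEMConfig
    se_method: str
    accept_rates: tuple[float, float, float]
    n_blq_excluded: int
    groups: tuple[str, ...]
    reference: str

    def to_json_dict(self) -> dict:
        m = self.model
        return {
            "schema_version": 1,
            "theta": {"cl_pop": m.theta[0], "v_pop": m.theta[1], "ka_pop": m.theta[2]},
            "beta_log_cl": dict(m.beta),
            "omega": np.asarray(m.omega).tolist(),
            "error_model": m.error_model,
            "error_params": {"a": m.error_params[0], "b": m.error_params[1]},
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "loglik": self.loglik,
            "loglik_mc_se": self.loglik_se,
            "converged": self.converged,
            "seed": self.seed,
            "se_method": self.se_method,
            "accept_rates": list(self.accept_rates),
            "n_blq_excluded": self.n_blq_excluded,
            "groups": list(self.groups),
            "reference": self.reference,
            "assumption_flags": {"omega_init": True, "proposal_scales": True},
        }


# ---------------------------------------------------------------------------
# internal compiled representation of a dataset


class _Problem:
    """Flat numpy view of a PKDataset for vectorised likelihood work."""

    def __init__(self, data: PKDataset, cfg: SAEMConfig):
        subs = [s for s in data.subjects if s.observations]
        if len(subs) < 2:
            raise ValidationError("need at least 2 subjects with >= 1 observation")
        self.tau = data.tau
        self.lloq = data.lloq
        self.groups = tuple(data.groups)
        self.reference = data.reference
        self.n = len(subs)
        self.ids = [s.id for s in subs]
        self.dose = np.array([s.dose for s in subs])
        self.glabels = [s.group for s in subs]
        self.gidx = np.array([self.groups.index(g) for g in self.glabels])

        y, t, sub = [], [], []
        cy_t, cy_sub = [], []
        n_blq = 0
        for i, s in enumerate(subs):
            for o in s.observations:
                if o.blq:
                    n_blq += 1
                    if cfg.blq_policy == "exclude":
                        continue
                    if cfg.blq_policy == "loq_half":
                        if self.lloq is None:
                            raise ValidationError("loq_half policy requires dataset lloq")
                        y.append(self.lloq / 2.0)
                        t.append(o.time)
                        sub.append(i)
                    else:  # censored
                        if self.lloq is None:
                            raise ValidationError("censored policy requires dataset lloq")
                        cy_t.append(o.time)
                        cy_sub.append(i)
                else:
                    if not math.isfinite(o.conc):
                        raise ValidationError(f"NaN concentration for subject {s.id}")
                    y.append(o.conc)
                    t.append(o.time)
                    sub.append(i)
        self.y = np.array(y)
        self.t = np.array(t)
        self.sub = np.array(sub, dtype=int)
        self.cens_t = np.array(cy_t)
        self.cens_sub = np.array(cy_sub, dtype=int)
        self.n_blq = n_blq
        if self.y.size + self.cens_t.size == 0:
            raise ValidationError("no usable observations after BLQ policy")
        pooled_times = np.unique(np.concatenate([self.t, self.cens_t]))
        if pooled_times.size < 3:
            raise EstimationError(
                "non-identifiable design: fewer than 3 distinct sampling times pooled",
                {"distinct_times": pooled_times.tolist()},
            )

        # fixed-effect design: mu = [log cl_pop, beta_(nonref...), log v_pop, log ka_pop]
        self.nonref = tuple(g for g in self.groups if g != self.reference) if cfg.covariate_on_cl else ()
        self.q = 3 + len(self.nonref)
        G = len(self.groups)
        self.A = np.zeros((G, 3, self.q))
        for g in range(G):
            self.A[g, 0, 0] = 1.0
            label = self.groups[g]
            if label in self.nonref:
                self.A[g, 0, 1 + self.nonref.index(label)] = 1.0
            self.A[g, 1, self.q - 2] = 1.0
            self.A[g, 2, self.q - 1] = 1.0
        self.A_sub = self.A[self.gidx]  # (n, 3, q)
        self.counts = np.bincount(self.gidx, minlength=G)

    # -- likelihood machinery ------------------------------------------------

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Per-observation predicted concentration (ng/mL) from (n,3) log-params."""
        cl = np.exp(phi[:, 0])
        v = np.exp(phi[:, 1])
        ka = np.exp(phi[:, 2])
        s = self.sub
        return _conc_ss_ng_l(self.dose[s], self.tau, self.t, cl[s], v[s], ka[s]) / 1000.0

    def loglik_subjects(self, phi: np.ndarray, error_model: str, a: float, b: float) -> np.ndarray:
        """(n,) vector of observation log-likelihoods given individual log-params."""
        out = np.zeros(self.n)
        if self.y.size:
            f = self.predict(phi)
            sd = _error_sd(error_model, a, b, f)
            ll = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((self.y - f) / sd) ** 2
            out += np.bincount(self.sub, weights=ll, minlength=self.n)
        if self.cens_t.size:
            s = self.cens_sub
            cl = np.exp(phi[:, 0])
            v = np.exp(phi[:, 1])
            ka = np.exp(phi[:, 2])
            fc = _conc_ss_ng_l(self.dose[s], self.tau, self.cens_t, cl[s], v[s], ka[s]) / 1000.0
            sdc = _error_sd(error_model, a, b, fc)
            out += np.bincount(s, weights=stats.norm.logcdf((self.lloq - fc) / sdc), minlength=self.n)
        return out

    def mean_phi(self, mu: np.ndarray) -> np.ndarray:
        return self.A_sub @ mu  # (n, 3)


def _error_sd(error_model: str, a: float, b: float, f: np.ndarray) -> np.ndarray:
    if error_model == "additive":
        return np.full(np.shape(f), max(a, 1e-12))
    if error_model == "proportional":
        return np.maximum(b * np.abs(f), 1e-12)
    return np.sqrt(np.maximum(a * a + b * b * f * f, 1e-24))


def _logprior_vec(eta: np.ndarray, w_inv: np.ndarray, logdet: float) -> np.ndarray:
    quad = np.einsum("ij,jk,ik->i", eta, w_inv, eta)
    return -0.5 * (3.0 * _LOG_2PI + logdet + quad)


# ---------------------------------------------------------------------------
# initialisation


def _pooled_nls(prob: _Problem, fallback: tuple[float, float, float] | None) -> np.ndarray:
    """Naive pooled nonlinear least squares for (log cl, log v, log ka)."""
    ybar = max(float(np.mean(prob.y)) if prob.y.size else 1.0, 1e-6)
    dbar = float(np.mean(prob.dose))
    cl0 = max(dbar / (1000.0 * ybar * prob.tau), 1e-6)
    x0 = np.log([cl0, cl0 / 0.2, 1.5])

    def resid(x):
        cl, v, ka = np.exp(x)
        f = _conc_ss_ng_l(prob.dose[prob.sub], prob.tau, prob.t, cl, v, ka) / 1000.0
        return prob.y - f

    try:
        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
        x = sol.x
        if not np.all(np.isfinite(x)):
            raise RuntimeError("non-finite NLS solution")
    except Exception:
        if fallback is None:
            raise
        x = np.log(fallback)
    cl, v, ka = np.exp(x)
    if ka <= cl / v:  # flip-flop: swap absorption/elimination roles, keep AUC
        cl, v, ka = cl, cl / ka, cl / v
    return np.log([cl, v, ka])


# ---------------------------------------------------------------------------
# M-step


def _mstep_mu_omega(
    phibar: np.ndarray,
    s2: np.ndarray,
    prob: _Problem,
    mu0: np.ndarray,
    omega0: np.ndarray,
    diagonal: bool,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint maximiser of the complete-data Gaussian layer.

    Alternates GLS for mu (given Omega) with the residual-moment update for
    Omega (given mu) until fixed point; this converges to the joint maximum of
    sum_i log N(phi_i; A_i mu, Omega) given the sufficient statistics
    ``phibar`` (per-subject smoothed phi) and ``s2`` (smoothed sum of outer
    products).
    """
    mu = mu0.copy()
    omega = omega0.copy()
    n = prob.n
    for _ in range(max_iter):
        w_inv = _safe_inv(omega)
        lhs = np.zeros((prob.q, prob.q))
        rhs = np.zeros(prob.q)
        for g in range(len(prob.groups)):
            if prob.counts[g] == 0:
                continue
            Ag = prob.A[g]
            AtW = Ag.T @ w_inv
            lhs += prob.counts[g] * (AtW @ Ag)
            rhs += AtW @ phibar[prob.gidx == g].sum(axis=0)
        mu_new = np.linalg.solve(lhs, rhs)
        m = prob.mean_phi(mu_new)
        cross = m.T @ phibar
        omega_new = (s2 - cross - cross.T + m.T @ m) / n
        omega_new = 0.5 * (omega_new + omega_new.T)
        if diagonal:
            omega_new = np.diag(np.diag(omega_new))
        omega_new = _floor_psd(omega_new)
        delta = max(
            float(np.max(np.abs(mu_new - mu))), float(np.max(np.abs(omega_new - omega)))
        )
        mu, omega = mu_new, omega_new
        if delta < tol:
            break
    return mu, omega


def _safe_inv(omega: np.ndarray) -> np.ndarray:
    w, q = np.linalg.eigh(omega)
    w = np.maximum(w, 1e-10)
    return (q / w) @ q.T


def _floor_psd(omega: np.ndarray, floor: float = 1e-10, max_cond: float = 1e4) -> np.ndarray:
    """Floor eigenvalues absolutely and relative to the largest.

    The relative floor caps the condition number: a collapsing Omega direction
    would otherwise make the conditional eta prior razor-sharp and freeze the
    MH chains.
    """
    w, q = np.linalg.eigh(omega)
    lo = max(floor, float(w.max()) / max_cond if w.max() > 0 else floor)
    if w.min() >= lo:
        return omega
    w = np.maximum(w, lo)
    return (q * w) @ q.T


def _mstep_error(
    error_model: str,
    r2bar: np.ndarray,
    f2bar: np.ndarray,
    u2bar: np.ndarray,
    a0: float,
    b0: float,
) -> tuple[float, float]:
    """Maximise the residual layer from smoothed per-observation statistics."""
    if error_model == "additive":
        return float(np.sqrt(np.mean(r2bar))), 0.0
    if error_model == "proportional":
        return 0.0, float(np.sqrt(np.mean(u2bar)))

    def nll(x):
        a2, b2 = np.exp(2.0 * x)
        var = a2 + b2 * f2bar
        return float(np.sum(0.5 * np.log(var) + r2bar / (2.0 * var)))

    x0 = np.log([max(a0, 1e-4), max(b0, 1e-4)])
    sol = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    a, b = np.exp(sol.x)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# main driver


def fit_saem(
    data: PKDataset,
    model_spec: PopulationModel | None = None,
    cfg: SAEMConfig | None = None,
) -> FitResult:
    """Fit the population model to ``data`` by SAEM.

    ``model_spec`` is a skeleton fixing the error model; its theta is used as
    a fallback initial guess if the pooled NLS initialisation fails.  All
    randomness flows from ``cfg.seed``.
    """
    cfg = cfg or SAEMConfig()
    if model_spec is not None and not cfg.covariate_on_cl and model_spec.beta:
        raise ValidationError("model_spec carries group effects but covariate_on_cl is off")
    error_model = model_spec.error_model if model_spec is not None else "additive"
    fallback_theta = model_spec.theta if model_spec is not None else None

    prob = _Problem(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    C, n, q = cfg.n_chains, prob.n, prob.q

    x_nls = _pooled_nls(prob, fallback_theta)
    mu = np.zeros(q)
    mu[0], mu[q - 2], mu[q - 1] = x_nls
    omega = np.diag([0.09, 0.09, 0.09])
    resid0 = prob.y - prob.predict(np.tile(x_nls, (n, 1))) if prob.y.size else np.array([1.0])
    a = float(np.sqrt(np.mean(resid0**2))) if error_model != "proportional" else 0.0
    b = 0.2 if error_model != "additive" else 0.0

    # chain state is phi itself (not eta): individual parameters stay anchored
    # to the data when the M-step moves mu
    phi_state = np.tile(prob.mean_phi(mu), (C, 1, 1))
    scales = np.array(cfg.proposal_scales, dtype=float)

    N = prob.y.size
    phibar = np.zeros((n, 3))
    s2 = np.zeros((3, 3))
    r2bar = np.zeros(N)
    f2bar = np.zeros(N)
    u2bar = np.zeros(N)
    acc_hist = np.zeros(3)

    n_iter = cfg.k1 + cfg.k2
    traj = np.zeros((n_iter, 3 + len(prob.nonref) + 6 + 2))
    col_names = (
        ["cl_pop"]
        + [f"beta:{g}" for g in prob.nonref]
        + ["v_pop", "ka_pop"]
        + ["om_cl", "om_v", "om_ka", "om_cl_v", "om_cl_ka", "om_v_ka"]
        + ["a", "b"]
    )

    for k in range(n_iter):
        w_inv = _safe_inv(omega)
        sgn, logdet = np.linalg.slogdet(omega + 1e-30 * np.eye(3))
        mean_phi = prob.mean_phi(mu)

        def loglik_only(phi):
            ll = prob.loglik_subjects(phi, error_model, a, b)
            if cfg.constrain_ka_gt_ke:
                bad = phi[:, 2] <= phi[:, 0] - phi[:, 1]
                ll = np.where(bad, -np.inf, ll)
            return ll

        def target(phi):
            return loglik_only(phi) + _logprior_vec(phi - mean_phi, w_inv, logdet)

        chol = np.linalg.cholesky(omega + 1e-12 * np.eye(3))
        prop_sd = scales * np.sqrt(np.diag(omega) + 1e-8)
        acc_iter = np.zeros(3)
        for c in range(C):
            # kernel 1: independence proposal from the eta prior
            # (acceptance reduces to the likelihood ratio)
            ll_cur = loglik_only(phi_state[c])
            prop = mean_phi + rng.standard_normal((n, 3)) @ chol.T
            ll_new = loglik_only(prop)
            accept = np.log(rng.random(n)) < ll_new - ll_cur
            phi_state[c][accept] = prop[accept]

            # kernel 2: component-wise random walk, scale tied to Omega
            cur = target(phi_state[c])
            for _ in range(cfg.n_sweeps):
                for j in range(3):
                    prop = phi_state[c].copy()
                    prop[:, j] += prop_sd[j] * rng.standard_normal(n)
                    new = target(prop)
                    accept = np.log(rng.random(n)) < new - cur
                    phi_state[c][accept] = prop[accept]
                    cur = np.where(accept, new, cur)
                    acc_iter[j] += accept.mean()
        acc_iter /= C * cfg.n_sweeps
        acc_hist = acc_iter

        if k < cfg.k1:  # adapt proposals during exploration only
            step = 2.0 / math.sqrt(k + 1.0)
            scales *= np.exp(step * (acc_iter - cfg.adapt_target))
            scales = np.clip(scales, 1e-4, 10.0)

        gamma = 1.0 if k < cfg.k1 else (k - cfg.k1 + 1.0) ** (-cfg.step_exponent)

        phi_c = phi_state  # (C, n, 3)
        phi_mean = phi_c.mean(axis=0)
        s2_draw = np.einsum("cij,cik->jk", phi_c, phi_c) / C
        phibar += gamma * (phi_mean - phibar)
        s2 += gamma * (s2_draw - s2)

        if N:
            r2_draw = np.zeros(N)
            f2_draw = np.zeros(N)
            u2_draw = np.zeros(N)
            for c in range(C):
                f = prob.predict(phi_c[c])
                r2 = (prob.y - f) ** 2
                r2_draw += r2
                f2_draw += f**2
                u2_draw += r2 / np.maximum(f, 1e-12) ** 2
            r2bar += gamma * (r2_draw / C - r2bar)
            f2bar += gamma * (f2_draw / C - f2bar)
            u2bar += gamma * (u2_draw / C - u2bar)

        mu, omega = _mstep_mu_omega(phibar, s2, prob, mu, omega, cfg.diagonal_omega)
        if N:
            a, b = _mstep_error(error_model, r2bar, f2bar, u2bar, a, b)

        row = [math.exp(mu[0])]
        row += [mu[1 + i] for i in range(len(prob.nonref))]
        row += [math.exp(mu[q - 2]), math.exp(mu[q - 1])]
        row += [omega[0, 0], omega[1, 1], omega[2, 2], omega[0, 1], omega[0, 2], omega[1, 2]]
        row += [a, b]
        traj[k] = row

    trajectories = pd.DataFrame(traj, columns=col_names)
    trajectories.insert(0, "iteration", np.arange(1, n_iter + 1))

    # ---- standard errors: Louis identity on the fixed effects, estimated by
    # a frozen-kernel MCMC pass at the final parameter values ----
    w_inv = _safe_inv(omega)
    h0 = np.zeros((q, q))
    for g in range(len(prob.groups)):
        Ag = prob.A[g]
        h0 += prob.counts[g] * (Ag.T @ w_inv @ Ag)
    # primary: joint Laplace information with the Schur-complement correction
    # for Omega/error-parameter uncertainty (deterministic, PSD in practice);
    # fallbacks: MCMC Louis, then complete-data information
    se_method = "laplace_joint"
    try:
        info = _laplace_joint_info(
            prob, mu, omega, error_model, a, b, cfg.diagonal_omega
        )
        if np.linalg.eigvalsh(info).min() <= 0:
            raise np.linalg.LinAlgError("joint information not PD")
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        se_method = "louis"
        score_var, _opg = _louis_score_variance(
            prob, phi_state, mu, omega, error_model, a, b, scales, cfg, rng
        )
        info = h0 - score_var
        try:
            if np.linalg.eigvalsh(info).min() <= 0:
                raise np.linalg.LinAlgError("information not positive definite")
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn(
                "marginal information not positive definite; falling back to "
                "complete-data information (SEs optimistic)",
                RuntimeWarning,
            )
            cov = np.linalg.inv(h0)
            se_method = "complete_info"
    se_mu = np.sqrt(np.diag(cov))

    # with the covariate off, every group still needs an (all-zero) entry so
    # downstream per-subject mapping accepts any label in the dataset
    beta = {g: 0.0 for g in prob.groups} if not prob.nonref else {prob.reference: 0.0}
    se: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    z = 1.959963984540054
    for name, idx in (("cl_pop", 0), ("v_pop", q - 2), ("ka_pop", q - 1)):
        se[name] = float(se_mu[idx])  # log-scale SE
        ci95[name] = (math.exp(mu[idx] - z * se_mu[idx]), math.exp(mu[idx] + z * se_mu[idx]))
    for i, g in enumerate(prob.nonref):
        beta[g] = float(mu[1 + i])
        se[f"beta:{g}"] = float(se_mu[1 + i])
        ci95[f"beta:{g}"] = (beta[g] - z * se_mu[1 + i], beta[g] + z * se_mu[1 + i])

    model = PopulationModel(
        theta=(math.exp(mu[0]), math.exp(mu[q - 2]), math.exp(mu[q - 1])),
        beta=beta,
        omega=omega,
        error_model=error_model,
        error_params=(a, b),
    )

    # convergence: relative movement of fixed effects over the last window
    win = min(cfg.convergence_window, cfg.k2)
    tail = trajectories.iloc[-win:][["cl_pop", "v_pop", "ka_pop"]].to_numpy()
    rel_move = (tail.max(axis=0) - tail.min(axis=0)) / np.maximum(np.abs(tail[-1]), 1e-12)
    converged = bool(np.all(rel_move < 0.05))

    result = FitResult(
        model=model,
        se=se,
        ci95=ci95,
        loglik=None,
        loglik_se=None,
        trajectories=trajectories,
        converged=converged,
        seed=cfg.seed,
        config=cfg,
        se_method=se_method,
        accept_rates=tuple(float(x) for x in acc_hist),
        n_blq_excluded=prob.n_blq if cfg.blq_policy == "exclude" else 0,
        groups=prob.groups,
        reference=prob.reference,
    )
    if cfg.compute_loglik:
        ll, mc_se = estimate_loglik_is(
            data, model, n_is_samples=cfg.loglik_samples, seed=cfg.seed + 1, cfg=cfg
        )
        result.loglik = ll
        result.loglik_se = mc_se
    return result


def _pack_variance_params(omega, a, b, error_model, diagonal):
    if diagonal:
        lam = list(0.5 * np.log(np.maximum(np.diag(omega), 1e-12)))
    else:
        L = np.linalg.cholesky(omega + 1e-12 * np.eye(3))
        lam = [math.log(L[0, 0]), L[1, 0], math.log(L[1, 1]), L[2, 0], L[2, 1], math.log(L[2, 2])]
    if error_model == "additive":
        lam += [math.log(max(a, 1e-8))]
    elif error_model == "proportional":
        lam += [math.log(max(b, 1e-8))]
    else:
        lam += [math.log(max(a, 1e-8)), math.log(max(b, 1e-8))]
    return np.array(lam)


def _unpack_variance_params(lam, error_model, diagonal):
    if diagonal:
        om = np.diag(np.exp(2.0 * lam[:3]))
        k = 3
    else:
        L = np.zeros((3, 3))
        L[0, 0] = math.exp(lam[0])
        L[1, 0] = lam[1]
        L[1, 1] = math.exp(lam[2])
        L[2, 0] = lam[3]
        L[2, 1] = lam[4]
        L[2, 2] = math.exp(lam[5])
        om = L @ L.T
        k = 6
    if error_model == "additive":
        a, b = math.exp(lam[k]), 0.0
    elif error_model == "proportional":
        a, b = 0.0, math.exp(lam[k])
    else:
        a, b = math.exp(lam[k]), math.exp(lam[k + 1])
    return om, a, b


def _laplace_joint_info(
    prob: _Problem,
    mu: np.ndarray,
    omega: np.ndarray,
    error_model: str,
    a: float,
    b: float,
    diagonal: bool,
    h: float = 1e-3,
) -> np.ndarray:
    """Fixed-effect information adjusted for variance-parameter uncertainty.

    Builds the joint observed information of (mu, lambda) — lambda being the
    Omega Cholesky/log-diagonal and error parameters — from the Laplace
    marginal likelihood, and returns the Schur complement
    I_mu|lambda = I_mumu - I_mulam I_lamlam^-1 I_lammu.  The mu block is
    analytic (Louis with Laplace posterior moments); the lambda blocks use
    central finite differences with warm-started mode searches.
    """
    q = mu.size
    lam0 = _pack_variance_params(omega, a, b, error_model, diagonal)
    p = lam0.size
    warm: dict[str, np.ndarray | None] = {"phi": None}

    def ll_and_score(lam):
        om, a_, b_ = _unpack_variance_params(lam, error_model, diagonal)
        ll, modes, _ = _laplace_marginal_ll(
            prob, mu, om, error_model, a_, b_, phi0=warm["phi"], tol=1e-6, max_iter=25
        )
        warm["phi"] = modes
        w_inv = _safe_inv(om)
        resid = modes - prob.mean_phi(mu)
        g = np.einsum("ijq,jl,il->q", prob.A_sub, w_inv, resid)
        return ll, g

    ll0, _ = ll_and_score(lam0)
    i_mumu = _laplace_info(prob, mu, omega, error_model, a, b)

    ll_plus = np.zeros(p)
    ll_minus = np.zeros(p)
    i_mulam = np.zeros((q, p))
    for k in range(p):
        e = np.zeros(p)
        e[k] = h
        lp, gp = ll_and_score(lam0 + e)
        lm, gm = ll_and_score(lam0 - e)
        ll_plus[k], ll_minus[k] = lp, lm
        i_mulam[:, k] = -(gp - gm) / (2.0 * h)
    i_lamlam = np.zeros((p, p))
    for k in range(p):
        i_lamlam[k, k] = -(ll_plus[k] - 2.0 * ll0 + ll_minus[k]) / h**2
    # cross terms by forward differences, reusing the +h singles
    for k in range(p):
        for l in range(k + 1, p):
            e = np.zeros(p)
            e[k] = e[l] = h
            fpp, _ = ll_and_score(lam0 + e)
            i_lamlam[k, l] = i_lamlam[l, k] = -(
                fpp - ll_plus[k] - ll_plus[l] + ll0
            ) / h**2

    # clamp flat/negative lambda directions (finite-difference noise and
    # slightly off-optimum lambda would otherwise explode the correction)
    w, qv = np.linalg.eigh(i_lamlam)
    w = np.maximum(w, max(1e-2, 1e-3 * float(np.max(np.abs(w)))))
    i_lamlam_inv = (qv / w) @ qv.T
    correction = i_mulam @ i_lamlam_inv @ i_mulam.T
    # back off the correction if it breaks positive definiteness
    for c in (1.0, 0.9, 0.75, 0.5, 0.25):
        adj = i_mumu - c * correction
        adj = 0.5 * (adj + adj.T)
        if np.linalg.eigvalsh(adj).min() > 0:
            return adj
    return 0.5 * (i_mumu + i_mumu.T)


def _louis_score_variance(
    prob: _Problem,
    phi_state: np.ndarray,
    mu: np.ndarray,
    omega: np.ndarray,
    error_model: str,
    a: float,
    b: float,
    scales: np.ndarray,
    cfg: SAEMConfig,
    rng: np.random.Generator,
    n_iter: int = 200,
) -> np.ndarray:
    """Posterior score moments for Louis' identity, by frozen-kernel MCMC.

    Louis' identity gives the observed information for the fixed effects as
    I = sum_i A_i' W A_i - sum_i Var(s_i | y_i) with
    s_i = A_i' W (phi_i - A_i mu).  The moments are estimated by continuing
    the MH kernels with all parameters frozen at their final values;
    subject-wise accumulation keeps the Monte-Carlo noise down.  Returns
    (sum_i Var(s_i|y), outer-product-of-scores matrix) — the second is a PSD
    BHHH-style information estimate kept for diagnostics.
    """
    C, n, _ = phi_state.shape
    q = prob.q
    w_inv = _safe_inv(omega)
    _, logdet = np.linalg.slogdet(omega + 1e-30 * np.eye(3))
    mean_phi = prob.mean_phi(mu)
    chol = np.linalg.cholesky(omega + 1e-12 * np.eye(3))
    prop_sd = scales * np.sqrt(np.diag(omega) + 1e-8)
    phi = phi_state.copy()

    def loglik_only(p):
        ll = prob.loglik_subjects(p, error_model, a, b)
        if cfg.constrain_ka_gt_ke:
            bad = p[:, 2] <= p[:, 0] - p[:, 1]
            ll = np.where(bad, -np.inf, ll)
        return ll

    def target(p):
        return loglik_only(p) + _logprior_vec(p - mean_phi, w_inv, logdet)

    s_sum = np.zeros((n, q))
    ss_sum = np.zeros((n, q, q))
    count = 0
    for _ in range(n_iter):
        for c in range(C):
            ll_cur = loglik_only(phi[c])
            prop = mean_phi + rng.standard_normal((n, 3)) @ chol.T
            ll_new = loglik_only(prop)
            accept = np.log(rng.random(n)) < ll_new - ll_cur
            phi[c][accept] = prop[accept]
            cur = target(phi[c])
            for j in range(3):
                prop = phi[c].copy()
                prop[:, j] += prop_sd[j] * rng.standard_normal(n)
                new = target(prop)
                accept = np.log(rng.random(n)) < new - cur
                phi[c][accept] = prop[accept]
                cur = np.where(accept, new, cur)
            s_i = np.einsum("ijq,jl,il->iq", prob.A_sub, w_inv, phi[c] - mean_phi)
            s_sum += s_i
            ss_sum += s_i[:, :, None] * s_i[:, None, :]
            count += 1
    m = s_sum / count
    second = ss_sum / count
    var_i = second - m[:, :, None] * m[:, None, :]
    # m_i estimates the per-subject marginal score (Fisher's identity), whose
    # outer-product sum is a PSD information estimate (BHHH) used as fallback
    opg = np.einsum("iq,ip->qp", m, m)
    return var_i.sum(axis=0), opg


# ---------------------------------------------------------------------------
# batched Laplace machinery (modes + curvature for all subjects at once)


def _batched_target(prob: _Problem, mean_phi, w_inv, logdet, error_model, a, b):
    def tvec(phi):
        return prob.loglik_subjects(phi, error_model, a, b) + _logprior_vec(
            phi - mean_phi, w_inv, logdet
        )

    return tvec


def _modes_newton(
    tvec,
    phi0: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 80,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simultaneous Newton ascent of a per-subject target over (n, 3) states.

    Gradients/Hessians by vectorised finite differences; damped steps keep
    every subject monotone.  Exits on gradient tolerance or when the target
    stagnates (finite-difference noise floor).  Returns (modes, neg Hessians
    (n,3,3), target values).
    """
    phi = phi0.copy()
    n = phi.shape[0]
    hg, hh = 1e-5, 1e-4
    eye = np.eye(3)
    cur = tvec(phi)
    stagnant = 0
    for _ in range(max_iter):
        grad = np.zeros((n, 3))
        for j in range(3):
            e = hg * eye[j]
            grad[:, j] = (tvec(phi + e) - tvec(phi - e)) / (2 * hg)
        if np.max(np.abs(grad)) < tol:
            break
        H = np.zeros((n, 3, 3))
        f0 = tvec(phi)
        for j in range(3):
            e = hh * eye[j]
            H[:, j, j] = -(tvec(phi + e) - 2 * f0 + tvec(phi - e)) / hh**2
        for j in range(3):
            for l in range(j + 1, 3):
                ej, el = hh * eye[j], hh * eye[l]
                H[:, j, l] = H[:, l, j] = -(
                    tvec(phi + ej + el)
                    - tvec(phi + ej - el)
                    - tvec(phi - ej + el)
                    + tvec(phi - ej - el)
                ) / (4 * hh**2)
        # PD-project and damp each subject's curvature before solving; the
        # eta prior contributes O(1/omega) so a floor well below that is safe
        w, qv = np.linalg.eigh(H)
        w = np.maximum(w, np.maximum(1e-2, 1e-3 * w.max(axis=1))[:, None])
        Hpd = np.einsum("nij,nj,nkj->nik", qv, w, qv)
        step = np.linalg.solve(Hpd, grad[:, :, None])[:, :, 0]
        norms = np.linalg.norm(step, axis=1)
        big = norms > 2.0
        step[big] *= (2.0 / norms[big])[:, None]
        t = np.ones(n)
        best = phi.copy()
        best_val = cur.copy()
        for _ in range(30):
            cand = phi + t[:, None] * step
            new = tvec(cand)
            better = new > best_val
            best[better] = cand[better]
            best_val = np.maximum(new, best_val)
            worse = new < cur
            if not np.any(worse):
                break
            t[worse] *= 0.5
        gain = float(np.max(best_val - cur))
        phi = best
        cur = best_val
        stagnant = stagnant + 1 if gain < 1e-9 else 0
        if stagnant >= 2:
            break
    # final curvature at the modes
    H = np.zeros((n, 3, 3))
    f0 = tvec(phi)
    for j in range(3):
        e = hh * eye[j]
        H[:, j, j] = -(tvec(phi + e) - 2 * f0 + tvec(phi - e)) / hh**2
    for j in range(3):
        for l in range(j + 1, 3):
            ej, el = hh * eye[j], hh * eye[l]
            H[:, j, l] = H[:, l, j] = -(
                tvec(phi + ej + el)
                - tvec(phi + ej - el)
                - tvec(phi - ej + el)
                + tvec(phi - ej - el)
            ) / (4 * hh**2)
    return phi, H, f0


def _laplace_marginal_ll(
    prob: _Problem,
    mu: np.ndarray,
    omega: np.ndarray,
    error_model: str,
    a: float,
    b: float,
    phi0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 80,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Laplace approximation of the total marginal log-likelihood.

    Returns (log-likelihood, per-subject modes, per-subject neg Hessians) so
    callers can reuse the posterior curvature.
    """
    w_inv = _safe_inv(omega)
    _, logdet = np.linalg.slogdet(omega + 1e-30 * np.eye(3))
    mean_phi = prob.mean_phi(mu)
    tvec = _batched_target(prob, mean_phi, w_inv, logdet, error_model, a, b)
    phi, H, t_at_mode = _modes_newton(
        tvec, phi0 if phi0 is not None else mean_phi.copy(), tol=tol, max_iter=max_iter
    )
    w = np.linalg.eigvalsh(H)
    w = np.maximum(w, 1e-10)
    logdet_h = np.sum(np.log(w), axis=1)
    ll = t_at_mode + 1.5 * _LOG_2PI - 0.5 * logdet_h
    return float(ll.sum()), phi, H


def _laplace_info(
    prob: _Problem,
    mu: np.ndarray,
    omega: np.ndarray,
    error_model: str,
    a: float,
    b: float,
) -> np.ndarray:
    """Observed information for mu via Louis' identity with Laplace posteriors.

    I = sum_i A_i' (W - W V_i W) A_i, with V_i the Gaussian (Laplace)
    approximation of each subject's posterior covariance of phi_i.  Positive
    semidefinite whenever every subject's likelihood curvature at its mode is.
    """
    w_inv = _safe_inv(omega)
    _, phi, H = _laplace_marginal_ll(prob, mu, omega, error_model, a, b)
    w, qv = np.linalg.eigh(H)
    w = np.maximum(w, 1e-10)
    V = np.einsum("nij,nj,nkj->nik", qv, 1.0 / w, qv)
    mid = w_inv[None, :, :] - np.einsum("jk,nkl,lm->njm", w_inv, V, w_inv)
    return np.einsum("njq,njl,nlp->qp", prob.A_sub, mid, prob.A_sub)


# ---------------------------------------------------------------------------
# marginal likelihood by importance sampling


def _subject_arrays(prob: _Problem, i: int):
    sel = prob.sub == i
    csel = prob.cens_sub == i if prob.cens_sub.size else np.array([], dtype=bool)
    return (
        prob.y[sel],
        prob.t[sel],
        prob.cens_t[csel] if prob.cens_t.size else np.array([]),
    )


def _subject_loglik_many(
    prob: _Problem, i: int, phi: np.ndarray, error_model: str, a: float, b: float
) -> np.ndarray:
    """Observation log-likelihood of subject ``i`` at many (M,3) log-params."""
    y, t, ct = _subject_arrays(prob, i)
    cl = np.exp(phi[:, 0:1])
    v = np.exp(phi[:, 1:2])
    ka = np.exp(phi[:, 2:3])
    out = np.zeros(phi.shape[0])
    if y.size:
        f = _conc_ss_ng_l(prob.dose[i], prob.tau, t[None, :], cl, v, ka) / 1000.0
        sd = _error_sd(error_model, a, b, f)
        out += np.sum(-0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((y[None, :] - f) / sd) ** 2, axis=1)
    if ct.size:
        fc = _conc_ss_ng_l(prob.dose[i], prob.tau, ct[None, :], cl, v, ka) / 1000.0
        sdc = _error_sd(error_model, a, b, fc)
        out += np.sum(stats.norm.logcdf((prob.lloq - fc) / sdc), axis=1)
    return out


def estimate_loglik_is(
    data: PKDataset,
    model: PopulationModel,
    n_is_samples: int = 1000,
    seed: int = 0,
    cfg: SAEMConfig | None = None,
) -> tuple[float, float]:
    """Importance-sampling estimate of the marginal log-likelihood.

    Per subject, a multivariate Student-t proposal (df 4) centred at the
    conditional mode with covariance 1.5^2 x the inverse curvature; random
    effects whose Omega diagonal is (numerically) zero are integrated out
    trivially at eta = 0.  Returns (log-likelihood, Monte-Carlo SE).
    """
    from .individual import _conditional_mode_free, _free_components, _num_hessian

    cfg = cfg or SAEMConfig()
    prob = _Problem(data, cfg)
    rng = np.random.default_rng(seed)
    a, bb = model.error_params
    omega = np.asarray(model.omega)
    free = _free_components(omega)
    nf = int(free.sum())

    mean_phi_all = np.zeros((prob.n, 3))
    for i in range(prob.n):
        mean_phi_all[i] = [
            math.log(model.theta[0]) + model.group_effect(prob.glabels[i]),
            math.log(model.theta[1]),
            math.log(model.theta[2]),
        ]

    if nf == 0:
        total = 0.0
        for i in range(prob.n):
            total += float(
                _subject_loglik_many(prob, i, mean_phi_all[i][None, :], model.error_model, a, bb)[0]
            )
        return total, 0.0

    om_f = omega[np.ix_(free, free)]
    om_f_inv = np.linalg.inv(om_f)
    sgn, om_logdet = np.linalg.slogdet(om_f)
    df = 4.0
    M = int(n_is_samples)

    # modes + curvature: batched Newton when all three effects are free,
    # per-subject quasi-Newton otherwise (degenerate Omega)
    modes_all = np.zeros((prob.n, nf))
    hess_all = np.zeros((prob.n, nf, nf))
    if nf == 3:
        w_inv3 = _safe_inv(omega)
        _, logdet3 = np.linalg.slogdet(omega + 1e-30 * np.eye(3))
        tvec = _batched_target(prob, mean_phi_all, w_inv3, logdet3, model.error_model, a, bb)
        phi_modes, H_all, _ = _modes_newton(tvec, mean_phi_all.copy())
        modes_all = phi_modes - mean_phi_all
        hess_all = H_all
    else:
        for i in range(prob.n):
            def neg_post(ef, i=i):
                e = np.zeros(3)
                e[free] = ef
                phi = mean_phi_all[i] + e
                ll = float(
                    _subject_loglik_many(prob, i, phi[None, :], model.error_model, a, bb)[0]
                )
                lp = -0.5 * (nf * _LOG_2PI + om_logdet + ef @ om_f_inv @ ef)
                return -(ll + lp)

            modes_all[i] = _conditional_mode_free(neg_post, nf)
            hess_all[i] = _num_hessian(neg_post, modes_all[i])

    total = 0.0
    var_sum = 0.0
    for i in range(prob.n):
        mode = modes_all[i]
        hess = hess_all[i]
        try:
            cov_prop = 1.5**2 * np.linalg.inv(hess)
            L = np.linalg.cholesky(cov_prop)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"degenerate curvature for subject {prob.ids[i]}; widened prior-based proposal",
                RuntimeWarning,
            )
            L = np.linalg.cholesky(2.0 * om_f + 1e-8 * np.eye(nf))
            cov_prop = L @ L.T

        zn = rng.standard_normal((M, nf))
        u = rng.chisquare(df, size=M)
        draws = mode[None, :] + (zn * np.sqrt(df / u)[:, None]) @ L.T

        delta = draws - mode[None, :]
        sol = np.linalg.solve(L, delta.T).T
        maha = np.sum(sol**2, axis=1)
        _, logdet_prop = np.linalg.slogdet(cov_prop)
        logq = (
            math.lgamma((df + nf) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * (nf * math.log(df * math.pi) + logdet_prop)
            - 0.5 * (df + nf) * np.log1p(maha / df)
        )

        e3 = np.zeros((M, 3))
        e3[:, free] = draws
        phi = mean_phi_all[i][None, :] + e3
        ll = _subject_loglik_many(prob, i, phi, model.error_model, a, bb)
        lp = -0.5 * (
            nf * _LOG_2PI + om_logdet + np.einsum("ij,jk,ik->i", draws, om_f_inv, draws)
        )
        logw = ll + lp - logq
        lse = logsumexp(logw)
        total += float(lse - math.log(M))
        w = np.exp(logw - logw.max())
        mw = w.mean()
        var_sum += float(w.var(ddof=1) / M / mw**2)
    return total, math.sqrt(var_sum)


# ---------------------------------------------------------------------------
# model comparison


_ERROR_NPARAMS = {"additive": 1, "proportional": 1, "combined": 2}


def compare_error_models(
    data: PKDataset,
    skeleton: PopulationModel | None = None,
    cfg: SAEMConfig | None = None,
) -> pd.DataFrame:
    """Fit additive/proportional/combined error models and rank by BIC.

    Deterministic for fixed ``cfg.seed`` (per-model seeds are spawned from
    it).  Rows for models whose fit fails carry the error message and NaNs.
    """
    cfg = cfg or SAEMConfig()
    base = skeleton or PopulationModel(theta=(0.3, 2.0, 1.5))
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(ERROR_ORDER))]

    rows = []
    for em, sd in zip(ERROR_ORDER, child_seeds):
        row: dict = {"error_model": em}
        try:
            spec = replace_error_model(base, em)
            fit = fit_saem(data, spec, replace(cfg, seed=sd, compute_loglik=True))
            n_par = _count_params(fit, cfg)
            n_obs = len(_Problem(data, cfg).y)
            row.update(
                loglik=fit.loglik,
                mc_se=fit.loglik_se,
                n_params=n_par,
                aic=-2.0 * fit.loglik + 2.0 * n_par,
                bic=-2.0 * fit.loglik + n_par * math.log(n_obs),
                a=fit.model.error_params[0],
                b=fit.model.error_params[1],
                error=None,
            )
        except Exception as exc:  # keep other rows alive
            row.update(
                loglik=np.nan, mc_se=np.nan, n_params=np.nan, aic=np.nan, bic=np.nan,
                a=np.nan, b=np.nan, error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table["bic"].rank(method="first")
    table["rank"] = order.astype("Int64")
    return table.sort_values("bic", na_position="last").reset_index(drop=True)


ERROR_ORDER = ("additive", "proportional", "combined")


def replace_error_model(m: PopulationModel, error_model: str) -> PopulationModel:
    a, b = {"additive": (1.0, 0.0), "proportional": (0.0, 0.2), "combined": (1.0, 0.2)}[error_model]
    return PopulationModel(
        theta=m.theta, beta=dict(m.beta), omega=np.asarray(m.omega).copy(),
        error_model=error_model, error_params=(a, b),
    )


def _count_params(fit: FitResult, cfg: SAEMConfig) -> int:
    n_fixed = 3 + max(len(fit.groups) - 1, 0) * int(bool(fit.model.beta) and cfg.covariate_on_cl)
    n_omega = 3 if cfg.diagonal_omega else 6
    return n_fixed + n_omega + _ERROR_NPARAMS[fit.model.error_model]


def lrt(fit_null: FitResult, fit_alt: FitResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: (statistic, p).

    Negative statistics (Monte-Carlo noise) are clamped to 0 with a warning.
    """
    if fit_null.loglik is None or fit_alt.loglik is None:
        raise ValidationError("both fits need a log-likelihood estimate")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        warnings.warn("negative LRT statistic clamped to 0 (MC noise)", RuntimeWarning)
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df))
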