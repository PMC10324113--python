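"""Empirical-Bayes conditional modes and derived individual PK quantities.

The primary per-subject estimate is the conditional mode (MAP) of the random
effects given the fitted population model; conditional means from an MCMC run
are available as an option.  From the individual parameters, the steady-state
interval AUC (dose/CL) and elimination half-life are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import EstimationError
from .popmodel import (
    PKDataset,
    PopulationModel,
    Subject,
    individual_params,
    loglik_conditional,
    logprior_eta,
)
from .structural import StructuralParams, auc_tau, half_life

__all__ = [
    "IndividualEstimate",
    "conditional_mode",
    "conditional_mean",
    "derive_individual",
    "estimate_all",
    "eta_shrinkage",
    "sample_conditional",
]


@dataclass
class IndividualEstimate:
    subject_id: str
    group: str
    eta_hat: np.ndarray  # (3,) conditional mode, (log-cl, log-v, log-ka) order
    params: StructuralParams
    auc_tau: float  # ng*h/mL
    t_half: float  # h

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "eta_cl": float(self.eta_hat[0]),
            "eta_v": float(self.eta_hat[1]),
            "eta_ka": float(self.eta_hat[2]),
            "cl": self.params.cl,
            "v": self.params.v,
            "ka": self.params.ka,
            "auc_tau": self.auc_tau,
            "t_half": self.t_half,
        }


def _free_components(omega: np.ndarray) -> np.ndarray:
    """Boolean mask of random effects with non-degenerate prior variance."""
    return np.diag(np.asarray(omega, dtype=float)) > 1e-12


def _central_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros(x.size)
    for i in range(x.size):
        e = np.zeros(x.size)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        for j in range(i, d):
            ej = np.zeros(d)
            ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h**2)
    return H


def _conditional_mode_free(neg_post, nf: int, starts: list[np.ndarray] | None = None) -> np.ndarray:
    """Minimise a negative log-posterior over the free eta subspace.

    Multi-start quasi-Newton with Newton polishing; raises EstimationError
    (with the best iterate in the diagnostics) if the gradient norm never
    drops below 1e-6.
    """
    if starts is None:
        starts = [np.zeros(nf)]
    best_x, best_f = None, math.inf
    for x0 in starts:
        sol = optimize.minimize(neg_post, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
        if sol.fun < best_f:
            best_x, best_f = sol.x, float(sol.fun)
    # Newton polishing with damped steps to hit a tight stationarity tolerance
    x = np.asarray(best_x, dtype=float)
    fx = best_f
    for _ in range(50):
        g = _central_grad(neg_post, x)
        if np.linalg.norm(g) < 1e-7:
            break
        H = _num_hessian(neg_post, x)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(nf), g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        for _ in range(30):
            xn = x - t * step
            fn = neg_post(xn)
            if fn <= fx:
                x, fx = xn, fn
                break
            t *= 0.5
        else:
            break
    grad = _central_grad(neg_post, x)
    if np.linalg.norm(grad) > 1e-6:
        raise EstimationError(
            "conditional-mode optimisation did not converge",
            {"best_eta": x.tolist(), "grad_norm": float(np.linalg.norm(grad))},
        )
    return x


def _neg_posterior(model: PopulationModel, s: Subject, tau: float, free: np.ndarray,
                   blq_policy: str, lloq: float | None):
    omega = np.asarray(model.omega)

    def f(ef: np.ndarray) -> float:
        eta = np.zeros(3)
        eta[free] = ef
        return -(
            loglik_conditional(model, s, eta, tau=tau, blq_policy=blq_policy, lloq=lloq)
            + logprior_eta(omega, eta)
        )

    return f


def sample_conditional(
    model: PopulationModel,
    s: Subject,
    tau: float = 24.0,
    n_iter: int = 500,
    seed: int = 0,
    blq_policy: str = "exclude",
    lloq: float | None = None,
    scale: float = 0.3,
) -> np.ndarray:
    """Random-walk MH draws from the conditional posterior of eta.

    Returns an (n_iter, 3) array (components with zero prior variance stay 0).
    Used for mode refinement, conditional means and posterior diagnostics.
    """
    rng = np.random.default_rng(seed)
    free = _free_components(model.omega)
    neg_post = _neg_posterior(model, s, tau, free, blq_policy, lloq)
    nf = int(free.sum())
    out = np.zeros((n_iter, 3))
    if nf == 0:
        return out
    cur = np.zeros(nf)
    cur_lp = -neg_post(cur)
    for k in range(n_iter):
        prop = cur + scale * rng.standard_normal(nf)
        lp = -neg_post(prop)
        if math.log(rng.random()) < lp - cur_lp:
            cur, cur_lp = prop, lp
        out[k, free] = cur
    return out


def conditional_mode(
    model: PopulationModel,
    s: Subject,
    tau: float = 24.0,
    refine_mcmc: bool = False,
    seed: int = 0,
    blq_policy: str = "exclude",
    lloq: float | None = None,
) -> np.ndarray:
    """MAP estimate of a subject's random effects under the fitted model.

    A subject with no contributing observations gets the prior mode eta = 0;
    with ``refine_mcmc`` a short MH run supplies an extra optimiser start
    (guards flip-flop multimodality on very sparse subjects).
    """
    free = _free_components(model.omega)
    nf = int(free.sum())
    usable = [o for o in s.observations if not o.blq] or (
        s.observations if blq_policy != "exclude" else []
    )
    if nf == 0 or not usable:
        return np.zeros(3)
    neg_post = _neg_posterior(model, s, tau, free, blq_policy, lloq)
    starts = [np.zeros(nf)]
    if refine_mcmc:
        draws = sample_conditional(
            model, s, tau=tau, n_iter=200, seed=seed, blq_policy=blq_policy, lloq=lloq
        )[:, free]
        vals = [neg_post(d) for d in draws[::10]]
        starts.append(draws[::10][int(np.argmin(vals))])
    ef = _conditional_mode_free(neg_post, nf, starts)
    eta = np.zeros(3)
    eta[free] = ef
    return eta


def conditional_mean(
    model: PopulationModel,
    s: Subject,
    tau: float = 24.0,
    n_iter: int = 2000,
    burn: int = 500,
    seed: int = 0,
    blq_policy: str = "exclude",
    lloq: float | None = None,
) -> np.ndarray:
    """Posterior-mean eta from an MH run (optional alternative to the mode)."""
    draws = sample_conditional(
        model, s, tau=tau, n_iter=n_iter, seed=seed, blq_policy=blq_policy, lloq=lloq
    )
    return draws[burn:].mean(axis=0)


def derive_individual(model: PopulationModel, s: Subject, eta_hat) -> IndividualEstimate:
    """Individual parameters and secondary quantities from an eta estimate."""
    eta_hat = np.asarray(eta_hat, dtype=float)
    psi = individual_params(model, s, eta_hat)
    return IndividualEstimate(
        subject_id=s.id,
        group=s.group,
        eta_hat=eta_hat,
        params=psi,
        auc_tau=auc_tau(psi, s.dose),
        t_half=half_life(psi),
    )


def estimate_all(
    model: PopulationModel,
    data: PKDataset,
    refine_mcmc: bool = False,
    seed: int = 0,
    blq_policy: str = "exclude",
) -> list[IndividualEstimate]:
    """Conditional modes + derived quantities for every subject in a dataset.

    Uses a batched Newton pass over all subjects when the random-effect
    covariance is full rank (falls back to per-subject optimisation for
    degenerate Omega, refine_mcmc, or designs the batched path rejects).
    """
    eta_by_id: dict[str, np.ndarray] = {}
    if not refine_mcmc and _free_components(model.omega).all():
        try:
            eta_by_id = _batched_modes(model, data, blq_policy)
        except Exception:
            eta_by_id = {}
    out = []
    for k, s in enumerate(data.subjects):
        if s.id in eta_by_id:
            eta = eta_by_id[s.id]
        else:
            eta = conditional_mode(
                model, s, tau=data.tau, refine_mcmc=refine_mcmc, seed=seed + k,
                blq_policy=blq_policy, lloq=data.lloq,
            )
        out.append(derive_individual(model, s, eta))
    return out


def _batched_modes(model: PopulationModel, data: PKDataset, blq_policy: str) -> dict[str, np.ndarray]:
    from .saem import SAEMConfig, _batched_target, _modes_newton, _Problem, _safe_inv

    cfg = SAEMConfig(blq_policy=blq_policy, constrain_ka_gt_ke=False)
    prob = _Problem(data, cfg)
    omega = np.asarray(model.omega)
    w_inv = _safe_inv(omega)
    _, logdet = np.linalg.slogdet(omega)
    mean_phi = np.array(
        [
            [
                math.log(model.theta[0]) + model.group_effect(g),
                math.log(model.theta[1]),
                math.log(model.theta[2]),
            ]
            for g in prob.glabels
        ]
    )
    a, b = model.error_params
    tvec = _batched_target(prob, mean_phi, w_inv, logdet, model.error_model, a, b)
    modes, _, _ = _modes_newton(tvec, mean_phi.copy())
    return {sid: modes[i] - mean_phi[i] for i, sid in enumerate(prob.ids)}


def estimates_to_frame(estimates: list[IndividualEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in estimates])


def eta_shrinkage(estimates: list[IndividualEstimate], model: PopulationModel) -> dict[str, float]:
    """Per-component eta shrinkage 1 - SD(eta_hat)/sqrt(Omega_kk).

    Components with zero population variance are reported as NaN (undefined).
    Values near 1 flag designs too sparse to individualise that parameter.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 subjects to compute shrinkage")
    etas = np.array([e.eta_hat for e in estimates])
    om = np.diag(np.asarray(model.omega))
    out = {}
    for k, name in enumerate(("cl", "v", "ka")):
        if om[k] <= 1e-12:
            out[name] = float("nan")
        else:
            out[name] = float(1.0 - etas[:, k].std(ddof=1) / math.sqrt(om[k]))
    return out
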