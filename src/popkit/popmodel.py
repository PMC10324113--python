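"""Hierarchical population layer on top of the structural model.

Individual parameters arise from typical values, additive group effects on
log-clearance and multivariate-normal random effects on the log scale
("exponential" between-subject variability).  Residual error is additive,
proportional or combined.  The conditional log-densities defined here are the
building blocks of both SAEM and empirical-Bayes estimation.

Random-effect ordering is fixed everywhere as (log-cl, log-v, log-ka).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structural import StructuralParams, _conc_ss_ng_l

__all__ = [
    "ERROR_MODELS",
    "BLQ_POLICIES",
    "Observation",
    "Subject",
    "PKDataset",
    "PopulationModel",
    "individual_params",
    "residual_sd",
    "loglik_conditional",
    "logprior_eta",
]

ERROR_MODELS = ("additive", "proportional", "combined")

#: how below-LLOQ records enter the likelihood: dropped, imputed at LLOQ/2,
#: or treated as left-censored (M3)
BLQ_POLICIES = ("exclude", "loq_half", "censored")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Observation:
    """A single concentration measurement.

    ``time`` is hours since the last dose; ``conc`` is ng/mL and NaN when the
    record is below the limit of quantification (``blq`` set).
    """

    time: float
    conc: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time!r}")
        if not self.blq and (not math.isfinite(self.conc) or self.conc < 0):
            raise ValueError(
                f"non-BLQ concentration must be finite and >= 0, got {self.conc!r}"
            )


@dataclass
class Subject:
    id: str
    group: str
    dose: float  # ng
    observations: list[Observation] = field(default_factory=list)
    body_weight: float | None = None  # g, informational

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")


@dataclass
class PKDataset:
    """A study: subjects plus the shared dosing interval and group layout.

    ``groups`` is the ordered set of treatment labels; the first entry (or the
    explicit ``reference``) is the reference level whose group effect is 0.
    """

    subjects: list[Subject]
    tau: float = 24.0
    groups: tuple[str, ...] | None = None
    reference: str | None = None
    lloq: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        if self.groups is None:
            self.groups = tuple(seen)
        else:
            self.groups = tuple(self.groups)
            unknown = set(seen) - set(self.groups)
            if unknown:
                raise ValueError(f"subjects carry undeclared groups: {sorted(unknown)}")
        if self.reference is None:
            self.reference = self.groups[0] if self.groups else None
        elif self.reference not in self.groups:
            raise ValueError(f"reference group {self.reference!r} not among {self.groups}")
        for s in self.subjects:
            for o in s.observations:
                if o.time > self.tau:
                    raise ValueError(
                        f"subject {s.id}: observation time {o.time} outside [0, tau={self.tau}]"
                    )

    @property
    def n_obs(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_blq(self) -> int:
        return sum(o.blq for s in self.subjects for o in s.observations)


@dataclass
class PopulationModel:
    """Population parameters: typical values, group effects, Omega, error model.

    ``theta`` is (cl_pop L/h, v_pop L, ka_pop 1/h); ``beta`` maps group label
    to an additive effect on log-CL with the reference group pinned at 0;
    ``omega`` is the 3x3 random-effect covariance in (log-cl, log-v, log-ka)
    order; ``error_params`` is (a ng/mL, b unitless).
    """

    theta: tuple[float, float, float]
    beta: dict[str, float] = field(default_factory=dict)
    omega: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    error_model: str = "additive"
    error_params: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.theta = tuple(float(x) for x in self.theta)
        if len(self.theta) != 3 or any(x <= 0 for x in self.theta):
            raise ValueError(f"theta must be 3 positive values, got {self.theta!r}")
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (3, 3):
            raise ValueError(f"omega must be 3x3, got shape {self.omega.shape}")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(self.omega).min() < -1e-10:
            raise ValueError("omega must be positive semidefinite")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(
                f"error_model must be one of {ERROR_MODELS}, got {self.error_model!r}"
            )
        a, b = self.error_params
        if a < 0 or b < 0 or (a == 0 and b == 0):
            raise ValueError("error_params need a >= 0, b >= 0 and a + b > 0")

    def group_effect(self, group: str) -> float:
        if group in self.beta:
            return self.beta[group]
        return 0.0


def individual_params(m: PopulationModel, s: Subject | str, eta: Sequence[float]) -> StructuralParams:
    """Map population parameters + group + eta to individual structural params.

    cl_i = cl_pop * exp(beta[group] + eta1); v_i = v_pop * exp(eta2);
    ka_i = ka_pop * exp(eta3).  ``s`` may be a Subject or a bare group label.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError(f"eta must be a finite 3-vector, got {eta!r}")
    group = s.group if isinstance(s, Subject) else s
    if m.beta and group not in m.beta:
        raise ValueError(f"unknown group label {group!r}; known: {sorted(m.beta)}")
    cl_pop, v_pop, ka_pop = m.theta
    return StructuralParams(
        cl=cl_pop * math.exp(m.group_effect(group) + eta[0]),
        v=v_pop * math.exp(eta[1]),
        ka=ka_pop * math.exp(eta[2]),
    )


def residual_sd(m: PopulationModel, c_pred) -> float | np.ndarray:
    """Residual standard deviation (ng/mL) at predicted concentration(s)."""
    a, b = m.error_params
    c = np.asarray(c_pred, dtype=float)
    if np.any(c < 0):
        raise ValueError("predicted concentration must be >= 0")
    if m.error_model == "additive":
        out = np.full(c.shape, a)
    elif m.error_model == "proportional":
        out = b * c
    else:
        out = np.sqrt(a * a + b * b * c * c)
    return float(out) if out.ndim == 0 else out


def _predict_subject(m: PopulationModel, s: Subject, eta, tau: float, times) -> np.ndarray:
    psi = individual_params(m, s, eta)
    return _conc_ss_ng_l(s.dose, tau, np.asarray(times, float), psi.cl, psi.v, psi.ka) / 1000.0


def loglik_conditional(
    m: PopulationModel,
    s: Subject,
    eta,
    tau: float = 24.0,
    blq_policy: str = "exclude",
    lloq: float | None = None,
) -> float:
    """Gaussian observation log-density of a subject's data given eta.

    BLQ records are handled per ``blq_policy``: dropped (default), imputed at
    LLOQ/2, or entered as left-censored normal terms ("censored" / M3).
    Returns 0.0 for a subject with no contributing observations.
    """
    if blq_policy not in BLQ_POLICIES:
        raise ValueError(f"blq_policy must be one of {BLQ_POLICIES}, got {blq_policy!r}")
    if blq_policy != "exclude" and lloq is None:
        raise ValueError(f"blq_policy {blq_policy!r} requires an lloq")

    obs = s.observations
    if not obs:
        return 0.0
    times = np.array([o.time for o in obs])
    blq = np.array([o.blq for o in obs])
    y = np.array([o.conc for o in obs])
    pred = _predict_subject(m, s, eta, tau, times)
    sd = np.asarray(residual_sd(m, pred), dtype=float)
    sd = np.broadcast_to(sd, pred.shape)

    total = 0.0
    quant = ~blq
    if blq_policy == "loq_half":
        y = np.where(blq, lloq / 2.0, y)
        quant = np.ones_like(blq)
    if np.any(quant):
        r = y[quant] - pred[quant]
        sq = sd[quant]
        total += float(np.sum(-0.5 * _LOG_2PI - np.log(sq) - 0.5 * (r / sq) ** 2))
    if blq_policy == "censored" and np.any(blq):
        from scipy.stats import norm

        total += float(np.sum(norm.logcdf((lloq - pred[blq]) / sd[blq])))
    return total


def logprior_eta(omega, eta) -> float:
    """log N3(eta; 0, omega), supporting singular omega on its support.

    Components orthogonal to the support must be (numerically) zero, else
    -inf.  The density is evaluated on the support subspace.
    """
    omega = np.asarray(omega, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if omega.shape != (3, 3) or eta.shape != (3,):
        raise ValueError("omega must be 3x3 and eta a 3-vector")
    w, q = np.linalg.eigh(omega)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("omega must be positive semidefinite")
    tol = 1e-12 * max(1.0, float(w.max()))
    live = w > tol
    z = q.T @ eta
    if np.any(np.abs(z[~live]) > 1e-9):
        return -math.inf
    r = int(live.sum())
    if r == 0:
        return 0.0 if np.allclose(eta, 0.0, atol=1e-9) else -math.inf
    quad = float(np.sum(z[live] ** 2 / w[live]))
    return -0.5 * (r * _LOG_2PI + float(np.sum(np.log(w[live]))) + quad)
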