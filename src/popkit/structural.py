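"""One-compartment oral absorption model with first-order elimination.

Closed-form concentration-time curves for repeated oral dosing, both as an
explicit superposition of administered doses and in the steady-state limit,
plus the derived secondary quantities (interval AUC, elimination half-life,
time of peak).

Units: doses in ng, volumes in L, clearances in L/h, rate constants in 1/h,
times in h.  Concentrations are computed internally in ng/L and converted to
ng/mL (factor 1000) only at the public boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralParams",
    "DosingRegimen",
    "conc_multidose",
    "conc_steady_state",
    "half_life",
    "auc_tau",
    "tmax_single_dose",
]

#: relative |ka - ke| threshold below which the ka == ke limit branch is used
_KA_KE_REL_TOL = 1e-8


@dataclass(frozen=True)
class StructuralParams:
    """Individual-level structural parameters.

    Attributes
    ----------
    cl : float
        Apparent oral clearance CL/F, L/h.
    v : float
        Apparent volume of distribution V/F, L.
    ka : float
        First-order absorption rate constant, 1/h.
    """

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant CL/V, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing schedule: equal doses every ``tau`` hours."""

    dose: float  # ng
    tau: float = 24.0  # h
    n_doses: int = 5

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses!r}")


def _conc_single_ng_l(dose, s, cl, v, ka):
    """Single-dose concentration in ng/L at time ``s`` >= 0 after that dose.

    Vectorised over all arguments; negative ``s`` contributes 0 (dose not yet
    given).  Uses the t*exp(-k t) limit branch when ka is within
    ``_KA_KE_REL_TOL`` of ke to avoid catastrophic cancellation.
    """
    s = np.asarray(s, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ke = cl / v
    dose, s, cl, v, ka, ke = np.broadcast_arrays(dose, s, cl, v, ka, ke)

    out = np.zeros(s.shape, dtype=float)
    active = s >= 0
    near = np.abs(ka - ke) < _KA_KE_REL_TOL * ke

    reg = active & ~near
    if np.any(reg):
        amp = dose[reg] * ka[reg] / (v[reg] * (ka[reg] - ke[reg]))
        out[reg] = amp * (np.exp(-ke[reg] * s[reg]) - np.exp(-ka[reg] * s[reg]))

    lim = active & near
    if np.any(lim):
        k = ke[lim]
        out[lim] = dose[lim] * k / v[lim] * s[lim] * np.exp(-k * s[lim])
    return out


def _conc_ss_ng_l(dose, tau, t, cl, v, ka):
    """Steady-state concentration in ng/L at ``t`` in [0, tau] since last dose.

    Vectorised core shared with the estimation modules.
    """
    t = np.asarray(t, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ke = cl / v
    dose, tau, t, cl, v, ka, ke = np.broadcast_arrays(dose, tau, t, cl, v, ka, ke)

    out = np.empty(t.shape, dtype=float)
    near = np.abs(ka - ke) < _KA_KE_REL_TOL * ke

    reg = ~near
    if np.any(reg):
        amp = dose[reg] * ka[reg] / (v[reg] * (ka[reg] - ke[reg]))
        acc_e = -np.expm1(-ke[reg] * tau[reg])  # 1 - exp(-ke*tau), stable
        acc_a = -np.expm1(-ka[reg] * tau[reg])
        out[reg] = amp * (
            np.exp(-ke[reg] * t[reg]) / acc_e - np.exp(-ka[reg] * t[reg]) / acc_a
        )

    if np.any(near):
        # sum_{m>=0} (t+m*tau) e^{-k(t+m*tau)} = e^{-kt} [t/(1-r) + tau*r/(1-r)^2]
        k = ke[near]
        r = np.exp(-k * tau[near])
        geom = t[near] / (1.0 - r) + tau[near] * r / (1.0 - r) ** 2
        out[near] = dose[near] * k / v[near] * np.exp(-k * t[near]) * geom
    return out


def conc_multidose(p: StructuralParams, r: DosingRegimen, t: float) -> float:
    """Concentration (ng/mL) at time ``t`` (h) since the *first* dose.

    Superposes the single-dose curves of every dose administered up to ``t``
    (doses are given at 0, tau, ..., (n_doses-1)*tau).
    """
    if t < 0:
        raise ValueError(f"time since first dose must be >= 0, got {t!r}")
    since = t - r.tau * np.arange(r.n_doses)
    return float(np.sum(_conc_single_ng_l(r.dose, since, p.cl, p.v, p.ka))) / 1000.0


def conc_steady_state(p: StructuralParams, dose: float, tau: float, t) -> float:
    """Steady-state concentration (ng/mL) at ``t`` hours after the last dose.

    ``t`` may be a scalar or array in [0, tau]; ``dose`` in ng.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose!r}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > tau):
        raise ValueError(f"t must lie within [0, tau={tau}], got {t!r}")
    out = _conc_ss_ng_l(dose, tau, t_arr, p.cl, p.v, p.ka) / 1000.0
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def half_life(p: StructuralParams) -> float:
    """Elimination half-life ln(2) * V / CL, h."""
    return math.log(2.0) * p.v / p.cl


def auc_tau(p: StructuralParams, dose: float) -> float:
    """Steady-state AUC over one dosing interval, ng*h/mL (= dose/CL / 1000)."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose!r}")
    return dose / p.cl / 1000.0


def tmax_single_dose(p: StructuralParams) -> float:
    """Time of the single-dose concentration peak, h.

    ln(ka/ke)/(ka - ke), with the analytic limit 1/ke as ka -> ke.
    """
    ke = p.ke
    if abs(p.ka - ke) < _KA_KE_REL_TOL * ke:
        return 1.0 / ke
    return math.log(p.ka / ke) / (p.ka - ke)
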