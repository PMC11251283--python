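"""Linear-growth and Lipschitz constants, uniqueness condition, and runtime
positivity/boundedness monitors.

Writing the system with a global derivative ``D_n x = x'/n'`` (default
``n(t) = t``, so ``n' = 1``) each right-hand side ``X_i`` satisfies a linear
growth bound ``|X_i|^2 <= K_i (1 + |x_i|^2)`` and a Lipschitz bound with
constant ``Kbar_i``, both expressed through sup-norms of the compartments
over the run. Existence of a unique solution is certified when the maximum
of six sup-norm ratios is below one. Boundedness and positivity are checked
empirically on trajectories rather than through a symbolic invariant-set
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mittag_leffler import SupNorms
from .model import STATE_NAMES

__all__ = ["SupNorms", "GrowthReport", "supnorms_from_trajectory",
           "growth_and_lipschitz", "uniqueness_condition",
           "Violation", "MonitorReport", "monitor_trajectory"]

RATIO_NAMES = ("tumor", "cd8", "dendritic", "il2", "il12", "inhibitor")


def supnorms_from_trajectory(traj) -> SupNorms:
    """Componentwise max of |state| over the grid (empirical sup-norms);
    ``n_prime`` defaults to 1 (the ``n(t) = t`` reading)."""
    if len(traj) == 0:
        raise ValueError("trajectory must be nonempty")
    sup = np.max(np.abs(traj.states), axis=0)
    return SupNorms(*map(float, sup))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.inf


@dataclass(frozen=True)
class GrowthReport:
    """Linear-growth constants K1..K6, Lipschitz constants Kbar1..Kbar6, the
    six condition ratios, and the uniqueness verdict (max ratio < 1)."""

    K: tuple
    Kbar: tuple
    ratios: tuple
    uniqueness_max: float
    unique: bool

    def as_dict(self) -> dict:
        return {"K": dict(zip(STATE_NAMES, self.K)),
                "Kbar": dict(zip(STATE_NAMES, self.Kbar)),
                "ratios": dict(zip(RATIO_NAMES, self.ratios)),
                "uniqueness_max": self.uniqueness_max,
                "unique": self.unique}


def growth_and_lipschitz(p, s: SupNorms) -> GrowthReport:
    """Evaluate the growth/Lipschitz constants and condition ratios.

    The composite constants Kbar1..Kbar3 reference two sup-norms of the same
    compartment (two candidate solutions); the single trajectory sup-norm is
    used for both. Zero denominators yield an infinite ratio (condition
    fails), never an exception.
    """
    n2 = s.n_prime ** 2
    sT2, sC2, sD2 = s.sup_T ** 2, s.sup_C ** 2, s.sup_D ** 2
    sI22, sI122 = s.sup_IL2 ** 2, s.sup_IL12 ** 2
    al, be, ga, ph, ro, ka = p.alpha, p.beta, p.gamma, p.phi, p.rho, p.kappa
    mu, om, la, d, ps, a = p.mu, p.omega, p.lam, p.d, p.psi, p.a

    K = (2 * n2 * sT2 * al ** 2,
         2 * n2 * ka ** 2 * sC2,
         2 * n2 * mu ** 2,
         2 * n2 * sD2 * la ** 2,
         2 * n2 * d ** 2 * sI22,
         4 * n2 * ps ** 2 * sI122)
    Kbar = (2 * n2 * (2 * (al ** 2 + be ** 2 * al ** 2 * sT2)
                      + 3 * (al ** 2 * be ** 2 * sT2 + ph ** 2 * sC2 + ga ** 2)),
            n2 * (3 * ph ** 2 * sT2 + 3 * ro ** 2 * sD2 + 3 * ka ** 2),
            n2 * 3 * (ro ** 2 * sC2 + la ** 2 + om ** 2),
            n2 * d ** 2,
            n2 * ps ** 2,
            n2 * a ** 2)
    ratios = (_ratio(3 * (al ** 2 * be ** 2 * sT2 + ga ** 2 + ph ** 2 * sC2),
                     al ** 2 * sT2),
              _ratio(2 * (ph ** 2 * sT2 + ro ** 2 * sD2), ka ** 2 * sC2),
              _ratio(3 * (ro ** 2 * sC2 + om ** 2 + la ** 2), mu ** 2),
              _ratio(d ** 2, la ** 2 * sD2),
              _ratio(ps ** 2, d ** 2 * sI22),
              _ratio(a ** 2, ps ** 2 * sI122))
    umax = max(ratios)
    return GrowthReport(K=K, Kbar=Kbar, ratios=ratios,
                        uniqueness_max=umax, unique=umax < 1)


def uniqueness_condition(p, s: SupNorms) -> tuple[float, bool]:
    """Max of the six condition ratios and the verdict ``max < 1``."""
    rep = growth_and_lipschitz(p, s)
    return rep.uniqueness_max, rep.unique


@dataclass(frozen=True)
class Violation:
    time: float
    compartment: str
    value: float
    kind: str  # "negative" | "unbounded"


@dataclass(frozen=True)
class MonitorReport:
    violations: tuple
    bound_scale: tuple
    positivity_ok: bool
    bounded_ok: bool

    def as_dict(self) -> dict:
        return {"violations": [{"time": v.time, "compartment": v.compartment,
                                "value": v.value, "kind": v.kind}
                               for v in self.violations],
                "bound_scale": dict(zip(STATE_NAMES, self.bound_scale)),
                "positivity_ok": self.positivity_ok,
                "bounded_ok": self.bounded_ok}


def monitor_trajectory(traj, p=None, negative_tol: float = -1e-9,
                       bound_factor: float = 10.0) -> MonitorReport:
    """Scan a trajectory for positivity and boundedness violations.

    A negative excursion below ``negative_tol`` is reported per (time,
    compartment). Unbounded growth is flagged when |component| exceeds
    ``bound_factor`` times its natural scale ``max(x0_i, mu/(omega+lam))``
    (the initial value or the dendritic source/sink balance, whichever is
    larger); if no parameters are given the scale is the initial value alone.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must be nonempty")
    x0 = np.abs(traj.states[0])
    scale = x0.copy()
    if p is not None:
        scale = np.maximum(scale, p.mu / (p.omega + p.lam))
    scale = np.maximum(scale, 1e-300)
    bound = bound_factor * scale

    violations: list[Violation] = []
    for j, name in enumerate(STATE_NAMES):
        col = traj.states[:, j]
        for i in np.flatnonzero(col < negative_tol):
            violations.append(Violation(float(traj.times[i]), name,
                                        float(col[i]), "negative"))
        for i in np.flatnonzero(np.abs(col) > bound[j]):
            violations.append(Violation(float(traj.times[i]), name,
                                        float(col[i]), "unbounded"))
    pos_ok = not any(v.kind == "negative" for v in violations)
    bnd_ok = not any(v.kind == "unbounded" for v in violations)
    return MonitorReport(violations=tuple(violations),
                         bound_scale=tuple(map(float, bound)),
                         positivity_ok=pos_ok, bounded_ok=bnd_ok)
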