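"""Vector field, Jacobian, equilibria, reproduction number and sensitivities.

The model tracks six interacting compartments: tumor cells ``T`` with
logistic growth ``alpha*T*(1 - beta*T)`` killed by dendritic cells (rate
``gamma``) and by CD8+ T cells (rate ``phi``); CD8+ T cells ``C`` sustained
by tumor and dendritic-cell contact and dying at rate ``kappa``; dendritic
cells ``D`` produced by a constant source ``mu``, inactivated by CD8+
contact (rate ``rho``) and decaying at rate ``omega``; and a linear cytokine
chain ``D -> IL2 -> IL12 -> Z`` (rates ``lam``, ``d``, ``psi``) feeding the
anti-PD-L1 inhibitor compartment ``Z``, which decays at rate ``a``.

The CD8+ compartment behaves like the "infected" class of an epidemic
model: its persistence threshold is the basic reproduction number
``R0 = mu*rho / (kappa*(lam + omega))``.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha", "beta", "gamma", "phi", "rho", "kappa",
               "mu", "omega", "lam", "d", "psi", "a")
STATE_NAMES = ("T", "C", "D", "IL2", "IL12", "Z")

#: residual tolerance scale for returned equilibria
_RESIDUAL_RTOL = 1e-8


@dataclass(frozen=True)
class ModelParameters:
    """The twelve biological rate constants.

    alpha : tumor logistic growth rate (1/time)
    beta  : inverse tumor carrying capacity (1/cells)
    gamma : dendritic kill rate of tumor cells (1/time)
    phi   : CD8+ elimination rate of tumor cells (1/(cells*time))
    rho   : CD8+--dendritic interaction rate (1/(cells*time))
    kappa : CD8+ natural death rate (1/time)
    mu    : dendritic-cell source (cells/time)
    omega : dendritic natural death rate (1/time)
    lam   : IL-2 source rate from dendritic cells (1/time)
    d     : IL-2 -> IL-12 conversion rate (1/time)
    psi   : IL-12 -> Z conversion rate (1/time)
    a     : anti-PD-L1 natural death rate (1/time)
    """

    alpha: float
    beta: float
    gamma: float
    phi: float
    rho: float
    kappa: float
    mu: float
    omega: float
    lam: float
    d: float
    psi: float
    a: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive and "
                    f"finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        return cls(**{name: float(data[name]) for name in PARAM_NAMES})


@dataclass(frozen=True)
class StateVector:
    """One point of the six-compartment state.

    Components are finite; nonnegativity is a *monitored* property (the
    solver must be able to represent violations in order to report them).
    """

    T: float
    C: float
    D: float
    IL2: float
    IL12: float
    Z: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"state component {f.name!r} is not finite: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.C, self.D, self.IL2, self.IL12, self.Z],
                        dtype=float)

    @classmethod
    def from_array(cls, x) -> "StateVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError(f"expected 6 components, got shape {x.shape}")
        return cls(*map(float, x))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in STATE_NAMES}


class EquilibriumKind(str, enum.Enum):
    disease_free = "disease_free"
    endemic_interior = "endemic_interior"
    boundary = "boundary"


@dataclass(frozen=True)
class EquilibriumPoint:
    state: StateVector
    kind: EquilibriumKind
    residual: float
    discriminant_A: float | None = None

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")


def _state_array(x) -> np.ndarray:
    if isinstance(x, StateVector):
        return x.as_array()
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValueError(f"expected 6 state components, got shape {x.shape}")
    return x


def _check_finite_state(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(x))]
        raise ValueError(f"non-finite state component(s): {', '.join(bad)}")


def rhs(t: float, x, p) -> np.ndarray:
    """Time-derivative of the six compartments (pure function; ``t`` unused
    beyond signature compatibility -- the system is autonomous)."""
    xv = _state_array(x)
    _check_finite_state(xv)
    T, C, D, IL2, IL12, Z = xv
    return np.array([
        p.alpha * T * (1.0 - p.beta * T) - p.gamma * T - p.phi * C * T,
        p.phi * C * T + p.rho * C * D - p.kappa * C,
        p.mu - p.rho * C * D - p.omega * D - p.lam * D,
        p.lam * D - p.d * IL2,
        p.d * IL2 - p.psi * IL12,
        p.psi * IL12 - p.a * Z,
    ])


def jacobian(x, p) -> np.ndarray:
    """6x6 Jacobian of :func:`rhs` at ``x``, derived from the vector field.

    The (6, 4) entry is 0: the inhibitor equation ``Z' = psi*IL12 - a*Z``
    does not depend on IL2.
    """
    xv = _state_array(x)
    _check_finite_state(xv)
    T, C, D, _IL2, _IL12, _Z = xv
    J = np.zeros((6, 6))
    J[0, 0] = p.alpha - 2.0 * p.alpha * p.beta * T - p.gamma - p.phi * C
    J[0, 1] = -p.phi * T
    J[1, 0] = p.phi * C
    J[1, 1] = p.phi * T + p.rho * D - p.kappa
    J[1, 2] = p.rho * C
    J[2, 1] = -p.rho * D
    J[2, 2] = -(p.rho * C + p.omega + p.lam)
    J[3, 2] = p.lam
    J[3, 3] = -p.d
    J[4, 3] = p.d
    J[4, 4] = -p.psi
    J[5, 4] = p.psi
    J[5, 5] = -p.a
    return J


def disease_free_state(p) -> StateVector:
    """Tumor- and CD8+-free fixed point; the cytokine chain balances the
    dendritic source against each conversion/death rate."""
    s = p.omega + p.lam
    D = p.mu / s
    return StateVector(0.0, 0.0, D, p.mu * p.lam / (p.d * s),
                       p.mu * p.lam / (p.psi * s), p.mu * p.lam / (p.a * s))


def _residual(x: StateVector, p) -> float:
    return float(np.max(np.abs(rhs(0.0, x, p))))


def _passes_residual(x: StateVector, p) -> tuple[bool, float]:
    r = _residual(x, p)
    scale = 1.0 + float(np.max(np.abs(x.as_array())))
    return r < _RESIDUAL_RTOL * scale, r


def endemic_discriminant(p) -> float:
    """The square-root discriminant entering the interior closed forms."""
    inner = (p.rho * p.alpha * (p.phi - p.beta * p.kappa)
             + p.phi * (-p.rho * p.gamma + p.phi * (p.omega + p.lam)))
    return math.sqrt(4.0 * p.beta * p.alpha * p.mu * p.rho ** 2 * p.phi ** 2
                     + inner ** 2)


def _endemic_branch(p, sign: int) -> StateVector | None:
    """Closed-form interior candidate; ``sign=+1`` is the printed branch."""
    A = sign * endemic_discriminant(p)
    al, be, ga, ph, ro, ka = p.alpha, p.beta, p.gamma, p.phi, p.rho, p.kappa
    om, la = p.omega, p.lam
    T = (ka * ro * be * al + ph * ro * al - ph * ro * ga
         + ph ** 2 * la + om * ph ** 2 - A) / (2.0 * ro * be * al * ph)
    C = -(ka * ro * be * al - ph * ro * al + ph * ro * ga
          + ph ** 2 * la + om * ph ** 2 - A) / (2.0 * ph ** 2 * ro)
    common = (ka * ro * be * al - ph * ro * al + ph * ro * ga
              - ph ** 2 * la - om * ph ** 2 + A)
    D = common / (2.0 * be * ro ** 2 * al)
    IL2 = la * common / (2.0 * p.d * be * al * ro ** 2)
    IL12 = la * common / (2.0 * be * al * ro ** 2 * p.psi)
    Z = la * common / (2.0 * p.a * be * al * ro ** 2)
    vals = (T, C, D, IL2, IL12, Z)
    if not all(math.isfinite(v) for v in vals):
        return None
    return StateVector(*vals)


def _boundary_branch(p) -> StateVector | None:
    """Tumor-free, CD8+-positive fixed point: T = 0, D = kappa/rho, C from
    the dendritic balance. Exists iff R0 > 1."""
    D = p.kappa / p.rho
    C = p.mu / p.kappa - (p.omega + p.lam) / p.rho
    IL2 = p.lam * D / p.d
    IL12 = p.lam * D / p.psi
    Z = p.lam * D / p.a
    vals = (0.0, C, D, IL2, IL12, Z)
    if not all(math.isfinite(v) for v in vals):
        return None
    return StateVector(*vals)


def equilibria(p) -> list[EquilibriumPoint]:
    """All fixed points: the disease-free point (always), any positive
    interior closed-form branch, and the tumor-free boundary point when it
    is positive. Every returned point satisfies the residual invariant."""
    out: list[EquilibriumPoint] = []

    dfe = disease_free_state(p)
    ok, r = _passes_residual(dfe, p)
    if not ok:  # pragma: no cover - closed form is exact
        raise ArithmeticError(f"disease-free residual {r} exceeds tolerance")
    out.append(EquilibriumPoint(dfe, EquilibriumKind.disease_free, r))

    A = endemic_discriminant(p)
    for sign in (+1, -1):
        cand = _endemic_branch(p, sign)
        if cand is None:
            continue
        if not all(v > 0 for v in cand.as_array()):
            continue
        ok, r = _passes_residual(cand, p)
        if ok:
            out.append(EquilibriumPoint(cand, EquilibriumKind.endemic_interior,
                                        r, discriminant_A=A))

    bnd = _boundary_branch(p)
    if bnd is not None and all(v > 0 for v in bnd.as_array()[1:]):
        ok, r = _passes_residual(bnd, p)
        if ok:
            out.append(EquilibriumPoint(bnd, EquilibriumKind.boundary, r))
    return out


def reproduction_number(p) -> float:
    """Basic reproduction number ``R0 = mu*rho / (kappa*(lam + omega))``."""
    den = p.kappa * (p.lam + p.omega)
    if den == 0:
        raise ValueError("kappa*(lam + omega) must be nonzero")
    return p.mu * p.rho / den


def reproduction_number_ngm(p) -> float:
    """R0 via an explicit next-generation-matrix construction.

    Infected set = {C} only: the new-infection term is the dendritic
    recruitment rho*C*D linearized at the disease-free point
    (F = rho*mu/(lam+omega)); all remaining C-losses form the transition
    V = kappa. R0 is the spectral radius of F V^-1. The tumor-contact term
    phi*C*T vanishes in the linearization because T = 0 at the
    disease-free point.
    """
    s = p.lam + p.omega
    if p.kappa == 0 or s == 0:
        raise ValueError("kappa and lam + omega must be nonzero")
    F = np.array([[p.rho * p.mu / s]])
    V = np.array([[p.kappa]])
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


@dataclass(frozen=True)
class SensitivityEntry:
    parameter: str
    derivative: float
    elasticity: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.derivative))


@dataclass(frozen=True)
class SensitivityTable:
    """Partial derivatives of R0 with respect to (mu, rho, kappa, lam, omega)
    plus normalized elasticities (p/R0) * dR0/dp."""

    entries: dict[str, SensitivityEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SensitivityEntry:
        return self.entries[name]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {k: {"derivative": e.derivative, "elasticity": e.elasticity,
                    "sign": e.sign} for k, e in self.entries.items()}


def sensitivity_indices(p) -> SensitivityTable:
    """Analytic dR0/dp for the five parameters entering R0.

    Signs are (+, +, -, -, -) for (mu, rho, kappa, lam, omega); dR0/dmu is
    positive by the formula rho/(kappa*(lam+omega)) even though some
    presentations tabulate it as negative.
    """
    ka, la, om = p.kappa, p.lam, p.omega
    s = la + om
    r0 = reproduction_number(p)
    derivs = {
        "mu": p.rho / (ka * s),
        "rho": p.mu / (ka * s),
        "kappa": -p.mu * p.rho / (ka ** 2 * s),
        "lam": -p.mu * p.rho / (ka * s ** 2),
        "omega": -p.mu * p.rho / (ka * s ** 2),
    }
    logger.warning(
        "dR0/dmu = rho/(kappa*(lam+omega)) = %.6g > 0; tabulations listing a "
        "negative sign for this derivative are inconsistent with the formula.",
        derivs["mu"])
    entries = {
        name: SensitivityEntry(name, dv, float(getattr(p, name)) / r0 * dv)
        for name, dv in derivs.items()
    }
    return SensitivityTable(entries)
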