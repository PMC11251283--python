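"""One-parameter Mittag-Leffler function and compartment positivity bounds.

``E_xi(z) = sum_k z**k / Gamma(xi*k + 1)`` generalizes the exponential
(``E_1 = exp``) and is the kernel of the Atangana-Baleanu / fractal-
fractional derivative used by the solver. Each compartment of the model
admits a closed-form lower bound of the type
``x(t) >= x(0) * E_xi(-const * t**xi)`` obtained by bounding its loss terms
with sup-norms of the coupled compartments; those bounds certify positivity
of solutions as long as their denominators stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath

from .model import STATE_NAMES, _state_array

__all__ = ["MLSettings", "MLConvergenceError", "ml",
           "SupNorms", "PositivityBound", "positivity_bound"]

_MAX_ABS_ARG = 1e4
_MAX_GUARD_DIGITS = 300


@dataclass(frozen=True)
class MLSettings:
    """Series evaluation control.

    series_tolerance : relative term-size cutoff, in (0, 1e-6]
    max_terms        : hard cap on series terms, >= 50
    """

    series_tolerance: float = 1e-16
    max_terms: int = 10000

    def __post_init__(self) -> None:
        if not (0 < self.series_tolerance <= 1e-6):
            raise ValueError("series_tolerance must be in (0, 1e-6]")
        if self.max_terms < 50:
            raise ValueError("max_terms must be >= 50")


DEFAULT_SETTINGS = MLSettings()


class MLConvergenceError(ArithmeticError):
    """Series did not converge within ``max_terms``; carries the partial sum."""

    def __init__(self, message: str, partial_sum: float):
        super().__init__(message)
        self.partial_sum = partial_sum


def ml(xi: float, z: float, settings: MLSettings = DEFAULT_SETTINGS) -> float:
    """Evaluate ``E_xi(z)`` by the power series with adaptive truncation.

    The alternating series for negative arguments loses all double-precision
    accuracy once terms exceed ~1e16 times the result, so the sum is
    accumulated in extended precision sized to the worst-case term growth
    and rounded to a float at the end. Restricted to real ``z`` with
    ``|z| <= 1e4`` (all in-package uses are moderate negative arguments).
    """
    if not (0 < xi <= 1):
        raise ValueError(f"order xi must be in (0, 1], got {xi}")
    if not math.isfinite(z):
        raise ValueError(f"argument must be finite, got {z}")
    if abs(z) > _MAX_ABS_ARG:
        raise ValueError(f"|z| <= {_MAX_ABS_ARG:g} required, got {z}")
    if z == 0.0:
        return 1.0

    # Largest term magnitude ~ exp(|z|**(1/xi)) (saddle of |z|^k/Gamma(xi k+1)
    # at k* = |z|**(1/xi)/xi); add its decimal size to the working precision
    # to absorb the cancellation of the alternating sum.
    guard = abs(z) ** (1.0 / xi) / math.log(10.0) if z < 0 else 0.0
    if guard > _MAX_GUARD_DIGITS:
        raise MLConvergenceError(
            f"E_{xi}({z}): series cancellation (~{guard:.0f} digits) exceeds "
            f"the {_MAX_GUARD_DIGITS}-digit working-precision cap",
            float("nan"))
    dps = int(30 + guard)
    with mpmath.workdps(dps):
        zm = mpmath.mpf(z)
        xim = mpmath.mpf(xi)  # promote BEFORE forming xi*k+1: a double-
        # precision gamma argument would break the extended-precision sum
        s = mpmath.mpf(1)
        prev_mag = mpmath.mpf(1)
        converged = False
        for k in range(1, settings.max_terms + 1):
            term = zm ** k / mpmath.gamma(xim * k + 1)
            s += term
            mag = abs(term)
            # stop only past the term-magnitude peak; for z < 0 the result
            # lies in (0, 1] while mid-series partial sums can be huge, so
            # the cutoff there is absolute rather than relative
            cutoff = settings.series_tolerance * ((1 + abs(s)) if z > 0 else 1)
            if mag <= prev_mag and mag < cutoff:
                converged = True
                break
            prev_mag = mag
        if not converged:
            raise MLConvergenceError(
                f"E_{xi}({z}) series did not converge in {settings.max_terms} terms",
                float(s))
        return float(s)


@dataclass(frozen=True)
class SupNorms:
    """Sup-norm bounds ||.||_inf of the six compartments over a run, plus a
    bound on |n'| for the global-derivative reading (default n(t)=t)."""

    sup_T: float
    sup_C: float
    sup_D: float
    sup_IL2: float
    sup_IL12: float
    sup_Z: float
    n_prime: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sup_T", "sup_C", "sup_D", "sup_IL2", "sup_IL12", "sup_Z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.n_prime > 0:
            raise ValueError("n_prime must be positive (n'(x) != 0)")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in
                ("sup_T", "sup_C", "sup_D", "sup_IL2", "sup_IL12", "sup_Z",
                 "n_prime")}


@dataclass(frozen=True)
class PositivityBound:
    compartment: str
    time: float
    bound: float
    decay_rate_argument: float
    supnorm_inputs: dict = field(default_factory=dict)
    b: float = 1.0
    ab_norm: float = 1.0


def _loss_rate(compartment: str, p, s: SupNorms) -> float:
    """Sup-norm bound on the per-capita loss rate of one compartment."""
    if compartment == "T":
        return p.alpha * p.beta * s.sup_T + p.gamma + p.phi * s.sup_C
    if compartment == "C":
        return -p.rho * s.sup_D + p.kappa - p.phi * s.sup_T
    if compartment == "D":
        return p.lam + p.omega + p.rho * s.sup_C
    if compartment == "IL2":
        return p.d
    if compartment == "IL12":
        return p.psi
    if compartment == "Z":
        return p.a
    raise ValueError(f"unknown compartment {compartment!r}")


def positivity_bound(compartment: str, t: float, x0, p, orders, supnorms: SupNorms,
                     b: float = 1.0,
                     settings: MLSettings = DEFAULT_SETTINGS) -> PositivityBound:
    """Closed-form lower bound ``x(0) * E_xi(arg)`` for one compartment.

    ``arg = -b**(1-eta) * xi * r * t**xi / (AB(xi) - (1-xi)*r)`` with ``r``
    the sup-norm loss rate of the compartment; raises a domain error when
    the denominator ``AB(xi) - (1-xi)*r`` is nonpositive (the bound is then
    undefined -- large sup-norms push the construction outside its premises).
    ``b`` is a caller-supplied time-scale constant defaulting to 1.
    """
    from .solver import ab_normalization

    if t < 0:
        raise ValueError("t must be nonnegative")
    if b <= 0:
        raise ValueError("b must be positive")
    xi, eta = orders.xi, orders.eta
    x0v = _state_array(x0)
    idx = STATE_NAMES.index(compartment)
    r = _loss_rate(compartment, p, supnorms)
    ab = ab_normalization(xi)
    den = ab - (1.0 - xi) * r
    if den <= 0:
        raise ValueError(
            f"positivity bound undefined for {compartment}: "
            f"AB(xi) - (1-xi)*rate = {den:g} <= 0")
    arg = -(b ** (1.0 - eta)) * xi * r * t ** xi / den
    bound = float(x0v[idx]) * ml(xi, arg, settings)
    return PositivityBound(compartment=compartment, time=float(t), bound=bound,
                           decay_rate_argument=float(arg),
                           supnorm_inputs=supnorms.as_dict(), b=float(b),
                           ab_norm=float(ab))
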