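"""Fractal-fractional integrator with Mittag-Leffler kernel.

The state obeys ``D^{xi,eta} x = F(t, x)`` where ``D^{xi,eta}`` is the
fractal-fractional derivative of order ``xi`` and fractal dimension ``eta``
with Atangana-Baleanu (Mittag-Leffler) kernel. Its Volterra form is

    x(t) = x(0) + eta*(1-xi)/AB(xi) * t**(eta-1) * F(t, x(t))
         + xi*eta/(AB(xi)*Gamma(xi)) *
           integral_0^t  s**(eta-1) * F(s, x(s)) * (t - s)**(xi-1) ds

with ``AB(xi) = 1 - xi + xi/Gamma(xi)``. The discretization interpolates
the fractal-weighted history ``y(s) = s**(eta-1) * F(s, x(s))`` with
piecewise quadratic (three-point Newton) polynomials on each grid panel
``[t_w, t_{w+1}]`` and integrates them against the singular kernel exactly,
which yields three weighted history sums per step (weights
:func:`kernel_weights`). The two leading panels ``[t_0, t_2]`` -- where no
backward nodes exist -- use the first available nodes with the same
exact-moment quadrature, so the full memory integral ``[0, t]`` is covered
and the ``xi = eta = 1`` limit collapses to a classical linear multistep
method. The full history is re-summed every step (O(N^2) overall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import STATE_NAMES, _state_array, rhs

__all__ = ["FractionalOrders", "SolverConfig", "Trajectory", "IntegrationError",
           "ab_normalization", "kernel_weights", "simulate_ffm",
           "simulate_classical", "convergence_order", "ConvergenceReport"]


@dataclass(frozen=True)
class FractionalOrders:
    """Fractional order ``xi`` and fractal dimension ``eta``, both in (0, 1].

    ``eta`` is the operator's second index (often written as a second
    lambda); it is renamed here to avoid a clash with the IL-2 source rate.
    """

    xi: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.xi <= 1):
            raise ValueError(f"xi must be in (0, 1], got {self.xi}")
        if not (0 < self.eta <= 1):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")


@dataclass(frozen=True)
class SolverConfig:
    """Step size, horizon and output thinning.

    ``t_end`` must be at least ``3*dt`` (the quadratic history scheme needs
    three seed points) and an integer multiple of ``dt``.
    """

    dt: float
    t_end: float
    bootstrap: str = "fractional_euler"
    store_every: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.t_end < 3 * self.dt:
            raise ValueError("t_end must be >= 3*dt")
        n = round(self.t_end / self.dt)
        if abs(n * self.dt - self.t_end) > 1e-9 * max(1.0, self.t_end):
            raise ValueError("t_end must be an integer multiple of dt")
        if self.bootstrap != "fractional_euler":
            raise ValueError(f"unknown bootstrap rule {self.bootstrap!r}")
        if not (isinstance(self.store_every, int) and self.store_every >= 1):
            raise ValueError("store_every must be a positive integer")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus aligned states; ``states[0]`` is the initial condition."""

    times: np.ndarray
    states: np.ndarray
    orders: FractionalOrders
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        # 17 significant digits: round-trips every double exactly
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, orders: FractionalOrders | None = None) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(times=df["t"].to_numpy(),
                   states=df[list(STATE_NAMES)].to_numpy(),
                   orders=orders or FractionalOrders(1.0, 1.0))


class IntegrationError(RuntimeError):
    """Non-finite state during integration; carries the last valid step."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


def ab_normalization(xi: float) -> float:
    """Normalization ``AB(xi) = 1 - xi + xi/Gamma(xi)`` of the ML kernel."""
    if not (0 < xi <= 1):
        raise ValueError(f"xi must be in (0, 1], got {xi}")
    return 1.0 - xi + xi / math.gamma(xi)


def kernel_weights(rho_idx: int, xi: float):
    """The three bracket weight sequences of the simplified Newton scheme.

    For the current step ``rho_idx`` and each history panel index
    ``w = 2..rho_idx`` (``delta = rho_idx - w``):

        w0 = (delta+1)**xi - delta**xi
        w1 = (delta+1)**xi*(delta+3+2*xi) - delta**xi*(delta+3+3*xi)
        w2 = (delta+1)**xi*(2*delta**2 + (10+3*xi)*delta + 12+9*xi+2*xi**2)
           - delta**xi   *(2*delta**2 + (5*xi+10)*delta + 12+18*xi+6*xi**2)

    Returned as arrays ordered by ``w`` ascending. ``sum(w0) ==
    (rho_idx-1)**xi`` (telescoping).
    """
    if rho_idx < 2:
        raise ValueError("kernel weights require rho_idx >= 2")
    delta = np.arange(rho_idx - 2, -1, -1, dtype=float)  # w = 2..rho_idx
    dp1 = (delta + 1.0) ** xi
    dp0 = delta ** xi
    w0 = dp1 - dp0
    w1 = dp1 * (delta + 3.0 + 2.0 * xi) - dp0 * (delta + 3.0 + 3.0 * xi)
    w2 = (dp1 * (2.0 * delta ** 2 + (10.0 + 3.0 * xi) * delta
                 + 12.0 + 9.0 * xi + 2.0 * xi ** 2)
          - dp0 * (2.0 * delta ** 2 + (5.0 * xi + 10.0) * delta
                   + 12.0 + 18.0 * xi + 6.0 * xi ** 2))
    return w0, w1, w2


def _panel_moments(a: float, w: int, xi: float):
    """Exact kernel moments over panel ``[t_w, t_{w+1}]`` for target node
    ``a`` (in grid units): ``m_j = int (s - t_0-like factors) * u**(xi-1)``
    expressed via ``u = a - s``; returns (m0, m1, m2) such that

        int_{t_w}^{t_{w+1}} P(s) (t_a - s)**(xi-1) ds
            = dt**xi * [ y0*m0 + dy*m1 + d2y/2*m2 ]

    for the Newton polynomial through nodes (0, 1, 2) in grid units.
    """
    u1, u2 = a - w - 1.0, a - w
    p0 = (u2 ** xi - u1 ** xi) / xi
    p1 = (u2 ** (xi + 1.0) - u1 ** (xi + 1.0)) / (xi + 1.0)
    p2 = (u2 ** (xi + 2.0) - u1 ** (xi + 2.0)) / (xi + 2.0)
    m0 = p0
    m1 = a * p0 - p1                                   # int (s-t_0) u^{xi-1}
    m2 = a * (a - 1.0) * p0 - (2.0 * a - 1.0) * p1 + p2  # int (s-t_0)(s-t_1)
    return m0, m1, m2


def _make_field(p) -> Callable[[float, np.ndarray], np.ndarray]:
    al, be, ga, ph, ro, ka = p.alpha, p.beta, p.gamma, p.phi, p.rho, p.kappa
    mu, om, la, d, ps, a = p.mu, p.omega, p.lam, p.d, p.psi, p.a

    def f(t: float, x: np.ndarray) -> np.ndarray:
        T, C, D, IL2, IL12, Z = x
        return np.array([
            al * T * (1.0 - be * T) - ga * T - ph * C * T,
            ph * C * T + ro * C * D - ka * C,
            mu - ro * C * D - om * D - la * D,
            la * D - d * IL2,
            d * IL2 - ps * IL12,
            ps * IL12 - a * Z,
        ])

    return f


def simulate_ffm(p, x0, orders: FractionalOrders, cfg: SolverConfig) -> Trajectory:
    """Integrate the fractal-fractional system on a uniform grid.

    Deterministic: identical inputs give bit-identical trajectories. Raises
    :class:`IntegrationError` (carrying the last valid step) if the state
    leaves the finite range.
    """
    xi, eta = orders.xi, orders.eta
    x0v = _state_array(x0)
    if not np.all(np.isfinite(x0v)):
        raise ValueError("initial state must be finite")
    f = _make_field(p)
    N = cfg.n_steps
    dt = cfg.dt
    times = np.arange(N + 1) * dt

    ab = ab_normalization(xi)
    lead = eta * (1.0 - xi) / ab
    c_hist = xi * eta / (ab * math.gamma(xi))          # outer Volterra factor
    dtxi = dt ** xi
    A1 = xi * eta * dtxi / (ab * math.gamma(xi + 1.0))
    A2 = xi * eta * dtxi / (ab * math.gamma(xi + 2.0))
    A3 = xi * eta * dtxi / (2.0 * ab * math.gamma(xi + 3.0))

    # fractal node weights t_k**(eta-1); the singular node t_0 (eta < 1) is
    # clamped to the first positive grid node (exact at eta = 1)
    g = np.empty(N + 1)
    g[1:] = times[1:] ** (eta - 1.0)
    g[0] = dt ** (eta - 1.0)

    X = np.empty((N + 1, 6))
    Y = np.empty((N + 1, 6))  # fractal-weighted field history g_k * F^k
    X[0] = x0v
    Y[0] = g[0] * f(0.0, x0v)

    for r in range(N):  # build X[r+1]
        a = float(r + 1)
        acc = x0v + lead * Y[r]
        if r == 0:
            # one-term fractional Euler seed: constant interpolant on [t0, t1]
            m0, _, _ = _panel_moments(a, 0, xi)
            acc = acc + c_hist * dtxi * (Y[0] * m0)
        elif r == 1:
            # linear interpolant through nodes 0,1 on both leading panels
            dy = Y[1] - Y[0]
            for w in (0, 1):
                m0, m1, _ = _panel_moments(a, w, xi)
                acc = acc + c_hist * dtxi * (Y[0] * m0 + dy * m1)
        else:
            # leading panels [t0,t1], [t1,t2]: quadratic through nodes 0,1,2
            d1 = Y[1] - Y[0]
            d2 = Y[2] - 2.0 * Y[1] + Y[0]
            for w in (0, 1):
                m0, m1, m2 = _panel_moments(a, w, xi)
                acc = acc + c_hist * dtxi * (Y[0] * m0 + d1 * m1 + 0.5 * d2 * m2)
            # backward-node panels w = 2..r with the simplified weights
            w0, w1, w2 = kernel_weights(r, xi)
            S1 = w0 @ Y[0:r - 1]
            S2 = w1 @ (Y[1:r] - Y[0:r - 1])
            S3 = w2 @ (Y[2:r + 1] - 2.0 * Y[1:r] + Y[0:r - 1])
            acc = acc + A1 * S1 + A2 * S2 + A3 * S3

        if not np.all(np.isfinite(acc)):
            raise IntegrationError(
                f"non-finite state at t = {times[r + 1]:g}",
                last_time=float(times[r]), last_state=X[r].copy())
        X[r + 1] = acc
        Y[r + 1] = g[r + 1] * f(times[r + 1], acc)

    sl = slice(None, None, cfg.store_every)
    meta = {"parameters": {k: float(getattr(p, k)) for k in
                           ("alpha", "beta", "gamma", "phi", "rho", "kappa",
                            "mu", "omega", "lam", "d", "psi", "a")},
            "dt": dt, "t_end": cfg.t_end, "store_every": cfg.store_every,
            "scheme": "ffm-newton"}
    return Trajectory(times=times[sl].copy(), states=X[sl].copy(),
                      orders=orders, meta=meta)


def simulate_classical(p, x0, cfg: SolverConfig) -> Trajectory:
    """High-accuracy adaptive reference integration of the integer-order
    system (the ``xi = eta = 1`` limit), sampled on the solver grid."""
    x0v = _state_array(x0)
    f = _make_field(p)
    times = np.arange(cfg.n_steps + 1) * cfg.dt
    sol = solve_ivp(f, (0.0, cfg.t_end), x0v, method="DOP853",
                    rtol=1e-10, atol=1e-12, t_eval=times)
    if not sol.success:
        raise IntegrationError("reference integrator failed: " + sol.message,
                               last_time=float(sol.t[-1]),
                               last_state=sol.y[:, -1].copy())
    states = sol.y.T.copy()
    states[0] = x0v
    sl = slice(None, None, cfg.store_every)
    return Trajectory(times=times[sl].copy(), states=states[sl].copy(),
                      orders=FractionalOrders(1.0, 1.0),
                      meta={"scheme": "classical-dop853", "dt": cfg.dt,
                            "t_end": cfg.t_end})


@dataclass(frozen=True)
class ConvergenceReport:
    dts: tuple
    errors: tuple
    orders: tuple
    estimated_order: float
    monotone: bool


def convergence_order(p, x0, orders: FractionalOrders, base_dt: float,
                      t_end: float = 10.0) -> ConvergenceReport:
    """Self-convergence study: run dt, dt/2, dt/4 against a dt/8 reference
    and report the observed log2 error ratios. The error is the terminal-
    time max-norm difference relative to the reference scale: for xi < 1
    the memory solution carries a weakly singular t**(eta-1)-type transient
    at 0+, so pointwise early-grid errors saturate and the endpoint error is
    the standard convergence measure. Non-monotone error decrease is
    reported, not raised."""
    dts = (base_dt, base_dt / 2.0, base_dt / 4.0)
    ref_dt = base_dt / 8.0
    ref = simulate_ffm(p, x0, orders, SolverConfig(dt=ref_dt, t_end=t_end))
    scale = max(1.0, float(np.max(np.abs(ref.states))))
    errors = []
    for dt in dts:
        traj = simulate_ffm(p, x0, orders, SolverConfig(dt=dt, t_end=t_end))
        err = np.max(np.abs(traj.states[-1] - ref.states[-1])) / scale
        errors.append(float(err))
    orders_obs = tuple(math.log2(errors[i] / errors[i + 1])
                       for i in range(len(errors) - 1)
                       if errors[i + 1] > 0)
    monotone = all(errors[i] > errors[i + 1] for i in range(len(errors) - 1))
    est = float(np.mean(orders_obs)) if orders_obs else float("nan")
    return ConvergenceReport(dts=dts, errors=tuple(errors), orders=orders_obs,
                             estimated_order=est, monotone=monotone)
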