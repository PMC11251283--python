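"""Local spectra, linear-feedback stabilization, and Lyapunov scans.

At the disease-free point the Jacobian is lower triangular, so its spectrum
has the closed form ``{-a, -d, alpha-gamma, -psi, -lam-omega,
(mu*rho - kappa*(lam+omega))/(lam+omega)}``: the point is locally
asymptotically stable iff both ``alpha < gamma`` and ``R0 < 1``. Linear
feedback control subtracts ``w_i * (x_i - x_i*)`` from each equation, which
shifts the Jacobian diagonal by ``-w_i`` and can render any equilibrium
spectrum stable for large enough gains. Global stability is probed with the
Volterra-type Lyapunov function ``L = sum_i (x_i - x_i* - x_i* log(x_i/x_i*))``
whose derivative along trajectories splits into a positive aggregate Sigma
and a negative aggregate Omega; ``Sigma < Omega`` certifies decrease
(LaSalle invariance argument).

Note: for fractional orders xi < 1 the Matignon sector criterion
``|arg(eig)| > xi*pi/2`` is *weaker* than negativity of real parts; the
verdicts here use real parts and therefore remain sufficient for every
xi in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import EquilibriumPoint, StateVector, _state_array, jacobian, rhs

__all__ = ["ControlGains", "SpectrumReport", "LyapunovRecord",
           "GlobalStabilityReport", "dfe_spectrum_closed_form", "spectrum_at",
           "controlled_spectrum", "lyapunov_terms", "global_stability_scan"]

_TIE_BAND = 1e-12


@dataclass(frozen=True)
class ControlGains:
    """Nonnegative feedback gains w1..w6; all-zero reproduces the
    uncontrolled system."""

    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 0.0
    w5: float = 0.0
    w6: float = 0.0

    def __post_init__(self) -> None:
        for i, v in enumerate(self.as_array(), start=1):
            if v < 0:
                raise ValueError(f"gain w{i} must be nonnegative, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5, self.w6])


def _verdict(max_real: float) -> str:
    if abs(max_real) <= _TIE_BAND:
        return "marginal"
    return "stable" if max_real < -_TIE_BAND else "unstable"


@dataclass(frozen=True)
class SpectrumReport:
    """Six eigenvalues sorted by real part ascending, with a verdict that
    treats a +/-1e-12 band around zero as marginal."""

    eigenvalues: np.ndarray
    max_real: float
    verdict: str

    @classmethod
    def from_eigenvalues(cls, eigs) -> "SpectrumReport":
        eigs = np.asarray(eigs, dtype=complex)
        if eigs.shape != (6,):
            raise ValueError("expected six eigenvalues")
        order = np.argsort(eigs.real, kind="stable")
        eigs = eigs[order]
        mr = float(np.max(eigs.real))
        return cls(eigenvalues=eigs, max_real=mr, verdict=_verdict(mr))

    def as_dict(self) -> dict:
        return {"eigenvalues": [[float(e.real), float(e.imag)]
                                for e in self.eigenvalues],
                "max_real": self.max_real, "verdict": self.verdict}


def dfe_spectrum_closed_form(p) -> SpectrumReport:
    """The six closed-form eigenvalues at the disease-free point."""
    s = p.lam + p.omega
    eigs = [-p.a, -p.d, p.alpha - p.gamma, -p.psi, -s,
            (-p.kappa * p.lam + p.mu * p.rho - p.kappa * p.omega) / s]
    return SpectrumReport.from_eigenvalues(eigs)


def spectrum_at(eq: EquilibriumPoint, p) -> SpectrumReport:
    """Numeric spectrum of the Jacobian at an equilibrium."""
    eigs = np.linalg.eigvals(jacobian(eq.state, p))
    return SpectrumReport.from_eigenvalues(eigs)


def controlled_spectrum(eq: EquilibriumPoint, p, gains: ControlGains) -> SpectrumReport:
    """Spectrum of the feedback-controlled Jacobian ``J - diag(w1..w6)``.

    At the disease-free point the matrix is lower triangular, so the
    eigenvalues are exactly the shifted diagonal entries.
    """
    J = jacobian(eq.state, p) - np.diag(gains.as_array())
    eigs = np.linalg.eigvals(J)
    return SpectrumReport.from_eigenvalues(eigs)


@dataclass(frozen=True)
class LyapunovRecord:
    """Lyapunov value and the Sigma/Omega split of its derivative."""

    L: float
    Sigma: float
    Omega: float

    @property
    def dL_sign(self) -> int:
        return int(np.sign(self.Sigma - self.Omega))


def lyapunov_terms(x, eq: EquilibriumPoint, p) -> LyapunovRecord:
    """Evaluate ``L`` and the term-for-term Sigma/Omega aggregates.

    Both state and equilibrium must be componentwise positive (the
    logarithms are undefined otherwise). The aggregates are transcribed
    term-for-term from the derivative expansion, including the
    ``+psi*IL12 - psi*IL12*`` pair kept inside Sigma; the decision rule
    tested downstream is ``Sigma < Omega  =>  dL < 0``.
    """
    xv = _state_array(x)
    ev = _state_array(eq.state)
    if np.any(xv <= 0):
        raise ValueError("lyapunov_terms requires a componentwise positive state")
    if np.any(ev <= 0):
        raise ValueError("lyapunov_terms requires a positive reference equilibrium")
    T, C, D, IL2, IL12, Z = xv
    Ts, Cs, Ds, IL2s, IL12s, Zs = ev

    L = float(np.sum(xv - ev - ev * np.log(xv / ev)))

    al, be, ga, ph, ro, ka = p.alpha, p.beta, p.gamma, p.phi, p.rho, p.kappa
    mu, om, la, d, ps, a = p.mu, p.omega, p.lam, p.d, p.psi, p.a
    qT = (T - Ts) ** 2 / T
    qC = (C - Cs) ** 2 / C
    qD = (D - Ds) ** 2 / D
    qI2 = (IL2 - IL2s) ** 2 / IL2
    qI12 = (IL12 - IL12s) ** 2 / IL12
    qZ = (Z - Zs) ** 2 / Z

    Sigma = (al * qT + ph * Cs * qT + ph * T * qC + ro * D * qC
             + mu + ro * Cs * qD
             + la * D + la * Ds * IL2s / IL2
             + d * IL2 + d * IL2s * IL12s / IL12
             + ps * IL12 - ps * IL12s + ps * IL12s * Zs / Z)
    Omega = (al * be * (T - Ts) ** 3 / T + ga * qT + ph * C * qT
             + ph * Ts * qC + ro * Ds * qC + ka * qC
             + mu * Ds / D + ro * C * qD + om * qD + la * qD
             + la * D * IL2s / IL2 + la * Ds
             + d * qI2 + d * IL2s + d * IL2 * IL12s / IL12
             + ps * qI12 + ps * IL12 * Zs / Z + a * qZ)
    return LyapunovRecord(L=L, Sigma=float(Sigma), Omega=float(Omega))


@dataclass(frozen=True)
class GlobalStabilityReport:
    n_steps: int
    n_skipped: int
    fraction_sigma_lt_omega: float
    fraction_L_nonincreasing_where_sigma_lt_omega: float
    records: tuple = field(repr=False, default=())

    def as_dict(self) -> dict:
        return {"n_steps": self.n_steps, "n_skipped": self.n_skipped,
                "fraction_sigma_lt_omega": self.fraction_sigma_lt_omega,
                "fraction_L_nonincreasing_where_sigma_lt_omega":
                    self.fraction_L_nonincreasing_where_sigma_lt_omega}


def global_stability_scan(traj, eq: EquilibriumPoint, p,
                          keep_records: bool = False) -> GlobalStabilityReport:
    """Per-step Lyapunov scan along a trajectory.

    Reports the fraction of usable steps with ``Sigma < Omega`` and, on
    those steps, how often the finite-difference ``L`` is non-increasing
    (with a small discretization tolerance). Steps with a nonpositive
    component are skipped and counted.
    """
    records: list[LyapunovRecord | None] = []
    n_skipped = 0
    for x in traj.states:
        if np.any(x <= 0):
            records.append(None)
            n_skipped += 1
            continue
        records.append(lyapunov_terms(x, eq, p))
    usable = [r for r in records if r is not None]
    n = len(usable)
    lt = [r.Sigma < r.Omega for r in usable]
    frac_lt = sum(lt) / n if n else float("nan")

    # finite-difference monotonicity of L where the certificate holds
    good = 0
    total = 0
    Lmax = max((r.L for r in usable), default=0.0)
    tol = 1e-9 * (1.0 + Lmax)
    for i in range(len(records) - 1):
        r0, r1 = records[i], records[i + 1]
        if r0 is None or r1 is None or not (r0.Sigma < r0.Omega):
            continue
        total += 1
        if r1.L <= r0.L + tol:
            good += 1
    frac_dec = good / total if total else float("nan")
    return GlobalStabilityReport(
        n_steps=len(records), n_skipped=n_skipped,
        fraction_sigma_lt_omega=frac_lt,
        fraction_L_nonincreasing_where_sigma_lt_omega=frac_dec,
        records=tuple(records) if keep_records else ())
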