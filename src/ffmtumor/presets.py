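"""Built-in scenarios and the random well-posed scenario generator."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import PARAM_NAMES, STATE_NAMES, ModelParameters, StateVector, \
    reproduction_number
from .solver import FractionalOrders, SolverConfig

__all__ = ["ScenarioPreset", "scenario_paper", "scenario_random", "get_preset",
           "PRESET_NAMES"]

_IC_KEYS = ("T0", "C0", "D0", "IL2_0", "IL12_0", "Z0")


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    parameters: ModelParameters
    initial: StateVector
    orders: FractionalOrders
    solver: SolverConfig

    def to_dict(self) -> dict:
        out: dict = {"name": self.name}
        out.update(self.parameters.as_dict())
        out.update(dict(zip(_IC_KEYS, self.initial.as_array().tolist())))
        out.update({"xi": self.orders.xi, "eta": self.orders.eta,
                    "dt": self.solver.dt, "t_end": self.solver.t_end,
                    "store_every": self.solver.store_every})
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioPreset":
        params = ModelParameters.from_dict(data)
        initial = StateVector(*(float(data[k]) for k in _IC_KEYS))
        orders = FractionalOrders(xi=float(data.get("xi", 0.95)),
                                  eta=float(data.get("eta", 0.95)))
        solver = SolverConfig(dt=float(data.get("dt", 0.05)),
                              t_end=float(data.get("t_end", 100.0)),
                              store_every=int(data.get("store_every", 1)))
        return cls(name=str(data.get("name", "custom")), parameters=params,
                   initial=initial, orders=orders, solver=solver)


def scenario_paper() -> ScenarioPreset:
    """The reference simulation scenario: a weak CD8+ recruitment regime
    (R0 ~ 1e-3) with a strong dendritic source, run at xi = eta = 0.95.
    Time units are days (assumed; the source scenario states none)."""
    params = ModelParameters(
        alpha=0.0514, beta=1.02e-9, gamma=0.1, phi=1e-7, rho=1e-8,
        kappa=0.02, mu=480.0, omega=0.24, lam=2e-7, d=3e-4, psi=3e-4, a=0.04)
    initial = StateVector(T=1.0, C=0.8, D=0.3, IL2=0.4, IL12=0.4, Z=0.3)
    return ScenarioPreset(name="paper", parameters=params, initial=initial,
                          orders=FractionalOrders(xi=0.95, eta=0.95),
                          solver=SolverConfig(dt=0.05, t_end=100.0))


def scenario_random(seed: int, force_R0_above_1: bool = False) -> ScenarioPreset:
    """Random well-posed scenario: each rate is the reference value scaled
    log-uniformly within +/- 2 decades; optionally ``rho`` is rescaled so
    that R0 lands in [1.5, 5]. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    base = scenario_paper()
    vals = {name: getattr(base.parameters, name) * 10.0 ** rng.uniform(-2, 2)
            for name in PARAM_NAMES}
    params = ModelParameters(**vals)
    if force_R0_above_1:
        target = rng.uniform(1.5, 5.0)
        rho = target * params.kappa * (params.lam + params.omega) / params.mu
        params = replace(params, rho=rho)
    return ScenarioPreset(name=f"random-{seed}", parameters=params,
                          initial=base.initial, orders=base.orders,
                          solver=base.solver)


PRESET_NAMES = ("paper",)


def get_preset(name: str) -> ScenarioPreset:
    if name == "paper":
        return scenario_paper()
    raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


def preset_reproduction_number(preset: ScenarioPreset) -> float:
    return reproduction_number(preset.parameters)
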