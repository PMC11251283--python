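import logging

import numpy as np
import pytest

from ffmtumor.model import ModelParameters, StateVector
from ffmtumor.presets import scenario_paper

# the sensitivity table intentionally warns about the dR0/dmu sign; keep the
# test output quiet
logging.getLogger("ffmtumor.model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper():
    return scenario_paper()


@pytest.fixture(scope="session")
def paper_params(paper):
    return paper.parameters


@pytest.fixture(scope="session")
def paper_x0(paper):
    return paper.initial


@pytest.fixture(scope="session")
def endemic_params():
    """Aggressive-tumor regime (alpha > gamma, R0 > 1): all three equilibrium
    kinds exist with positive components."""
    return ModelParameters(alpha=0.5, beta=0.01, gamma=0.1, phi=0.01,
                           rho=0.01, kappa=0.1, mu=3.0, omega=0.1, lam=0.1,
                           d=0.1, psi=0.1, a=0.1)


def random_params(rng) -> ModelParameters:
    """Log-uniform positive parameter draw around the reference scenario."""
    base = scenario_paper().parameters
    return ModelParameters(**{k: v * 10.0 ** rng.uniform(-1.5, 1.5)
                              for k, v in base.as_dict().items()})


def random_state(rng) -> StateVector:
    return StateVector(*np.abs(rng.normal(1.0, 0.5, size=6)) + 0.05)


def central_difference_r0(p, name: str, rel_step: float = 1e-6) -> float:
    """Independent finite-difference oracle for dR0/dp.

    Evaluated in extended precision: in double precision the symmetric
    difference cancels catastrophically when the perturbed parameter is
    many orders of magnitude below its partner (e.g. lam << omega).
    """
    import mpmath

    with mpmath.workdps(50):
        vals = {k: mpmath.mpf(repr(v)) for k, v in p.as_dict().items()}

        def r0(vs):
            return vs["mu"] * vs["rho"] / (vs["kappa"] * (vs["lam"] + vs["omega"]))

        h = mpmath.mpf(repr(rel_step)) * vals[name]
        up = dict(vals)
        dn = dict(vals)
        up[name] = vals[name] + h
        dn[name] = vals[name] - h
        return float((r0(up) - r0(dn)) / (2 * h))
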