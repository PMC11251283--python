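"""YAML/JSON configuration round-tripping for scenarios.

Schema (flat mapping): the twelve rate constants ``alpha, beta, gamma, phi,
rho, kappa, mu, omega, lam, d, psi, a``; initial conditions ``T0, C0, D0,
IL2_0, IL12_0, Z0``; optional ``xi, eta, dt, t_end, store_every, name``.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .presets import ScenarioPreset

__all__ = ["load_scenario", "save_scenario"]


def load_scenario(path) -> ScenarioPreset:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return ScenarioPreset.from_dict(data)


def save_scenario(preset: ScenarioPreset, path) -> None:
    path = Path(path)
    data = preset.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
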