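"""Scenario files, trajectory tables and run records.

Scenario schema (YAML, one document)::

    model: minimal | detailed
    params:            # optional overrides of the base parameter table
      k_2a: 2.1
    initial_state:     # optional; scalar T for minimal, mapping for detailed
      T: 0.01
    settle_first: true # optional, default false
    pulses:
      - {channel: A, amplitude: 100, t_on: 20, t_off: 70}
    t_end: 400
    name: fig3_CD      # optional

Unknown keys anywhere in the document are an error, so parameter-name
typos fail loudly instead of silently running the base model.
"""

from __future__ import annotations

import hashlib
from dataclasses import fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .params import DetailedParams, MinimalParams, SystemState
from .simulate import CHANNELS, Scenario, ScenarioError, SquarePulse, Trajectory

__all__ = [
    "scenario_from_yaml",
    "scenario_to_yaml",
    "load_scenario",
    "save_scenario",
    "trajectory_frame",
    "write_trajectory",
    "run_record",
]

_TOP_KEYS = {"model", "params", "initial_state", "settle_first", "pulses", "t_end", "name"}
_PULSE_KEYS = {"channel", "amplitude", "t_on", "t_off"}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ScenarioError(f"unknown key(s) {sorted(unknown)} in {where}")


def scenario_from_yaml(text: str) -> Scenario:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ScenarioError("scenario document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "scenario")
    model = doc.get("model", "detailed")
    base_cls = MinimalParams if model == "minimal" else DetailedParams
    overrides = doc.get("params") or {}
    if not isinstance(overrides, dict):
        raise ScenarioError("params must be a mapping of overrides")
    known = {f.name for f in fields(base_cls)}
    _check_keys(overrides, known, "params")
    params = base_cls(**{k: float(v) for k, v in overrides.items()})
    init = doc.get("initial_state")
    if init is not None:
        if model == "minimal":
            init = float(init)
        else:
            if not isinstance(init, dict):
                raise ScenarioError("detailed initial_state must be a mapping")
            _check_keys(init, set(SystemState.NAMES), "initial_state")
            init = SystemState(**{k: float(v) for k, v in init.items()})
    pulses = []
    for i, p in enumerate(doc.get("pulses") or []):
        if not isinstance(p, dict):
            raise ScenarioError(f"pulse #{i} must be a mapping")
        _check_keys(p, _PULSE_KEYS, f"pulse #{i}")
        missing = _PULSE_KEYS - set(p)
        if missing:
            raise ScenarioError(f"pulse #{i} missing key(s) {sorted(missing)}")
        try:
            pulses.append(SquarePulse(channel=str(p["channel"]),
                                      amplitude=float(p["amplitude"]),
                                      t_on=float(p["t_on"]),
                                      t_off=float(p["t_off"])))
        except ScenarioError as exc:
            raise ScenarioError(f"pulse #{i}: {exc}") from None
    return Scenario(model=model, params=params, initial_state=init,
                    pulses=tuple(pulses),
                    t_end=float(doc.get("t_end", 400.0)),
                    settle_first=bool(doc.get("settle_first", False)),
                    name=str(doc.get("name", "")))


def scenario_to_yaml(scn: Scenario) -> str:
    base = type(scn.params)()
    overrides = {f.name: getattr(scn.params, f.name) for f in fields(scn.params)
                 if getattr(scn.params, f.name) != getattr(base, f.name)}
    doc: dict[str, Any] = {"model": scn.model}
    if scn.name:
        doc["name"] = scn.name
    if overrides:
        doc["params"] = overrides
    if scn.model == "minimal":
        if scn.initial_state != 0.0:
            doc["initial_state"] = float(scn.initial_state)
    else:
        if scn.initial_state != SystemState():
            doc["initial_state"] = {n: getattr(scn.initial_state, n)
                                    for n in SystemState.NAMES}
    if scn.settle_first:
        doc["settle_first"] = True
    doc["pulses"] = [dict(channel=p.channel, amplitude=p.amplitude,
                          t_on=p.t_on, t_off=p.t_off) for p in scn.pulses]
    doc["t_end"] = scn.t_end
    return yaml.safe_dump(doc, sort_keys=False)


def load_scenario(path: str | Path) -> Scenario:
    return scenario_from_yaml(Path(path).read_text())


def save_scenario(scn: Scenario, path: str | Path) -> None:
    Path(path).write_text(scenario_to_yaml(scn))


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tabulate a trajectory: time, state columns, applied channel levels."""
    data = {"time": traj.t}
    for i, n in enumerate(traj.var_names):
        data[n] = traj.y[i]
    for i, c in enumerate(CHANNELS):
        data[c] = traj.channels[i]
    return pd.DataFrame(data)


def write_trajectory(traj: Trajectory, path: str | Path, sep: str = "\t") -> None:
    trajectory_frame(traj).to_csv(path, sep=sep, index=False, float_format="%.10g")


def run_record(scn: Scenario, summary: dict[str, Any]) -> dict[str, Any]:
    """JSON-serializable provenance record for a run."""
    from . import __version__

    text = scenario_to_yaml(scn)
    return {
        "scenario_name": scn.name,
        "scenario_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "scenario": yaml.safe_load(text),
        "integrator": {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10},
        "summary": summary,
        "tool_version": __version__,
    }
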