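"""The library of canonical experiment protocols (one per figure panel).

Each fixture encodes one published panel as a complete scenario: settle to
the healthy state, apply the antigen and/or inhibitor pulses of that
panel, and integrate past the last pulse.  The expectation ledger records
the published qualitative outcome per panel so the whole set can be
re-checked in one sweep (``granulosim reproduce-paper``).

The two Treg-sensitivity panels (``fig4_A``/``fig4_B``) have no published
parameter values; the shipped pair straddles the IL-2-sensitivity switch
of this implementation (located with the threshold finder) rather than
guessing unprinted numbers.
"""

from __future__ import annotations

from importlib import resources

from .io import scenario_from_yaml
from .simulate import Scenario

__all__ = ["fixture_names", "load_fixture", "fixture_scenarios", "EXPECTATIONS"]

_FIXTURE_DIR = resources.files("granulosim") / "fixtures"

#: Published qualitative outcome per panel.  ``state`` is a coarse-state
#: index; ``T_high``/``T_M_high``/``all_low`` are feature expectations;
#: ``threshold`` is a printed threshold checked with the panel's knob;
#: ``differs_from`` names another panel whose outcome must differ.
EXPECTATIONS: dict[str, dict] = {
    "fig1": {"kind": "threshold", "knob": "antigen amplitude",
             "bracket": (3.0, 5.0), "step": 0.5, "threshold": 4.0},
    "fig3_AB": {"kind": "state", "state": 1},
    "fig3_CD": {"kind": "state", "state": 8},
    "fig4_A": {"kind": "state", "state": 7},
    "fig4_B": {"kind": "state", "state": 8},
    "fig5_A": {"kind": "state", "state": 8},
    "fig5_B": {"kind": "state", "state": 7},
    "fig5_C": {"kind": "state", "state": 8},
    "fig5_D": {"kind": "state", "state": 6},
    "fig6_A": {"kind": "feature", "T_high": True, "M_high": True},
    "fig6_B": {"kind": "feature", "T_high": False, "M_high": False},
    "fig6_C": {"kind": "feature", "T_high": False, "M_high": False},
    "fig6_D": {"kind": "feature", "R_high": True},
    "fig6_E": {"kind": "feature", "R_high": False, "T_high": True, "M_high": True},
    "fig6_F": {"kind": "feature", "R_high": True},
    "fig7_A": {"kind": "feature", "T_high": True},
    "fig7_B": {"kind": "same_as", "other": "fig7_A"},
    "fig7_C": {"kind": "differs_from", "other": "fig7_A"},
}


def fixture_names() -> list[str]:
    return sorted(EXPECTATIONS)


def load_fixture(name: str) -> Scenario:
    """Load one shipped fixture scenario by panel name."""
    if name not in EXPECTATIONS:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    path = _FIXTURE_DIR / f"{name}.yaml"
    return scenario_from_yaml(path.read_text())


def fixture_scenarios(names: list[str] | None = None) -> dict[str, Scenario]:
    return {n: load_fixture(n) for n in (names or fixture_names())}
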