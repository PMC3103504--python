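"""In-silico cytokine-inhibitor therapy on an established sarcoid state.

A therapy is a square pulse on one (or two) of the inhibitor channels
``I_delta`` (anti-IL-2), ``I_gamma`` (anti-IFN-gamma), ``I_alpha``
(anti-TNF-alpha), applied to a system already settled in a sarcoid state.
The outcome is the coarse-state comparison of the post-therapy steady
state with the pre-therapy one: remission (everything back to the low
branch), partial response (some population lowered, Teff still high), no
effect, or a paradoxical response (a population newly high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .analysis import CoarseState, ReferenceScales, classify_state
from .params import DetailedParams, SystemState
from .simulate import Scenario, SquarePulse, final_steady_state, run

__all__ = [
    "TherapyOutcome",
    "verdict",
    "sarcoid_scenario",
    "establish_sarcoid",
    "apply_therapy",
    "run_monotherapy",
    "titrate_combination",
    "anti_tnf_scan",
]

_CHANNEL_OF = {"anti-IL2": "I_delta", "anti-IFNg": "I_gamma", "anti-TNFa": "I_alpha"}


@dataclass(frozen=True)
class TherapyOutcome:
    """Pre/post coarse states and the verdict derived from them."""

    pre: CoarseState
    post: CoarseState
    verdict: str
    post_state: SystemState | None = None


def verdict(pre: CoarseState, post: CoarseState) -> str:
    """Pure verdict function on the (pre, post) coarse-state pair.

    Priority order: any population newly high is *paradoxical*; everything
    low is *remission*; no flag change is *no_effect*; any other lowering
    is *partial*.
    """
    if any(po and not pr for pr, po in zip(pre.flags, post.flags)):
        return "paradoxical"
    if not any(post.flags):
        return "remission"
    if post.flags == pre.flags:
        return "no_effect"
    return "partial"


def sarcoid_scenario(params: DetailedParams | None = None,
                     antigen_amplitude: float = 100.0,
                     window: tuple[float, float] = (20.0, 70.0),
                     t_end: float = 400.0) -> Scenario:
    """The canonical disease-induction protocol: settle, then antigen pulse."""
    p = params if params is not None else DetailedParams().with_(k_2a=2.1)
    return Scenario(model="detailed", params=p, settle_first=True,
                    pulses=(SquarePulse("A", antigen_amplitude, *window),),
                    t_end=t_end, name="sarcoid-induction")


def establish_sarcoid(scn: Scenario | None = None,
                      scales: ReferenceScales | None = None
                      ) -> tuple[SystemState, CoarseState]:
    """Run the induction protocol and verify a high-Teff state was reached."""
    scn = scn if scn is not None else sarcoid_scenario()
    s = final_steady_state(run(scn))
    if s is None:
        raise RuntimeError("sarcoid induction did not settle")
    pre = classify_state(s, scales)
    if not pre.T_high:
        raise RuntimeError(
            f"protocol error: pre-therapy state is not sarcoid (got {pre})")
    return s, pre


def apply_therapy(pre_state: SystemState, params: DetailedParams,
                  pulses: Sequence[SquarePulse], t_end: float = 800.0,
                  scales: ReferenceScales | None = None) -> TherapyOutcome:
    """Apply inhibitor pulses to an established state and classify the outcome."""
    pre = classify_state(pre_state, scales)
    scn = Scenario(model="detailed", params=params, initial_state=pre_state,
                   pulses=tuple(pulses), t_end=t_end, name="therapy")
    # the pre-state is a steady state, so starting the clock at 0 with the
    # therapy window at its nominal position reproduces the protocol exactly
    traj = run(scn)
    s = final_steady_state(traj)
    if s is None:
        raise RuntimeError("post-therapy trajectory did not settle")
    post = classify_state(s, scales)
    return TherapyOutcome(pre=pre, post=post, verdict=verdict(pre, post), post_state=s)


def run_monotherapy(inhibitor: str, amplitude: float,
                    window: tuple[float, float],
                    scenario: Scenario | None = None,
                    scales: ReferenceScales | None = None,
                    t_end: float = 800.0) -> TherapyOutcome:
    """Single-inhibitor pulse on the established sarcoid state.

    ``inhibitor`` is one of ``anti-IL2``, ``anti-IFNg``, ``anti-TNFa`` (or
    a raw channel name ``I_delta``/``I_gamma``/``I_alpha``).
    """
    channel = _CHANNEL_OF.get(inhibitor, inhibitor)
    scn = scenario if scenario is not None else sarcoid_scenario()
    pre_state, _ = establish_sarcoid(scn, scales)
    pulses = [] if amplitude == 0 else [SquarePulse(channel, amplitude, *window)]
    if not pulses:
        pre = classify_state(pre_state, scales)
        return TherapyOutcome(pre=pre, post=pre, verdict="no_effect",
                              post_state=pre_state)
    return apply_therapy(pre_state, scn.params, pulses, t_end=t_end, scales=scales)


def titrate_combination(i_delta_grid: Sequence[float], i_gamma_grid: Sequence[float],
                        window: tuple[float, float] = (100.0, 120.0),
                        scenario: Scenario | None = None,
                        scales: ReferenceScales | None = None,
                        t_end: float = 800.0) -> dict[tuple[float, float], TherapyOutcome]:
    """Outcome map of simultaneous anti-IL-2 / anti-IFN-gamma dose pairs."""
    scn = scenario if scenario is not None else sarcoid_scenario()
    pre_state, pre = establish_sarcoid(scn, scales)
    out: dict[tuple[float, float], TherapyOutcome] = {}
    for i_d in i_delta_grid:
        for i_g in i_gamma_grid:
            pulses = []
            if i_d > 0:
                pulses.append(SquarePulse("I_delta", i_d, *window))
            if i_g > 0:
                pulses.append(SquarePulse("I_gamma", i_g, *window))
            if not pulses:
                out[(i_d, i_g)] = TherapyOutcome(pre=pre, post=pre,
                                                 verdict="no_effect",
                                                 post_state=pre_state)
                continue
            out[(i_d, i_g)] = apply_therapy(pre_state, scn.params, pulses,
                                            t_end=t_end, scales=scales)
    return out


def anti_tnf_scan(amplitudes: Sequence[float],
                  window: tuple[float, float] = (100.0, 140.0),
                  scenario: Scenario | None = None,
                  scales: ReferenceScales | None = None,
                  t_end: float = 800.0) -> dict[float, TherapyOutcome]:
    """Anti-TNF-alpha amplitude scan on the TNF-sensitised sarcoid state.

    The canonical protocol doubles the TNF-alpha antagonism of Tregs
    (k_2b = 0.2) before induction; the scan then reports the outcome per
    amplitude, including amplitude 0 as the untreated reference.
    """
    if scenario is None:
        p = DetailedParams().with_(k_2a=2.1, k_2b=0.2)
        scenario = sarcoid_scenario(params=p)
    pre_state, pre = establish_sarcoid(scenario, scales)
    out: dict[float, TherapyOutcome] = {}
    for a in amplitudes:
        if a == 0:
            untreated = apply_therapy(pre_state, scenario.params, [],
                                      t_end=t_end, scales=scales)
            out[0.0] = untreated
            continue
        out[float(a)] = apply_therapy(pre_state, scenario.params,
                                      [SquarePulse("I_alpha", a, *window)],
                                      t_end=t_end, scales=scales)
    return out
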