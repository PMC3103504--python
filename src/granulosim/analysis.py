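"""Steady-state structure, threshold finding and coarse-state classification.

The minimal model's steady states solve the cubic

    beta_T - eps_T*T + f_T * T^2/(theta_T^2 + T^2) = 0

whose root structure (one root, or low/middle/high) defines the bistable
range of the drive ``f_T`` and the hysteresis of the Th1 switch.  The
detailed model's long-term behaviour is summarized on a coarse low/high
grid per cell population, mapped onto the eight qualitative network states
(healthy, sarcoid, lymphopenic sarcoid, and the structurally unlikely
combinations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import DetailedParams, MinimalParams, SystemState
from .simulate import Scenario, SquarePulse, final_steady_state, run, settle

__all__ = [
    "steady_states_minimal",
    "SteadyStateCurve",
    "bistable_range",
    "hysteresis_sweep",
    "CoarseState",
    "STATE_TABLE",
    "ReferenceScales",
    "classify_state",
    "reachable_states",
    "find_threshold",
    "ThresholdResult",
    "BracketError",
]

_RESIDUAL_TOL = 1e-10


def steady_states_minimal(f_T: float, p: MinimalParams) -> list[float]:
    """All real nonnegative steady states of the minimal model at drive ``f_T``.

    Roots of the cubic ``eps*T^3 - (beta+f)*T^2 + eps*theta^2*T - beta*theta^2``
    (obtained by clearing the Hill denominator), each verified by direct
    substitution into the rate equation.  Returns 1 or 3 roots, sorted
    ascending; a tangency (double root) is collapsed so endpoints of the
    bistable range count as monostable.
    """
    if f_T < 0:
        raise ValueError("f_T must be >= 0")
    th2 = p.theta_T ** 2
    coeffs = [p.eps_T, -(p.beta_T + f_T), p.eps_T * th2, -p.beta_T * th2]
    roots = np.roots(coeffs)
    real = sorted(r.real for r in roots
                  if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and r.real >= -1e-9)

    def g(T):  # rate equation with the drive held fixed
        return p.beta_T - p.eps_T * T + f_T * T * T / (th2 + T * T)

    def dg(T):
        return -p.eps_T + f_T * 2.0 * T * th2 / (th2 + T * T) ** 2

    out: list[float] = []
    for r in real:
        r = max(r, 0.0)
        for _ in range(50):  # Newton polish to the residual tolerance
            res = g(r)
            if abs(res) < 0.1 * _RESIDUAL_TOL:
                break
            d = dg(r)
            if d == 0:
                break
            r = max(r - res / d, 0.0)
        if abs(g(r)) > _RESIDUAL_TOL:
            continue
        if out and abs(r - out[-1]) < 1e-7 * max(1.0, out[-1]):  # tangency
            continue
        out.append(r)
    if len(out) == 2:
        # fold point: treat as monostable (open-interval convention)
        out = [out[0]] if out[0] < out[1] else [out[1]]
    return out


@dataclass(frozen=True)
class SteadyStateCurve:
    """Sampled steady-state branches T_s(f_T) with the bistable interval."""

    f_values: np.ndarray
    branches: list[list[float]]  # roots per f value, ascending
    f_lo: float | None
    f_hi: float | None

    def n_roots(self) -> np.ndarray:
        return np.array([len(b) for b in self.branches])


def bistable_range(p: MinimalParams, f_max: float = 200.0,
                   xtol: float = 1e-8) -> tuple[float, float] | None:
    """Endpoints (f_lo, f_hi) of the drive interval with three steady states.

    Located by bisection on the root count to ``xtol``; returns ``None``
    when the parameters admit no bistability (e.g. clearance dominates).
    """
    n = lambda f: len(steady_states_minimal(f, p))
    # coarse scan for a tristable point
    fs = np.linspace(0.0, f_max, 801)
    tri = [f for f in fs if n(f) == 3]
    if not tri:
        return None
    f_in = tri[len(tri) // 2]

    def bisect(lo, hi, want_three_at_lo):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (n(mid) == 3) == want_three_at_lo:
                lo = mid
            else:
                hi = mid
            if hi - lo < xtol:
                break
        return 0.5 * (lo + hi)

    lo_edge = bisect(0.0, f_in, want_three_at_lo=False) if n(0.0) != 3 else 0.0
    # find an upper monostable point
    hi_scan = f_in
    while n(hi_scan) == 3:
        hi_scan *= 2.0
        if hi_scan > 1e6:
            return (lo_edge, np.inf)
    hi_edge = bisect(f_in, hi_scan, want_three_at_lo=True)
    return (lo_edge, hi_edge)


def steady_state_curve(p: MinimalParams, f_values: Sequence[float]) -> SteadyStateCurve:
    rng = bistable_range(p)
    f_lo, f_hi = rng if rng is not None else (None, None)
    fv = np.asarray(f_values, dtype=float)
    return SteadyStateCurve(fv, [steady_states_minimal(f, p) for f in fv], f_lo, f_hi)


def hysteresis_sweep(p: MinimalParams, f_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-static up-then-down sweep of the drive with state continuation.

    At each drive value the state relaxes to the nearest stable branch
    (continuation by choosing the stable root closest to the previous
    state).  Returns the up-sweep and down-sweep steady states; on a
    bistable switch these differ inside the hysteresis loop.
    """
    fv = np.asarray(f_values, dtype=float)

    def relax(f, T_prev):
        roots = steady_states_minimal(f, p)
        stable = roots if len(roots) == 1 else [roots[0], roots[2]]
        # middle root repels: move to the stable root on the current side
        if len(roots) == 3 and T_prev is not None:
            return roots[0] if T_prev < roots[1] else roots[2]
        return min(stable, key=lambda r: abs(r - (T_prev if T_prev is not None else r)))

    up = []
    T = None
    for f in fv:
        T = relax(f, T)
        up.append(T)
    down = []
    for f in fv[::-1]:
        T = relax(f, T)
        down.append(T)
    return np.array(up), np.array(down)[::-1]


# ---------------------------------------------------------------------------
# coarse (low/high) classification onto the qualitative-network state table
# ---------------------------------------------------------------------------

#: (T, R, M) low/high triples in canonical order, with labels.
STATE_TABLE = {
    (False, False, False): (1, "healthy"),
    (False, True, False): (2, "unlikely"),
    (False, False, True): (3, "unlikely"),
    (False, True, True): (4, "unlikely"),
    (True, False, False): (5, "unlikely"),
    (True, True, False): (6, "sarcoid, lymphopenia"),
    (True, False, True): (7, "sarcoid"),
    (True, True, True): (8, "sarcoid, lymphopenia"),
}


@dataclass(frozen=True)
class CoarseState:
    """Low/high flags of (T, R, M) mapped onto the 8-state table."""

    T_high: bool
    R_high: bool
    M_high: bool

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.T_high, self.R_high, self.M_high)

    @property
    def index(self) -> int:
        return STATE_TABLE[self.flags][0]

    @property
    def label(self) -> str:
        return STATE_TABLE[self.flags][1]

    def __str__(self) -> str:
        sym = "".join("+" if f else "0" for f in self.flags)
        return f"state {self.index} ({sym}: {self.label})"


@dataclass(frozen=True)
class ReferenceScales:
    """Per-population low reference and high scale used for classification.

    The cut for each population is the geometric mean of its basal level
    (beta/eps, the low branch) and a high-branch scale; the branches are
    separated by orders of magnitude, so any mid-gap cut is stable and the
    geometric mean keeps the cut invariant under common rescaling.
    """

    low: tuple[float, float, float]
    high: tuple[float, float, float]

    def cuts(self) -> tuple[float, float, float]:
        return tuple(float(np.sqrt(l * h)) for l, h in zip(self.low, self.high))

    @classmethod
    def from_params(cls, p: DetailedParams, high_state: SystemState) -> "ReferenceScales":
        low = (p.beta_T / p.eps_T, p.beta_R / p.eps_R, p.beta_M / p.eps_M)
        high = (high_state.T, high_state.R, high_state.M)
        return cls(low=low, high=high)


_default_scales: ReferenceScales | None = None


def default_reference_scales(recompute: bool = False) -> ReferenceScales:
    """Reference scales anchored on the base-parameter sarcoid state.

    The high scale is estimated once by running the canonical
    switching protocol (antigen pulse of amplitude 100 over t=20..70 with
    the Treg IL-2 sensitivity k_2a = 2.1) and settling the outcome.
    """
    global _default_scales
    if _default_scales is None or recompute:
        p = DetailedParams().with_(k_2a=2.1)
        scn = Scenario(model="detailed", params=p, settle_first=True,
                       pulses=(SquarePulse("A", 100.0, 20.0, 70.0),), t_end=400.0)
        s = final_steady_state(run(scn))
        if s is None:
            s = settle(p, SystemState.from_array(run(scn).final_state()))
        _default_scales = ReferenceScales.from_params(p, s)
    return _default_scales


def classify_state(s: SystemState, scales: ReferenceScales | None = None) -> CoarseState:
    """Coarse low/high classification of a settled steady state."""
    if s is None:
        raise ValueError("cannot classify an indeterminate (non-settled) state")
    if scales is None:
        scales = default_reference_scales()
    cT, cR, cM = scales.cuts()
    return CoarseState(T_high=s.T > cT, R_high=s.R > cR, M_high=s.M > cM)


def reachable_states(scenarios: Sequence[Scenario],
                     scales: ReferenceScales | None = None) -> set[int]:
    """Set of coarse-state indices reached by a collection of scenarios.

    Raises with the scenario name if any outcome fails to settle.
    """
    out: set[int] = set()
    for scn in scenarios:
        traj = run(scn)
        s = final_steady_state(traj)
        if s is None:
            raise RuntimeError(f"scenario {scn.name or '<unnamed>'} did not settle")
        if scn.model == "minimal":
            raise ValueError("reachable_states applies to detailed-model scenarios")
        out.add(classify_state(s, scales).index)
    return out


# ---------------------------------------------------------------------------
# threshold finding over scenario knobs
# ---------------------------------------------------------------------------


class BracketError(ValueError):
    """The predicate does not differ between the bracket endpoints."""


@dataclass(frozen=True)
class ThresholdResult:
    """Smallest knob value satisfying the predicate, with its bracket."""

    threshold: float
    below: float
    predicate_name: str = ""


def find_threshold(evaluate: Callable[[float], bool], lo: float, hi: float,
                   step: float | None = None, xtol: float = 1e-3,
                   predicate_name: str = "") -> ThresholdResult:
    """Locate the smallest knob value in ``(lo, hi]`` where ``evaluate`` flips.

    ``evaluate`` maps a knob value (pulse amplitude, pulse end time, or a
    parameter) to a boolean outcome; it must be False at ``lo`` and True at
    ``hi``.  With ``step`` given, the published grid is scanned so that the
    reported threshold is comparable to a printed bracket; otherwise the
    transition is bisected to ``xtol``.
    """
    if hi <= lo:
        raise BracketError(f"degenerate bracket [{lo}, {hi}]")
    if evaluate(lo):
        raise BracketError(f"predicate already true at lo={lo}")
    if step is not None:
        values = np.arange(lo + step, hi + 0.5 * step, step)
        prev = lo
        for v in values:
            v = round(float(v), 10)
            if evaluate(v):
                return ThresholdResult(threshold=v, below=prev,
                                       predicate_name=predicate_name)
            prev = v
        raise BracketError(f"predicate still false at hi={hi}")
    if not evaluate(hi):
        raise BracketError(f"predicate still false at hi={hi}")
    a, b = lo, hi
    while b - a > xtol:
        mid = 0.5 * (a + b)
        if evaluate(mid):
            b = mid
        else:
            a = mid
    return ThresholdResult(threshold=b, below=a, predicate_name=predicate_name)
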