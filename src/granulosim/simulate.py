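"""Time-course integration under square-pulse perturbation schedules.

Every experiment follows the same protocol: let the system settle to its
low (healthy) steady state, apply one or more square pulses on the antigen
or inhibitor channels, integrate well past the last pulse and classify the
final steady state.  Pulse edges are handled by segmenting the integration
at every on/off time, so discontinuous forcing never depends on integrator
step-size luck.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.integrate import solve_ivp

from .equations import detailed_rhs, minimal_rhs
from .params import DetailedParams, MinimalParams, SystemState

__all__ = [
    "CHANNELS",
    "SquarePulse",
    "Scenario",
    "Trajectory",
    "SettleError",
    "settle",
    "run",
    "final_steady_state",
]

#: Forcing channels: antigen plus the three cytokine inhibitors.
CHANNELS = ("A", "I_delta", "I_gamma", "I_alpha")

# integrator defaults: stiff-capable adaptive method; tolerances tight
# enough that threshold brackets of width 0.1 are edge-exact.
RTOL = 1e-8
ATOL = 1e-10
#: steady state declared when the RHS infinity-norm stays below this
SS_TOL = 1e-7
#: trailing window (time units) over which the RHS norm is monitored
SS_WINDOW = 20.0
#: settling budget before declaring non-convergence
SETTLE_BUDGET = 500.0


class SettleError(RuntimeError):
    """Settling did not converge within the budget (oscillation/runaway)."""


class ScenarioError(ValueError):
    """Invalid scenario or pulse definition."""


@dataclass(frozen=True)
class SquarePulse:
    """A time-windowed constant input on one forcing channel.

    Outside ``[t_on, t_off)`` the pulse contributes nothing.
    """

    channel: str
    amplitude: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ScenarioError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.amplitude < 0:
            raise ScenarioError(f"pulse amplitude must be >= 0, got {self.amplitude}")
        if not self.t_on < self.t_off:
            raise ScenarioError(
                f"pulse on channel {self.channel!r} has t_on={self.t_on} >= t_off={self.t_off}")

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


@dataclass(frozen=True)
class Scenario:
    """Model + parameters + initial state + pulse schedule + horizon.

    ``model`` selects ``"minimal"`` or ``"detailed"``.  With
    ``settle_first=True`` the initial state is first relaxed to the nearby
    steady state (the low branch when starting from the default initial
    conditions) before the clock starts.
    """

    model: str = "detailed"
    params: MinimalParams | DetailedParams | None = None
    initial_state: SystemState | float | None = None
    pulses: tuple[SquarePulse, ...] = ()
    t_end: float = 400.0
    settle_first: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("minimal", "detailed"):
            raise ScenarioError(f"model must be 'minimal' or 'detailed', got {self.model!r}")
        object.__setattr__(self, "pulses", tuple(sorted(self.pulses, key=lambda p: p.t_on)))
        if self.params is None:
            default = MinimalParams() if self.model == "minimal" else DetailedParams()
            object.__setattr__(self, "params", default)
        if self.model == "minimal" and not isinstance(self.params, MinimalParams):
            raise ScenarioError("minimal model requires MinimalParams")
        if self.model == "detailed" and not isinstance(self.params, DetailedParams):
            raise ScenarioError("detailed model requires DetailedParams")
        if self.initial_state is None:
            init = 0.0 if self.model == "minimal" else SystemState()
            object.__setattr__(self, "initial_state", init)
        if self.pulses and self.t_end <= max(p.t_off for p in self.pulses):
            raise ScenarioError("horizon t_end must lie beyond the last pulse t_off")
        if self.model == "minimal":
            for p in self.pulses:
                if p.channel != "A":
                    raise ScenarioError("minimal model supports only antigen pulses")

    def with_(self, **kw) -> "Scenario":
        return replace(self, **kw)

    def channel_levels(self, t: float) -> dict[str, float]:
        """Summed active pulse amplitudes per channel at time ``t``."""
        levels = dict.fromkeys(CHANNELS, 0.0)
        for p in self.pulses:
            if p.active(t):
                levels[p.channel] += p.amplitude
        return levels


@dataclass
class Trajectory:
    """Dense time-course output.

    Columns: time, the state variables, then the applied channel levels.
    """

    t: np.ndarray
    y: np.ndarray  # (n_vars, n_times)
    channels: np.ndarray  # (4, n_times) applied A, I_delta, I_gamma, I_alpha
    var_names: tuple[str, ...]
    scenario: Scenario | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ScenarioError("trajectory times must be strictly increasing")

    def final_state(self) -> np.ndarray:
        return self.y[:, -1]


def _rhs_vector(model: str, params, y, levels) -> np.ndarray:
    if model == "minimal":
        return np.array([minimal_rhs(max(y[0], 0.0), levels["A"], params)])
    return detailed_rhs(y, levels["A"],
                        (levels["I_delta"], levels["I_gamma"], levels["I_alpha"]),
                        params)


def _initial_array(scn: Scenario) -> np.ndarray:
    if scn.model == "minimal":
        y0 = scn.initial_state
        if isinstance(y0, SystemState):
            raise ScenarioError("minimal model takes a scalar initial T")
        return np.array([float(y0)])
    y0 = scn.initial_state
    if not isinstance(y0, SystemState):
        raise ScenarioError("detailed model takes a SystemState initial state")
    return y0.as_array()


def _integrate_segment(model, params, y0, t0, t1, levels, t_eval=None):
    sol = solve_ivp(
        lambda t, y: _rhs_vector(model, params, y, levels),
        (t0, t1), y0, method="LSODA", rtol=RTOL, atol=ATOL,
        t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:.3f}, state={sol.y[:, -1]}: {sol.message}")
    if np.any(sol.y < -1e-9):
        raise RuntimeError(
            f"negative density beyond tolerance in segment [{t0}, {t1}]: min={sol.y.min()}")
    return sol.t, np.maximum(sol.y, 0.0)


def settle(params: MinimalParams | DetailedParams,
           initial_state: SystemState | float | None = None,
           tol: float = SS_TOL,
           budget: float = SETTLE_BUDGET) -> SystemState | float:
    """Relax the unforced system to a steady state.

    Integrates with no pulses until the RHS infinity-norm stays below
    ``tol`` over a trailing window, or raises :class:`SettleError` after
    ``budget`` time units (a diagnostic for oscillation or runaway).
    From the default initial conditions with base parameters this lands on
    the low ("healthy") branch.
    """
    model = "minimal" if isinstance(params, MinimalParams) else "detailed"
    if initial_state is None:
        initial_state = 0.0 if model == "minimal" else SystemState()
    y = (np.array([float(initial_state)]) if model == "minimal"
         else initial_state.as_array())
    levels = dict.fromkeys(CHANNELS, 0.0)
    t = 0.0
    chunk = max(5.0 * SS_WINDOW, 50.0)
    while t < budget:
        t_eval = np.linspace(t, t + chunk, 41)
        ts, ys = _integrate_segment(model, params, y, t, t + chunk, levels, t_eval)
        y = ys[:, -1]
        # RHS norm over the trailing window of the chunk
        window = ts >= ts[-1] - SS_WINDOW
        norms = [np.max(np.abs(_rhs_vector(model, params, ys[:, i], levels)))
                 for i in np.nonzero(window)[0]]
        if max(norms) < tol:
            return float(y[0]) if model == "minimal" else SystemState.from_array(y)
        t += chunk
    raise SettleError(
        f"no steady state within {budget} time units (last RHS norm {max(norms):.3g})")


def _segment_edges(scn: Scenario, t0: float) -> list[float]:
    edges = {t0, scn.t_end}
    for p in scn.pulses:
        for e in (p.t_on, p.t_off):
            if t0 < e < scn.t_end:
                edges.add(e)
    return sorted(edges)


def run(scn: Scenario, points_per_unit: float = 2.0) -> Trajectory:
    """Integrate a scenario, restarting the integrator at every pulse edge.

    Returns a :class:`Trajectory` sampled densely enough to classify the
    final steady state and to export plottable time courses.
    """
    y = _initial_array(scn)
    if scn.settle_first:
        settled = settle(scn.params, scn.initial_state)
        y = (np.array([settled]) if scn.model == "minimal" else settled.as_array())
    edges = _segment_edges(scn, 0.0)
    ts_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        levels = scn.channel_levels(0.5 * (t0 + t1))
        n = max(int(np.ceil((t1 - t0) * points_per_unit)), 8)
        t_eval = np.linspace(t0, t1, n + 1)
        ts, ys = _integrate_segment(scn.model, scn.params, y, t0, t1, levels, t_eval)
        y = ys[:, -1]
        keep = slice(None) if not ts_all else slice(1, None)
        ts_all.append(ts[keep])
        ys_all.append(ys[:, keep])
    t = np.concatenate(ts_all)
    yy = np.concatenate(ys_all, axis=1)
    ch = np.zeros((len(CHANNELS), t.size))
    for j, tj in enumerate(t):
        lv = scn.channel_levels(tj)
        for i, c in enumerate(CHANNELS):
            ch[i, j] = lv[c]
    names = ("T",) if scn.model == "minimal" else SystemState.NAMES
    return Trajectory(t=t, y=yy, channels=ch, var_names=tuple(names), scenario=scn)


def final_steady_state(traj: Trajectory, window: float = SS_WINDOW,
                       tol: float = SS_TOL):
    """Terminal state of a trajectory, or ``None`` if it is still moving.

    Checks that max |dy/dt| over the trailing ``window`` is below ``tol``
    (never silently returns a transient).  The trajectory must extend
    beyond the last pulse by at least the window.
    """
    scn = traj.scenario
    if window > traj.t[-1] - traj.t[0]:
        raise ValueError("window exceeds trajectory span")
    if scn is not None and scn.pulses:
        last_off = max(p.t_off for p in scn.pulses)
        if traj.t[-1] < last_off + window:
            raise ValueError("trajectory must extend past the last pulse by the window")
    mask = traj.t >= traj.t[-1] - window
    model = scn.model if scn is not None else ("minimal" if traj.y.shape[0] == 1 else "detailed")
    params = scn.params if scn is not None else None
    if params is None:
        raise ValueError("trajectory lacks scenario metadata")
    levels = dict.fromkeys(CHANNELS, 0.0)
    for i in np.nonzero(mask)[0]:
        if scn is not None:
            levels = scn.channel_levels(traj.t[i])
        if np.max(np.abs(_rhs_vector(model, params, traj.y[:, i], levels))) > tol:
            return None
    y = traj.final_state()
    return float(y[0]) if model == "minimal" else SystemState.from_array(y)
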