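"""Parameter sets and state containers for the Th1-granuloma models.

Two models are implemented:

* a **minimal** one-variable switch for Th1 activity ``T`` driven by a lumped
  antigen/cytokine signal, and
* a **detailed** six-variable network of effector T cells (``T``), regulatory
  T cells (``R``), macrophages (``M``) and the cytokines IL-2 (``delta``),
  IFN-gamma (``gamma``) and TNF-alpha (``alpha``).

All quantities are dimensionless densities; time is in arbitrary model units.
Parameter names follow the conventional symbols (``beta_T``, ``k_1a``, ...)
so that configuration files can be audited against the published base values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "MinimalParams",
    "DetailedParams",
    "SystemState",
    "Drives",
    "params_to_text",
    "params_from_text",
]


class ParamError(ValueError):
    """Raised for invalid or unknown parameter values."""


@dataclass(frozen=True)
class MinimalParams:
    """Parameters of the one-variable Th1 activation switch.

    ``dT/dt = beta_T - eps_T*T + f_T * T^2 / (theta_T^2 + T^2)`` with the
    activation drive ``f_T = eta1*A + eta2*c`` combining antigen density ``A``
    and a lumped, constant cytokine density ``c``.

    Attributes
    ----------
    theta_T:
        Half-activation threshold of the autocatalytic (Hill) term.  Raising
        it mimics stronger regulatory-T-cell suppression.
    beta_T:
        Basal influx rate of Th1 activity.
    eps_T:
        First-order clearance rate constant (must be positive).
    eta1, eta2:
        Non-negative coupling coefficients of antigen and cytokine into the
        drive.
    c:
        Lumped cytokine density, held constant in this model.
    """

    theta_T: float = 1.0
    beta_T: float = 0.02
    eps_T: float = 1.0
    eta1: float = 1.0
    eta2: float = 1.0
    c: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ParamError(f"{f.name} must be finite and >= 0, got {v}")
        if self.eps_T <= 0:
            raise ParamError("eps_T must be > 0")
        if self.theta_T <= 0:
            raise ParamError("theta_T must be > 0")

    def with_(self, **kw: float) -> "MinimalParams":
        return replace(self, **kw)


# Base parameter values of the detailed model (the published defaults).
_DETAILED_DEFAULTS = dict(
    beta_T=0.05, eps_T=1.0, theta_T=1.0,
    k_1a=1.0, k_1b=20.5, k_1c=10.0, k_1d=1.0, k_1e=0.1,
    beta_R=0.05, eps_R=1.0, theta_R=1.0,
    k_2a=1.0, k_2b=0.1,
    beta_M=0.05, eps_M=1.0, theta_M=1.0,
    k_6=1.0, k_6b=1.0, k_6c=0.1,
    beta_delta=0.01, eps_delta=10.0, k_3=1.0,
    beta_gamma=0.01, eps_gamma=10.0, k_4a=1.0, k_4b=1.0,
    beta_alpha=0.01, eps_alpha=10.0, k_5a=1.0, k_5b=1.0,
)


@dataclass(frozen=True)
class DetailedParams:
    """Rate constants of the six-variable granuloma network.

    Defaults reproduce the published base parameter table exactly.  The
    coefficients are grouped by the population they drive:

    * Teff drive: ``k_1a`` (antigen presentation, multiplies ``A*M``),
      ``k_1b`` (IL-2), ``k_1c`` (IFN-gamma); ``k_1d`` (Treg inhibition of
      Teff proliferation, divisor of the drive); ``k_1e`` (TNF-alpha-driven
      Teff deactivation/death, acts as extra clearance).
    * Treg drive: ``k_2a`` (IL-2 dependence), ``k_2b`` (TNF-alpha
      antagonism, divisor).
    * Macrophage drive: ``k_6`` (IFN-gamma), ``k_6b`` (TNF-alpha), ``k_6c``
      (Treg inhibition, divisor).
    * Cytokine production: ``k_3`` (IL-2 from Teff); ``k_4a``/``k_4b``
      (IFN-gamma from Teff/macrophage); ``k_5a``/``k_5b`` (TNF-alpha from
      Teff/macrophage).

    Each population also has a basal influx ``beta_*``, clearance ``eps_*``
    and, for the cells, an activation threshold ``theta_*``.
    """

    beta_T: float = _DETAILED_DEFAULTS["beta_T"]
    eps_T: float = _DETAILED_DEFAULTS["eps_T"]
    theta_T: float = _DETAILED_DEFAULTS["theta_T"]
    k_1a: float = _DETAILED_DEFAULTS["k_1a"]
    k_1b: float = _DETAILED_DEFAULTS["k_1b"]
    k_1c: float = _DETAILED_DEFAULTS["k_1c"]
    k_1d: float = _DETAILED_DEFAULTS["k_1d"]
    k_1e: float = _DETAILED_DEFAULTS["k_1e"]
    beta_R: float = _DETAILED_DEFAULTS["beta_R"]
    eps_R: float = _DETAILED_DEFAULTS["eps_R"]
    theta_R: float = _DETAILED_DEFAULTS["theta_R"]
    k_2a: float = _DETAILED_DEFAULTS["k_2a"]
    k_2b: float = _DETAILED_DEFAULTS["k_2b"]
    beta_M: float = _DETAILED_DEFAULTS["beta_M"]
    eps_M: float = _DETAILED_DEFAULTS["eps_M"]
    theta_M: float = _DETAILED_DEFAULTS["theta_M"]
    k_6: float = _DETAILED_DEFAULTS["k_6"]
    k_6b: float = _DETAILED_DEFAULTS["k_6b"]
    k_6c: float = _DETAILED_DEFAULTS["k_6c"]
    beta_delta: float = _DETAILED_DEFAULTS["beta_delta"]
    eps_delta: float = _DETAILED_DEFAULTS["eps_delta"]
    k_3: float = _DETAILED_DEFAULTS["k_3"]
    beta_gamma: float = _DETAILED_DEFAULTS["beta_gamma"]
    eps_gamma: float = _DETAILED_DEFAULTS["eps_gamma"]
    k_4a: float = _DETAILED_DEFAULTS["k_4a"]
    k_4b: float = _DETAILED_DEFAULTS["k_4b"]
    beta_alpha: float = _DETAILED_DEFAULTS["beta_alpha"]
    eps_alpha: float = _DETAILED_DEFAULTS["eps_alpha"]
    k_5a: float = _DETAILED_DEFAULTS["k_5a"]
    k_5b: float = _DETAILED_DEFAULTS["k_5b"]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ParamError(f"{f.name} must be finite and >= 0, got {v}")
        for name in ("eps_T", "eps_R", "eps_M", "eps_delta", "eps_gamma", "eps_alpha"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")
        for name in ("theta_T", "theta_R", "theta_M"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")

    def with_(self, **kw: float) -> "DetailedParams":
        try:
            return replace(self, **kw)
        except TypeError as exc:  # unknown field name
            raise ParamError(str(exc)) from None

    def basal_state(self) -> "SystemState":
        """Componentwise beta/eps fixed point reached when every drive and
        cross-coupling is switched off."""
        return SystemState(
            T=self.beta_T / self.eps_T,
            R=self.beta_R / self.eps_R,
            M=self.beta_M / self.eps_M,
            delta=self.beta_delta / self.eps_delta,
            gamma=self.beta_gamma / self.eps_gamma,
            alpha=self.beta_alpha / self.eps_alpha,
        )


@dataclass(frozen=True)
class SystemState:
    """One point of the six-variable state space (all components >= 0).

    Default values are the published initial conditions.
    """

    T: float = 0.01
    R: float = 0.01
    M: float = 0.001
    delta: float = 0.001
    gamma: float = 0.001
    alpha: float = 0.001

    NAMES = ("T", "R", "M", "delta", "gamma", "alpha")

    def __post_init__(self) -> None:
        for name in self.NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParamError(f"state component {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        # tolerate tiny integrator undershoot, then clamp
        if np.any(y < -1e-9):
            raise ParamError(f"state has negative component beyond tolerance: {y}")
        y = np.maximum(y, 0.0)
        return cls(**dict(zip(cls.NAMES, y)))

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


@dataclass(frozen=True)
class Drives:
    """Instantaneous activation drives of the three cell populations."""

    f_T: float
    f_R: float
    f_M: float


# ---------------------------------------------------------------------------
# flat key-value serialization (auditable against the published table)
# ---------------------------------------------------------------------------

def params_to_text(p: MinimalParams | DetailedParams) -> str:
    """Serialize a parameter set to a flat ``name = value`` text block."""
    kind = "minimal" if isinstance(p, MinimalParams) else "detailed"
    lines = [f"# granulosim {kind} parameters"]
    for f in fields(p):
        lines.append(f"{f.name} = {getattr(p, f.name)!r}")
    return "\n".join(lines) + "\n"


def params_from_text(text: str | Path) -> MinimalParams | DetailedParams:
    """Parse a flat key-value parameter file written by :func:`params_to_text`.

    Unknown keys are an error: silent typos in rate-constant names (e.g.
    ``k_6b`` vs ``k_6c``) must fail loudly.
    """
    if isinstance(text, Path):
        text = text.read_text()
    values: dict[str, float] = {}
    kind = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("#"):
            if "minimal" in line:
                kind = "minimal"
            elif "detailed" in line:
                kind = "detailed"
            continue
        if not line:
            continue
        if "=" not in line:
            raise ParamError(f"malformed parameter line: {raw!r}")
        name, _, val = line.partition("=")
        values[name.strip()] = float(val)
    if kind is None:
        minimal_names = {f.name for f in fields(MinimalParams)}
        kind = "minimal" if set(values) <= minimal_names else "detailed"
    cls = MinimalParams if kind == "minimal" else DetailedParams
    known = {f.name for f in fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ParamError(f"unknown parameter name(s): {sorted(unknown)}")
    return cls(**values)
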