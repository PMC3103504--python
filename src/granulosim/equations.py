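"""Right-hand sides of the Th1-granuloma models, in one place.

This module is the single authoritative transcription of the model
equations; every other part of the package calls into it.

Minimal model (one variable, Th1 activity ``T``)::

    dT/dt = beta_T - eps_T*T + f_T * T^2 / (theta_T^2 + T^2)
    f_T   = eta1*A + eta2*c

The quadratic Hill term is autocatalytic (zero without a seed population),
sigmoidal in ``T`` and saturates at the drive ``f_T``; together with the
linear influx/clearance terms it yields a cubic steady-state equation and
hence a bistable range of ``f_T`` (low vs. high Th1 activity).

Detailed model (six variables)::

    dT/dt = beta_T - eps_T*T - k_1e*alpha*T + f_T * T^2/(theta_T^2 + T^2)
    f_T   = (k_1a*A*M + k_1b*delta + k_1c*gamma) / (1 + k_1d*R)

    dR/dt = beta_R - eps_R*R + f_R * R^2/(theta_R^2 + R^2)
    f_R   = k_2a*delta / (1 + k_2b*alpha)

    dM/dt = beta_M - eps_M*M + f_M * M^2/(theta_M^2 + M^2)
    f_M   = (k_6*gamma + k_6b*alpha) / (1 + k_6c*R)

    d(delta)/dt = beta_delta + k_3*T            - (eps_delta + I_delta)*delta
    d(gamma)/dt = beta_gamma + k_4a*T + k_4b*M  - (eps_gamma + I_gamma)*gamma
    d(alpha)/dt = beta_alpha + k_5a*T + k_5b*M  - (eps_alpha + I_alpha)*alpha

Reading of the interactions:

* ``A*M`` is antigen presentation: macrophages are the only
  antigen-presenting cells, so antigen enters the Teff drive only through
  the product with ``M``.
* Tregs inhibit Teff *proliferation*: ``k_1d*R`` divides the autocatalytic
  drive (it sits in the denominator of the activation term).  Their
  downregulation of cytokine output is indirect, through lower ``T``.
* TNF-alpha suppresses Teffs by deactivation/killing (death-receptor
  signalling): ``k_1e*alpha`` adds to Teff clearance.
* Tregs are IL-2 dependent (``k_2a*delta``) and antagonized by TNF-alpha
  (``k_2b*alpha`` divisor), so the Teff->Treg influence can change sign
  when TNF-alpha dominates.
* Macrophages are activated by IFN-gamma and TNF-alpha (classical M1
  stimuli, both fed by Teffs and macrophages themselves) and suppressed by
  Tregs (``k_6c*R`` divisor); Teffs recruit macrophages through the
  cytokines they secrete rather than by direct contact.
* Cytokine inhibitors (anti-IL-2 ``I_delta``, anti-IFN-gamma ``I_gamma``,
  anti-TNF-alpha ``I_alpha``) neutralize their target by first-order
  mass action, i.e. an extra clearance ``-I_x * x`` while the therapy
  pulse is on.

Where the published description left the algebra open (term placement for
``k_1e``, the inputs of the macrophage drive), the form above was selected
from the structurally admissible readings as the one that reproduces the
published switching experiments; see ``docs/methods.md`` for the full
rationale.
"""

from __future__ import annotations

import numpy as np

from .params import DetailedParams, Drives, MinimalParams

__all__ = [
    "minimal_drive",
    "hill_activation",
    "minimal_rhs",
    "detailed_drives",
    "detailed_rhs",
]


def minimal_drive(A: float, p: MinimalParams) -> float:
    """Lumped activation drive ``f_T = eta1*A + eta2*c`` of the minimal model.

    Parameters
    ----------
    A:
        Antigen density (>= 0).
    p:
        Minimal-model parameters.
    """
    if A < 0:
        raise ValueError(f"antigen density must be >= 0, got {A}")
    return p.eta1 * A + p.eta2 * p.c


def hill_activation(x: float, f: float, theta: float) -> float:
    """Autocatalytic activation rate ``f * x^2 / (theta^2 + x^2)``.

    Vanishes at ``x = 0`` (no seed population, no autocatalysis), is
    nondecreasing in ``x`` and saturates at the drive ``f`` as ``x`` grows;
    scales linearly with ``f``.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if x < 0 or f < 0:
        raise ValueError("x and f must be >= 0")
    x2 = x * x
    return f * x2 / (theta * theta + x2)


def minimal_rhs(T: float, A: float, p: MinimalParams) -> float:
    """``dT/dt`` of the minimal Th1 switch."""
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    return p.beta_T - p.eps_T * T + hill_activation(T, minimal_drive(A, p), p.theta_T)


def detailed_drives(y, A: float, p: DetailedParams) -> Drives:
    """Instantaneous activation drives (f_T, f_R, f_M) of the detailed model.

    ``y`` is the state as an array-like ``(T, R, M, delta, gamma, alpha)``.
    """
    T, R, M, delta, gamma, alpha = (max(float(v), 0.0) for v in y)
    if A < 0:
        raise ValueError(f"antigen density must be >= 0, got {A}")
    f_T = (p.k_1a * A * M + p.k_1b * delta + p.k_1c * gamma) / (1.0 + p.k_1d * R)
    f_R = p.k_2a * delta / (1.0 + p.k_2b * alpha)
    f_M = (p.k_6 * gamma + p.k_6b * alpha) / (1.0 + p.k_6c * R)
    return Drives(f_T=f_T, f_R=f_R, f_M=f_M)


def detailed_rhs(y, A: float, I, p: DetailedParams) -> np.ndarray:
    """Six time derivatives of the detailed model.

    Parameters
    ----------
    y:
        State array ``(T, R, M, delta, gamma, alpha)``; tiny negative
        excursions from the integrator are clamped to zero.
    A:
        Antigen density currently applied.
    I:
        Inhibitor levels ``(I_delta, I_gamma, I_alpha)`` currently applied.
    p:
        Parameter set.
    """
    T, R, M, delta, gamma, alpha = (max(float(v), 0.0) for v in y)
    I_delta, I_gamma, I_alpha = I
    if min(I_delta, I_gamma, I_alpha) < 0:
        raise ValueError("inhibitor levels must be >= 0")
    d = detailed_drives((T, R, M, delta, gamma, alpha), A, p)
    dT = (p.beta_T - p.eps_T * T - p.k_1e * alpha * T
          + hill_activation(T, d.f_T, p.theta_T))
    dR = p.beta_R - p.eps_R * R + hill_activation(R, d.f_R, p.theta_R)
    dM = p.beta_M - p.eps_M * M + hill_activation(M, d.f_M, p.theta_M)
    dd = p.beta_delta + p.k_3 * T - (p.eps_delta + I_delta) * delta
    dg = p.beta_gamma + p.k_4a * T + p.k_4b * M - (p.eps_gamma + I_gamma) * gamma
    da = p.beta_alpha + p.k_5a * T + p.k_5b * M - (p.eps_alpha + I_alpha) * alpha
    return np.array([dT, dR, dM, dd, dg, da])
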