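"""Phenomenological mitochondrial permeability transition (MPT).

Three ingredients:

* a ubiquinol-gated pore open fraction — an arctangent switch in QH₂
  centered on the threshold ``qthr`` (the largest QH₂ level compatible
  with the ATP-producing branch);
* Goldman–Hodgkin–Katz (GHK) efflux of matrix solutes, proportional to
  the open fraction; at Δψ = 0 (the operative regime while the pore is
  open) the GHK expression reduces to its Fickian limit
  ``P·k·(c_matrix − c_external)``;
* dissipation of Δψ while the pore is engaged, implemented as a smooth
  high-gain conductance rather than a hard constraint so the vector
  field stays integrable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MPTParams

__all__ = ["EffluxSpec", "permeability", "ghk_flux", "ghk_efflux",
           "clamp_conductance", "V_THERMAL_MV"]

#: thermal voltage RT/F at 37 °C, mV
V_THERMAL_MV = 26.73


@dataclass(frozen=True)
class EffluxSpec:
    """One solute crossing the open pore."""

    solute: str
    z: float            # effective transported charge
    c_matrix: float     # nmol/mg (matrix side)
    c_external: float   # nmol/mg-equivalent (cytosolic bath)
    k_perm: float       # permeability scale at full opening, s^-1

    def __post_init__(self) -> None:
        if self.c_matrix < 0 or self.c_external < 0:
            raise ValueError(f"negative concentration for solute {self.solute!r}")


def permeability(qh2: float, p: MPTParams) -> float:
    """Pore open fraction P ∈ (0, 1) as a function of ubiquinol.

    ``P = (arctan(steepness·(qh2 − qthr)) / (π/2) + 1) / 2`` — a steep
    sigmoid, strictly increasing in qh2, with P(qthr) = 1/2 and the
    symmetry P(qthr + d) + P(qthr − d) = 1.
    """
    return float((np.arctan(p.steepness * (qh2 - p.qthr)) / (0.5 * np.pi) + 1.0) / 2.0)


def _ghk_driving(u: float, c_from: float, c_to: float) -> float:
    """GHK driving factor ``u·(c_from − c_to·e^{−u}) / (1 − e^{−u})``.

    The removable singularity at u → 0 is evaluated through the
    two-term series ``(c_from − c_to) + u·(c_from + c_to)/2`` rather
    than left to floating-point cancellation.
    """
    if abs(u) < 1e-6:
        return (c_from - c_to) + 0.5 * u * (c_from + c_to)
    em = np.expm1(-u)            # e^{-u} − 1, stable for small |u|
    return u * (c_from - c_to * (em + 1.0)) / (-em)


def ghk_flux(z: float, c_from: float, c_to: float, dphi: float,
             permeability_scale: float = 1.0) -> float:
    """Goldman–Hodgkin–Katz electrodiffusion flux, ``from`` side → ``to`` side.

    ``dphi`` (mV) is the potential of the *from* side minus the *to*
    side: a positive ``dphi`` pushes a positive charge out of the
    ``from`` side.  For z = 0 or dphi = 0 the expression reduces to
    Fick's law ``P·(c_from − c_to)``.  Positive result = net from → to.
    """
    u = z * dphi / V_THERMAL_MV
    return permeability_scale * _ghk_driving(u, c_from, c_to)


def ghk_efflux(spec: EffluxSpec, pore_open: float, dpsi: float) -> float:
    """Matrix → external efflux through the open pore, nmol·mg⁻¹·s⁻¹.

    Linear in the open fraction.  ``dpsi`` is the usual positive
    membrane-potential magnitude with the matrix negative, so the
    potential of the matrix side relative to the outside is ``−dpsi``
    and cation (z > 0) efflux is electrically opposed.  During the MPT
    the Δψ clamp holds dpsi ≈ 0 and the flux is effectively Fickian.
    """
    if not 0.0 <= pore_open <= 1.0:
        raise ValueError(f"pore open fraction {pore_open} outside [0, 1]")
    return pore_open * ghk_flux(spec.z, spec.c_matrix, spec.c_external,
                                -dpsi, spec.k_perm)


def clamp_conductance(pore_open: float, p: MPTParams) -> float:
    """Smoothly engaged charge conductance that collapses Δψ during the MPT.

    Zero while the pore is closed; ≈ ``g_clamp`` once the open fraction
    exceeds ``engage_center`` (default 1/2).
    """
    x = (pore_open - p.engage_center) / p.engage_width
    return p.g_clamp / (1.0 + np.exp(np.clip(-x, -500.0, 500.0)))
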