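"""Matrix-pH dynamics and Ca²⁺-uniporter uptake.

Both act as *modifiers* of the respiratory-chain bifurcation structure:
matrix alkalinization slows the Q-cycle (complex III needs matrix H⁺ to
protonate the i-site quinone) and so pushes the chain toward the
ROS-producing branch, while Ca²⁺ entry depolarizes Δψ, accelerates
compensatory H⁺ pumping, and alkalinizes the matrix with the same net
effect.
"""

from __future__ import annotations

import numpy as np

from .params import CaParams, PHParams
from .mpt import ghk_flux

__all__ = ["proton_balance", "ca_uptake_flux"]


def proton_balance(rates, p: PHParams) -> float:
    """d(matrix pH)/dt from the H⁺ stoichiometry of the pumping reactions.

    Complex I and the lumped complex III/IV turnover pump H⁺ out of the
    matrix (alkalinize, pH rises); ATP synthase and the proton leak
    return H⁺ (acidify).  The net proton flux is scaled by the buffering
    capacity (nmol·mg⁻¹ per pH unit).

    ``rates`` is a :class:`~mitoswitch.core_model.ReactionRates` (or any
    mapping supporting ``rates["v1"]`` … ``rates["v6"]``).
    """
    net_out = (p.h_per_v1 * rates["v1"] + p.h_per_v3 * rates["v3"]
               - p.h_per_v5 * rates["v5"] - p.h_per_leak * rates["v6"])
    return net_out / p.buffering


def ca_uptake_flux(ca_ext: float, p: CaParams, dpsi: float) -> float:
    """Uniporter Ca²⁺ uptake (external → matrix), nmol·mg⁻¹·s⁻¹.

    Goldman–Hodgkin–Katz flux for z = +2 with a fixed matrix activity:
    the outside sits at potential +dpsi relative to the matrix, so a
    positive dpsi drives uptake.  Zero at electrochemical equilibrium
    and strictly increasing in dpsi at fixed concentrations.
    """
    if ca_ext < 0:
        raise ValueError(f"ca_ext = {ca_ext} is negative")
    return ghk_flux(2.0, ca_ext, p.ca_matrix, dpsi, p.p_uniporter)
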