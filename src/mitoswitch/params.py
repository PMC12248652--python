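"""Parameter containers and defaults for the reduced respiratory-chain model.

All metabolite pools are in nmol per mg of mitochondrial protein
(nmol·mg⁻¹), membrane potential in mV, time in seconds.  External
glutamate (``glu_o``) is in mM, as in the figure protocols.

The reaction set is a deliberately small lumped network: one rate per
respiratory complex (complex IV is taken at quasi-steady state with
complex III), ATP synthase, proton leak, ATP consumption, and a lumped
Krebs / malate–aspartate backbone that carries the glutamate signal to
complex II.  Reaction indices (v1…v16) used throughout the code:

====  =======================================================  ==========================
idx   reaction                                                 stoichiometry
====  =======================================================  ==========================
v1    complex I                                                NADH + Q → NAD⁺ + QH₂, 4q↑
v2    complex II (succinate dehydrogenase)                     SUC + Q → MAL + QH₂
v3    complex III (Q-cycle)                                    QH₂ → Q, 2q↑
v4    complex IV (quasi-steady with v3)                        4q↑
v5    ATP synthase                                             ADP → ATP, 3q↓
v6    proton leak                                              1q↓
v7    ATP consumption (cellular workload)                      ATP → ADP
v8    glutamate dehydrogenase                                  GLU → AKG + NADH
v9    aspartate transaminase                                   GLU + OAA → AKG + ASP
v10   α-ketoglutarate dehydrogenase (lumped to succinate)      AKG → SUC + NADH
v11   malate dehydrogenase                                     MAL → OAA + NADH
v12   citrate synthase + isocitrate DH (acetyl-CoA lumped)     OAA → AKG + NADH
v13   malate drain (export / biosynthetic use)                 MAL → ∅
v14   malate supply (isolated-mitochondria protocols)          ∅ → MAL
v15   aspartate export (glutamate/aspartate antiporter)        ASP → ∅
v16   glutamate entry (carries the ``glu_o`` parameter)        ∅ → GLU
v17   complex-I flavin electron leak to O₂ (superoxide)        NADH → NAD⁺
v18   complex-III semiquinone electron leak to O₂              QH₂ → Q
v19   dicarboxylate-carrier succinate export                   SUC → ∅
====  =======================================================  ==========================

``q↑`` / ``q↓`` mark outward / inward charge translocation entering the
Δψ balance.  Complex III is the bistable element: its rate requires both
ubiquinol (QH₂, o-site) and ubiquinone (Q, i-site, cooperatively), so it
collapses when the pool is driven to near-complete reduction.
"""

from __future__ import annotations

from typing import Dict, List, Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MPTParams",
    "PHParams",
    "CaParams",
    "ModelParams",
    "EFFLUX_SOLUTES",
]

#: Matrix solutes released through the permeability-transition pore in the
#: default configuration: the Krebs intermediates plus matrix
#: glutamate/aspartate.  Adenine and pyridine nucleotide pools are treated
#: as impermeant on the timescale of a transient pore opening, which also
#: keeps the ATP+ADP and NAD⁺+NADH conservation sums exact.
EFFLUX_SOLUTES: List[str] = ["oaa", "akg", "succ", "mal", "glu_m", "asp"]


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MPTParams(_Frozen):
    """Phenomenological permeability-transition settings.

    The pore open fraction is a steep arctangent switch in ubiquinol:
    ``P = (arctan(steepness·(qh2 − qthr))/(π/2) + 1)/2``.
    """

    qthr: float = Field(1.55, gt=0, description="QH2 switching threshold, nmol/mg; the largest ubiquinol level compatible with the ATP-producing branch (ships as the qh2 value at the limit point of the default continuation diagram)")
    steepness: float = Field(1000.0, gt=0, description="switch steepness, (nmol/mg)^-1")
    k_efflux: float = Field(10.0, ge=0, description="per-solute efflux rate scale during full opening, s^-1")
    c_ext: Dict[str, float] = Field(
        default_factory=lambda: {s: 0.005 for s in EFFLUX_SOLUTES},
        description="external (cytosolic bath) concentration per solute, nmol/mg-equivalent",
    )
    solute_charge: Dict[str, float] = Field(
        default_factory=lambda: {s: 0.0 for s in EFFLUX_SOLUTES},
        description="effective transported charge per solute (0 = electroneutral with counter-ion)",
    )
    solutes: List[str] = Field(default_factory=lambda: list(EFFLUX_SOLUTES))
    g_clamp: float = Field(1.0, ge=0, description="high-gain charge conductance that dissipates dpsi while the pore is engaged, nmol/mg/s per mV")
    engage_center: float = Field(0.5, gt=0, lt=1, description="pore open fraction at which the dpsi clamp engages")
    engage_width: float = Field(0.05, gt=0, description="smoothness of the clamp engagement sigmoid")
    k_h_equil: float = Field(0.02, ge=0, description="rate of matrix-pH relaxation toward cytosolic pH while the pore is open, s^-1")
    ph_cytosol: float = 7.0

    @model_validator(mode="after")
    def _check_solutes(self) -> "MPTParams":
        for s in self.solutes:
            if s not in self.c_ext or s not in self.solute_charge:
                raise ValueError(f"efflux solute {s!r} lacks c_ext/charge entries")
        return self


class PHParams(_Frozen):
    """Matrix-pH dynamics (active when ``ModelParams.ph_variable``).

    Proton pumping by complexes I and III/IV removes matrix H⁺
    (alkalinizes); the synthase and the leak return H⁺ (acidify).
    """

    buffering: float = Field(40.0, gt=0, description="buffering capacity, nmol/mg per pH unit")
    h_per_v1: float = Field(4.0, ge=0, description="H+ pumped out per complex-I turnover")
    h_per_v3: float = Field(6.0, ge=0, description="H+ pumped out per complex-III turnover (complex IV lumped in)")
    h_per_v5: float = Field(3.0, ge=0, description="H+ returned per ATP synthesized")
    h_per_leak: float = Field(1.0, ge=0)
    ph_init: float = Field(7.0, description="initial matrix pH")
    nh_ciii: float = Field(0.6, ge=0, description="order of the complex-III dependence on matrix H+ (i-site quinone protonation)")


class CaParams(_Frozen):
    """Ca²⁺ uniporter uptake (active when ``ModelParams.ca_enabled``).

    Uptake follows the Goldman–Hodgkin–Katz flux for z = +2 driven by Δψ;
    the matrix activity is held constant (matrix Ca²⁺ is assumed buffered
    by protein binding and phosphate precipitation), so only the external
    pool is a state variable.
    """

    p_uniporter: float = Field(0.003, ge=0, description="uniporter permeability scale, s^-1")
    ca_matrix: float = Field(0.001, ge=0, description="fixed matrix Ca2+ activity, nmol/mg-equivalent")
    ca_ext_init: float = Field(0.0, ge=0, description="initial external Ca2+, nmol/mg")
    h_per_ca: float = Field(0.0, ge=0, description="explicit H+ efflux per Ca2+ charge taken up (0: compensation emerges from pump kinetics)")


class ModelParams(_Frozen):
    """Kinetic constants, conservation totals and feature flags.

    Defaults are the package's calibrated reference set: at external
    glutamate 0.01 mM the model settles on the ATP-producing branch, at
    0.08 mM (permeability transition disabled) on the ROS-producing
    branch; the functional branch terminates at a limit point at
    glu_o ≈ 0.0225 mM (qh2 ≈ 1.55 nmol/mg, the shipped Qthr).
    """

    # conservation totals, nmol/mg
    a_tot: float = Field(20.0, gt=0, description="ATP + ADP")
    n_tot: float = Field(20.0, gt=0, description="NAD+ + NADH")
    q_tot: float = Field(4.1, gt=0, description="Q + QH2")

    # v1 complex I
    vm1: float = Field(4.0, ge=0)
    kn1: float = Field(1.03, gt=0, description="NADH half-saturation")
    kq1: float = Field(0.6, gt=0, description="Q half-saturation")
    v1_half: float = Field(180.0, description="dpsi back-pressure midpoint, mV")
    v1_slope: float = Field(15.0, gt=0)

    # v2 complex II
    vm2: float = Field(3.97, ge=0)
    k2s: float = Field(9.74, gt=0, description="succinate half-saturation")
    kq2: float = Field(0.05, gt=0)
    ki_oaa: float = Field(0.30, gt=0, description="oxaloacetate inhibition constant")

    # v3 complex III (Q-cycle; bistable element)
    vm3: float = Field(3.6, ge=0)
    ko3: float = Field(0.3, gt=0, description="QH2 (o-site) half-saturation")
    ki3: float = Field(1.25, gt=0, description="Q (i-site) half-saturation")
    nq3: float = Field(1.0, ge=1, description="Hill exponent of the complex-III Q (i-site) dependence")
    v3_half: float = Field(205.0, description="dpsi back-pressure midpoint, mV")
    v3_slope: float = Field(15.0, gt=0)

    # v5 ATP synthase
    vm5: float = Field(4.97, ge=0)
    k5: float = Field(2.0, gt=0, description="ADP half-saturation")
    v5_half: float = Field(120.0, description="dpsi activation midpoint, mV")
    v5_slope: float = Field(10.0, gt=0)

    # v6 proton leak
    k_leak: float = Field(0.055, ge=0, description="leak conductance, nmol/mg/s per mV")

    # v7 ATP consumption
    vm7: float = Field(2.8, ge=0)
    k7: float = Field(2.0, gt=0)

    # v8 glutamate dehydrogenase
    vm8: float = Field(1.3, ge=0)
    k8: float = Field(1.03, gt=0)
    k_nad: float = Field(0.041, gt=0, description="NAD+ half-saturation shared by matrix dehydrogenases")

    # v9 aspartate transaminase (mass action)
    k9: float = Field(1.15, ge=0, description="second-order rate constant, (nmol/mg)^-1 s^-1")

    # v10 akg dehydrogenase lump
    vm10: float = Field(5.97, ge=0)
    k10: float = Field(0.86, gt=0)

    # v11 malate dehydrogenase
    vm11: float = Field(2.1, ge=0)
    k11: float = Field(0.8, gt=0)
    ki_oaa_mdh: float = Field(0.64, gt=0, description="product inhibition of MDH by oxaloacetate")

    # v12 citrate synthase + IDH lump
    vm12: float = Field(0.37, ge=0)
    k12: float = Field(0.05, gt=0)

    # v13..v15 exchange
    k13: float = Field(0.068, ge=0, description="malate drain rate constant, s^-1")
    k19: float = Field(0.01, ge=0, description="succinate export rate constant, s^-1")
    mal_in: float = Field(0.0, ge=0, description="constant malate supply, nmol/mg/s (isolated-mitochondria protocols)")
    k15: float = Field(0.3, ge=0, description="aspartate export rate constant, s^-1")

    # v16 glutamate entry
    vm16: float = Field(1.5, ge=0)
    kg16: float = Field(0.147, gt=0, description="external-glutamate half-saturation, mM")
    kgi16: float = Field(25.3, gt=0, description="matrix-glutamate product inhibition of entry, nmol/mg")
    k16x: float = Field(0.041, ge=0, description="basal matrix-glutamate export rate constant, s^-1")
    glu_o: float = Field(0.01, ge=0, description="external glutamate concentration, mM")

    # membrane
    c_mem: float = Field(2e-3, gt=0, description="membrane capacitance, charge-nmol/mg per mV")
    q_per_v1: float = Field(4.0, ge=0, description="charges translocated per complex-I turnover")
    q_per_v3: float = Field(2.0, ge=0)
    q_per_v4: float = Field(4.0, ge=0)
    q_per_v5: float = Field(3.0, ge=0)

    # v17/v18 electron leak to O2 (superoxide formation); rates are the
    # leak scale times the matching ROS-species fraction, so ROS output
    # tracks the semiquinone content of each complex
    k_ros1: float = Field(0.5, ge=0, description="complex-I flavin leak scale, nmol/mg/s at full FMN-radical occupancy")
    k_ros3: float = Field(0.1, ge=0, description="complex-III semiquinone leak scale, nmol/mg/s at full SQ occupancy")

    # semiquinone (ROS-proxy) fraction half-saturations
    kf_ci: float = Field(12.0, gt=0, description="NADH level at half-maximal complex-I flavin radical fraction")
    kf_ciii: float = Field(2.8, gt=0, description="QH2 level at half-maximal complex-III semiquinone fraction")
    kf_cii: float = Field(3.2, gt=0, description="QH2 level at half-maximal complex-II FAD radical fraction")

    # regime classifier
    dpsi_floor: float = Field(100.0, description="minimal dpsi for the ATP-producing label, mV")
    classify_margin: float = Field(0.15, ge=0, description="relative dead-band around the thresholds in which classification is UNRESOLVED")

    # unit bridge to the spatial module
    mg_protein_per_l: float = Field(4.0e4, gt=0, description="mg mitochondrial protein per liter matrix volume (nmol/mg → µM conversion: ×mg_protein_per_l×1e-3)")

    # feature flags and sub-models
    mpt_enabled: bool = False
    ph_variable: bool = False
    ca_enabled: bool = False
    closed_external: bool = Field(False, description="track finite external glutamate/malate pools instead of an infinite bath")
    bath_volume_ratio: float = Field(10.0, gt=0, description="external:matrix volume ratio used in closed-bath mode")

    mpt: MPTParams = Field(default_factory=MPTParams)
    ph: PHParams = Field(default_factory=PHParams)
    ca: CaParams = Field(default_factory=CaParams)

    @model_validator(mode="after")
    def _check_qthr(self) -> "ModelParams":
        if not (0.0 < self.mpt.qthr < self.q_tot):
            raise ValueError(
                f"mpt.qthr={self.mpt.qthr} must lie strictly inside (0, q_tot={self.q_tot})"
            )
        return self

    def with_updates(self, **kw: float) -> "ModelParams":
        """Return a copy with top-level fields replaced (used by sweeps/events)."""
        return self.model_copy(update=kw)


RegimeLabel = Literal["ATP_PRODUCING", "ROS_PRODUCING", "UNRESOLVED"]
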