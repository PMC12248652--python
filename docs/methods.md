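# Methods

## The model in one paragraph

`mitoswitch` implements a reduced kinetic model of the mitochondrial
respiratory chain (RC) in which the chain is bistable: a **functional,
ATP-producing** steady state (moderate ubiquinol, high Δψ and ATP, low
semiquinone content) coexists with a **signaling, ROS-producing** state
(near-complete ubiquinone reduction, collapsed Δψ and ATP, high
semiquinone content). The bistability originates in complex III's
Q-cycle, which consumes *both* ubiquinol (QH₂, o-site) and ubiquinone
(Q, i-site): driving the pool toward full reduction starves the i-site
and chokes electron exit while complexes I and II keep reducing
whatever Q remains. An excess of external glutamate — imported into the
matrix, transaminated against oxaloacetate (relieving oxaloacetate
inhibition of complex II) and deaminated into Krebs-cycle carbon —
pushes the chain over this edge. A phenomenological mitochondrial
permeability transition (MPT), gated by QH₂, can rescue the collapsed
state: the open pore voids the matrix metabolite pools, the electron
pressure on the quinone pool falls, complex III re-oxidizes the pool,
and the chain returns to ATP production. On top of the temporal model,
a finite-volume solver reproduces glutamate spillover and H₂O₂
production on a voxelized tissue phantom with threshold-switched
mitochondrial sources.

## Reaction network

One lumped rate per respiratory complex plus lumped metabolism
(reaction indices as used throughout the code; pools in nmol·mg⁻¹ of
mitochondrial protein, time in s):

| idx | reaction | rate law (schematic) |
|-----|----------|----------------------|
| v1 | complex I, NADH + Q → NAD⁺ + QH₂, 4 charges out | Vm·MM(NADH)·MM(Q)·σ↓(Δψ) |
| v2 | complex II, SUC + Q → MAL + QH₂ | Vm·MM(SUC)·MM(Q)·/(1+OAA/Ki) |
| v3 | complex III (Q-cycle), QH₂ → Q, 2 charges out | Vm·MM(QH₂)·MM(Q)·σ↓(Δψ)·10^(0.6·(7−pH)) |
| v4 | complex IV, quasi-steady with v3, 4 charges out | = v3 |
| v5 | ATP synthase, ADP → ATP, 3 charges in | Vm·MM(ADP)·σ↑(Δψ), exactly 0 at Δψ = 0 |
| v6 | proton leak (ohmic) | k·Δψ |
| v7 | ATP consumption (workload) | Vm·MM(ATP) |
| v8 | glutamate dehydrogenase, GLU → AKG + NADH | Vm·MM(GLU)·MM(NAD⁺) |
| v9 | aspartate transaminase, GLU + OAA → AKG + ASP | k·GLU·OAA |
| v10 | α-KG dehydrogenase (lumped), AKG → SUC + NADH | Vm·MM(AKG)·MM(NAD⁺) |
| v11 | malate dehydrogenase, MAL → OAA + NADH | Vm·MM(MAL)·MM(NAD⁺)·/(1+OAA/Ki) |
| v12 | citrate synthase + IDH (acetyl-CoA lumped), OAA → AKG + NADH | Vm·MM(OAA)·MM(NAD⁺) |
| v13 | malate drain | k·MAL |
| v14 | malate supply (isolated-mitochondria protocols) | constant |
| v15 | aspartate export | k·ASP |
| v16 | glutamate entry (drive parameter `glu_o`, mM) | Vm·MM(glu_o)·/(1+GLU/Kgi) − k·GLU |
| v17 | complex-I flavin electron leak to O₂ | k·f_CI(NADH) |
| v18 | complex-III semiquinone electron leak to O₂ | k·f_CIII(QH₂) |
| v19 | dicarboxylate-carrier succinate export | k·SUC |

σ↓/σ↑ are logistic functions of Δψ (thermodynamic back-pressure on the
pumps, activation of the synthase). Conserved pairs ATP+ADP = 20,
NAD⁺+NADH = 20 and Q+QH₂ = 4.1 nmol·mg⁻¹ are enforced *exactly* by
integrating one member of each pair and reconstructing the partner.
Δψ evolves as net outward charge flux over a fixed capacitance
C_mem = 2×10⁻³ nmol·mg⁻¹·mV⁻¹, calibrated so the resting potential
sits near 130–180 mV. Matrix pH, when dynamic, is driven by the H⁺
stoichiometry of pumping (4 H⁺ per complex-I turnover, 6 per lumped
complex-III/IV turnover out; 3 per ATP in; 1 per leak charge) over a
buffering capacity of 40 nmol·mg⁻¹ per pH unit; matrix H⁺ enters
complex III's rate because the i-site quinone must be protonated from
the matrix, which is what makes alkalinization a transition trigger.

The electron leaks v17/v18 are scaled by the same semiquinone
("ROS-generating species") fractions that the package reports:
saturating Hill functions of NADH (complex-I flavin radical) and QH₂
(complex-III semiubiquinone, complex-II FAD radical). They are small on
the functional branch (≤ 1 % of electron flux) but dominant in the
ROS-producing state, and they are what lets the MPT rescue work: with
the matrix carbon pools voided by the open pore, the leaks discharge
NADH and QH₂ until complex III can restart.

## Permeability transition

Pore open fraction: `P(QH₂) = (arctan(1000·(QH₂ − Qthr))/(π/2) + 1)/2`,
a steep switch with `P(Qthr) = ½` and the symmetry `P(Qthr+d) +
P(Qthr−d) = 1`. `Qthr` = 1.55 nmol·mg⁻¹ ships as the ubiquinol level
of the limit point of the default continuation diagram — by definition
the largest QH₂ compatible with an ATP-producing steady state — and can
be overridden in config (a helper recomputes it from a fresh
continuation). While the pore is open:

* matrix solutes (the Krebs intermediates and matrix
  glutamate/aspartate, configurable) leave by Goldman–Hodgkin–Katz
  electrodiffusion, linear in `P`, with scale 10 s⁻¹ at full opening
  against a nearly empty cytosolic bath (0.005 nmol·mg⁻¹-equivalent).
  Adenine and pyridine nucleotides are treated as impermeant on the
  timescale of a transient opening, which also keeps the conservation
  sums exact. At the clamped Δψ ≈ 0 the GHK expression reduces to its
  Fickian limit; the removable singularity is evaluated analytically.
* Δψ is dissipated by a smooth high-gain conductance engaged when
  `P` exceeds ½ (a hard clamp would make the vector field
  non-integrable). The pore current is treated as carried by H⁺, so it
  feeds back into the matrix-pH balance — without this the pumps would
  alkalinize without bound during a long opening.
* matrix pH relaxes toward cytosolic pH 7 at 0.02 s⁻¹·P — slow enough
  that a Ca²⁺-driven alkalinization outlives individual pore openings,
  which is what makes the ROS-residence time scale with the Ca²⁺ load.

## Calibration and the study conditions

The rate constants are the package's own calibrated set (frozen in
`params.py`), chosen so that the canonical protocols hold:

* 0.01 mM external glutamate → ATP-producing steady state; 0.08 mM
  (MPT disabled) → ROS-producing; after the pulse returns to 0.01 mM
  the chain stays ROS-producing (no return without the MPT).
* the functional branch terminates at a limit point at
  `glu_o ≈ 0.0225` mM; the ROS branch extends to arbitrarily low
  glutamate, so up/down parameter sweeps disagree everywhere left of
  the fold (hysteresis).
* with the MPT enabled the 0.08 mM run recovers; with a ten-fold lower
  ATP demand the recovery repeats as sustained relaxation oscillations
  (pore engagements every ~2–3 min), which stop when glutamate is
  dropped to 0.01 mM mid-run and accelerate when the transaminase
  maximal rate is raised five-fold.
* with dynamic pH at 0.04 mM glutamate, an initial matrix pH of 6
  leaves the chain ATP-producing while pH 7, 8, 9 trigger the
  transition (acid resistance); with Ca²⁺ uniporter uptake at
  0.013 mM glutamate, 5 nmol·mg⁻¹ initial Ca²⁺ is sub-threshold while
  9 and 12 trigger it with ROS residence increasing in the load.

Trajectory regimes are classified from QH₂ against `Qthr` (±15 %
dead-band) and Δψ against a 100 mV floor; states inside the corridor
are reported UNRESOLVED rather than guessed. For runs with pore
flicker, the prevailing regime of the trailing window (time-averaged
state) is the robust label.

## Numerics

* Stiff integration: `scipy` BDF, rtol 10⁻⁸ / atol 10⁻¹⁰; mid-run
  parameter changes are handled by segmented integration at the event
  time, never by interpolating across the discontinuity.
* Steady states: scaled Newton (`hybr`, `lm` fallback) with the Δψ row
  weighted by C_mem and the pH row by the buffering capacity;
  stability from the Jacobian spectrum of the reduced (pool-eliminated)
  system, central differences with step `max(10⁻⁷, 10⁻⁷·|x|)`.
* Continuation: pseudo-arclength in scaled (state, parameter) space
  with a secant predictor and Newton corrector; step halving on
  failure, gentle growth on success. Limit points are flagged by
  tangent reversal (with the near-zero real eigenvalue as residual),
  Hopf points by a sign change in the real part of the least-damped
  complex pair, refined by bracketed bisection re-correcting the state
  at every trial point. The machinery is generic over any residual
  f(x, p) and is verified against the fold and Hopf normal forms.
* IVP sweeps settle each parameter value until the weighted residual
  falls below 10⁻⁸ (time cap 3000 s); oscillatory points are detected
  by peak counting and excluded from branches rather than silently
  included.

### A note on the bifurcation census

In this model the functional branch terminates in a **single limit
point**. The least-damped complex eigenvalue pair approaches the axis
near the fold (to within ~10⁻³ s⁻¹ over wide parameter ranges) but does
not cross it, so no Hopf points are detected: the oscillatory
instability that would split the termination into a
Hopf–Hopf–limit-point cluster is not present in this reaction network
at the shipped calibration. Sustained oscillations in the package arise
only through the MPT relief cycle, not from a core-model limit cycle.
The detection machinery itself resolves both point types (verified on
normal forms), so the census is a property of the model, not of the
numerics.

## Spatial solver

Units µm / ms / µM. The digital phantom is a constructive-solid-geometry
surrogate: an ellipsoidal envelope (semi-axes 1.42 × 1.60 × 1.30 µm)
holding two corrugated dendrites along the convection axis (Y), eight
prolate mitochondria (4 per dendrite, seed-permuted transverse slots),
five synaptic contact patches (3 small, 2 large) on the dendrite
membranes, and an interstitial space (ISF) built as a thin film
(~0.115 µm) sheathing the dendrites plus two transverse ISF sheets that
cut the astrocyte bulk into its three parts. Thin-film ISF is what
gives neuropil its high surface-to-volume ratio; the film/sheet
construction reaches the reference ISF area (48.16 µm², within 5 % as
measured on a marching-cubes isosurface) while bisection on the sheet
thickness and the mitochondrion scale plus an exact voxel-trim pass pin
the ISF and mitochondrial volumes (2.7729 / 0.59325 µm³) to well within
1 %. Voxel size 0.05 µm (the smallest mitochondrion axis spans 6
voxels).

Glutamate lives on the ISF: backward-Euler diffusion
(D = 1.29×10⁻⁶ cm²/s, one sparse LU), explicit first-order upwind
advection along +Y (|u| = 5×10⁻⁷ m/s, CFL-guarded), Michaelis–Menten
EAAT uptake on astrocyte and neuron membrane faces (surface densities
1.25×10⁻⁸ / 1.25×10⁻⁹ mol·m⁻², turnover 41 s⁻¹, Km 12 µM) applied as a
positivity-preserving per-voxel implicit substep, and synaptic release
as Dirichlet spikes on the contact patches (instantaneous rise to a
configurable peak — 1 mM small / 2 mM large synapses, decay τ 0.4 ms;
surrogate values, as is the activation threshold below). Every substep
reports the exact mass it moved, so the per-step audit closes to
linear-solver round-off (~10⁻¹⁵ relative in practice).

H₂O₂ spans the whole tissue: diffusion (D = 1.83×10⁻⁹ m²/s) with the
cell surface voxels clamped at α_cell·c₀ = 5 nM, α-partitioned initial
conditions, ISF-only advection, and volumetric sources on mitochondrion
voxels: 5.05 µmol·l⁻¹·min⁻¹ in the NORMAL regime, 106 µmol·l⁻¹·min⁻¹
INDUCED. A mitochondrion is INDUCED while the mean glutamate over its
probe region — ISF voxels within two voxels of the host-dendrite
membrane and within 0.65 µm of the mitochondrion — is at or above
`c_glu_thr`. The clamped rows are eliminated and the symmetric
positive-definite system is solved by warm-started Jacobi-preconditioned
conjugate gradients (a direct factorization of the ~10⁵-voxel 3-D
operator is prohibitively fill-heavy).

`c_glu_thr` = 120 µM is a surrogate value chosen once so that a single
simultaneous release at all five synapses activates exactly one
mitochondrion on the reference phantom; paired releases with
t_next = 1.0 ms and 0.5 ms then activate 4 and 5. Problem sizes used
throughout (5 ms horizon, 0.01 ms steps, ~2.2×10⁴ ISF voxels, ~10⁵
tissue voxels) run a full three-scenario comparison in under a minute.

## What the synthetic protocols do and do not show

All inputs are generated by the package itself (there is no external
data): the protocols are *in-silico* reproductions of idealized
experiments. Passing them shows that the implemented mechanisms —
Q-cycle bistability, glutamate drive, MPT rescue, pH/Ca²⁺ modulation,
spillover-switched H₂O₂ production — interact as described, with
magnitudes in physiological ranges. It does not show quantitative
agreement with any particular mitochondrial preparation: the kinetic
constants are calibrated to the qualitative regime structure, not
fitted to rate data, and the spatial spike waveform and activation
threshold are surrogates. Known limitations: no antioxidant systems, no
Ca²⁺/H⁺ antiport or Na⁺/Ca²⁺ exchange (matrix Ca²⁺ is held constant),
complex IV is slaved to complex III, the Δψ-peak signature precedes the
transition only in the slow (pH-driven) protocols — Ca²⁺ runs transition
during the uptake transient without a preceding peak — and the
bifurcation census lacks the Hopf pair discussed above.
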