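"""Reduced kinetic model of the mitochondrial respiratory chain.

The model keeps one lumped rate per respiratory complex and carries the
complex-III dependence on both ubiquinol (QH₂) and ubiquinone (Q) that
makes the chain bistable: the Q-cycle needs QH₂ at the o-site and,
cooperatively, Q at the i-site, so near-complete reduction of the pool
(Q → 0) chokes electron exit while complexes I and II keep reducing
whatever Q remains.  The two attractors are

* an **ATP-producing** state — moderate QH₂, high Δψ and ATP, low
  semiquinone (ROS-proxy) fractions; and
* an **ROS-producing** state — QH₂ close to the pool total, collapsed
  Δψ and ATP, high semiquinone fractions.

Conserved pairs (ATP+ADP, NAD⁺+NADH, Q+QH₂) are eliminated
algebraically: only one member of each pair is integrated and the
partner is reconstructed from the totals, so the conservation sums hold
to machine precision along every trajectory.

See :mod:`mitoswitch.params` for the reaction table (v1…v16) and units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ModelParams
from . import mpt as _mpt
from . import modifiers as _modifiers

__all__ = [
    "RCState",
    "ReactionRates",
    "Trajectory",
    "Regime",
    "NegativeConcentrationError",
    "SteadyStateError",
    "STATE_FIELDS",
    "RATE_NAMES",
    "compute_rates",
    "stoichiometry_matrix",
    "rhs",
    "simulate",
    "find_steady_state",
    "ros_fractions",
    "classify_branch",
    "reference_initial_state",
    "active_indices",
]

# ---------------------------------------------------------------------------
# state container

STATE_FIELDS: Tuple[str, ...] = (
    "qh2", "nadh", "atp", "dpsi",
    "oaa", "akg", "succ", "mal", "glu_m", "asp",
    "ph", "ca_ext", "ext_glu", "ext_mal",
)

_POOL_FIELDS = ("qh2", "nadh", "atp", "oaa", "akg", "succ", "mal",
                "glu_m", "asp", "ca_ext", "ext_glu", "ext_mal")


class NegativeConcentrationError(ValueError):
    """A metabolite pool was negative where a physical state is required."""


class SteadyStateError(RuntimeError):
    """Newton iteration failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class RCState:
    """Dynamical state of the lumped mitochondrion.

    Pools in nmol·mg⁻¹, ``dpsi`` in mV, ``ph`` in pH units, ``ext_glu``
    in mM.  ``ph``/``ca_ext``/``ext_*`` only evolve when the matching
    feature flag is on; otherwise they ride along as constants.
    """

    qh2: float = 0.33
    nadh: float = 0.63
    atp: float = 17.0
    dpsi: float = 137.0
    oaa: float = 0.97
    akg: float = 0.07
    succ: float = 9.0
    mal: float = 0.72
    glu_m: float = 0.04
    asp: float = 0.15
    ph: float = 7.0
    ca_ext: float = 0.0
    ext_glu: float = 0.0
    ext_mal: float = 0.0

    # -- derived pools -------------------------------------------------
    def q(self, params: ModelParams) -> float:
        """Oxidized ubiquinone, Q_tot − QH₂."""
        return params.q_tot - self.qh2

    def adp(self, params: ModelParams) -> float:
        return params.a_tot - self.atp

    def nad(self, params: ModelParams) -> float:
        return params.n_tot - self.nadh

    # -- vector interface ----------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "RCState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, y)})

    def validate(self, params: ModelParams) -> None:
        """Raise :class:`NegativeConcentrationError` naming the first bad field."""
        for f in _POOL_FIELDS:
            v = getattr(self, f)
            if v < -1e-9:   # tolerate integrator-level round-off below zero
                raise NegativeConcentrationError(f"{f} = {v} is negative")
        if not np.isfinite(self.dpsi):
            raise NegativeConcentrationError(f"dpsi = {self.dpsi} is not finite")
        for name, v, tot in (("qh2", self.qh2, params.q_tot),
                             ("atp", self.atp, params.a_tot),
                             ("nadh", self.nadh, params.n_tot)):
            if v > tot * (1 + 1e-9):
                raise NegativeConcentrationError(
                    f"{name} = {v} exceeds its conservation total {tot}")


# ---------------------------------------------------------------------------
# reaction rates

RATE_NAMES: Tuple[str, ...] = (
    "v1", "v2", "v3", "v4", "v5", "v6", "v7", "v8", "v9", "v10",
    "v11", "v12", "v13", "v14", "v15", "v16", "v17", "v18", "v19",
    "v_ca", "mpt_clamp",
    "mpt_oaa", "mpt_akg", "mpt_succ", "mpt_mal", "mpt_glu_m", "mpt_asp",
    "mpt_h",
)
_RI = {n: i for i, n in enumerate(RATE_NAMES)}


@dataclass
class ReactionRates:
    """Named view over the rate vector (nmol·mg⁻¹·s⁻¹) plus the pore open fraction."""

    values: np.ndarray
    pore_open: float = 0.0

    def __getitem__(self, name: str) -> float:
        return float(self.values[_RI[name]])

    def as_dict(self) -> Dict[str, float]:
        return {n: float(v) for n, v in zip(RATE_NAMES, self.values)}


def _sig_dec(x: float, half: float, slope: float) -> float:
    """Decreasing sigmoid: thermodynamic back-pressure on H⁺ pumps."""
    return 1.0 / (1.0 + np.exp(np.clip((x - half) / slope, -500, 500)))


def _sig_inc(x: float, half: float, slope: float) -> float:
    return 1.0 / (1.0 + np.exp(np.clip((half - x) / slope, -500, 500)))


def _rates_vector(y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Rate vector with pools clipped at zero (integrator-safe)."""
    qh2, nadh, atp, dpsi = y[0], y[1], y[2], y[3]
    oaa, akg, succ, mal, glu_m, asp = y[4:10]
    ph, ca_ext, ext_glu = y[10], y[11], y[12]

    clip = lambda v: max(float(v), 0.0)
    qh2 = min(clip(qh2), p.q_tot)
    nadh = min(clip(nadh), p.n_tot)
    atp = min(clip(atp), p.a_tot)
    oaa, akg, succ = clip(oaa), clip(akg), clip(succ)
    mal, glu_m, asp, ca_ext = clip(mal), clip(glu_m), clip(asp), clip(ca_ext)

    q = p.q_tot - qh2
    adp = p.a_tot - atp
    nad = p.n_tot - nadh

    v = np.zeros(len(RATE_NAMES))

    # matrix-H+ effect on the Q-cycle: the i-site quinone must pick up
    # matrix protons, so alkalinization slows complex III
    f_h = 10.0 ** (p.ph.nh_ciii * (7.0 - ph))

    v[_RI["v1"]] = (p.vm1 * nadh / (p.kn1 + nadh) * q / (p.kq1 + q)
                    * _sig_dec(dpsi, p.v1_half, p.v1_slope))
    v[_RI["v2"]] = (p.vm2 * succ / (p.k2s + succ) * q / (p.kq2 + q)
                    / (1.0 + oaa / p.ki_oaa))
    qn = q ** p.nq3
    v[_RI["v3"]] = (p.vm3 * qh2 / (p.ko3 + qh2) * qn / (p.ki3 ** p.nq3 + qn)
                    * _sig_dec(dpsi, p.v3_half, p.v3_slope) * f_h)
    v[_RI["v4"]] = v[_RI["v3"]]          # complex IV at quasi-steady state
    # synthase activation normalized to vanish exactly at dpsi = 0
    # (no ATP synthesis without a proton-motive force)
    s5_0 = _sig_inc(0.0, p.v5_half, p.v5_slope)
    f5 = max(_sig_inc(dpsi, p.v5_half, p.v5_slope) - s5_0, 0.0) / (1.0 - s5_0)
    v[_RI["v5"]] = p.vm5 * adp / (p.k5 + adp) * f5
    v[_RI["v6"]] = p.k_leak * dpsi
    v[_RI["v7"]] = p.vm7 * atp / (p.k7 + atp)
    nad_f = nad / (p.k_nad + nad)
    v[_RI["v8"]] = p.vm8 * glu_m / (p.k8 + glu_m) * nad_f
    v[_RI["v9"]] = p.k9 * glu_m * oaa
    v[_RI["v10"]] = p.vm10 * akg / (p.k10 + akg) * nad_f
    v[_RI["v11"]] = (p.vm11 * mal / (p.k11 + mal) * nad_f
                     / (1.0 + oaa / p.ki_oaa_mdh))
    v[_RI["v12"]] = p.vm12 * oaa / (p.k12 + oaa) * nad_f
    v[_RI["v13"]] = p.k13 * mal
    v[_RI["v14"]] = p.mal_in
    v[_RI["v15"]] = p.k15 * asp
    glu_o = clip(ext_glu) if p.closed_external else p.glu_o
    v[_RI["v16"]] = (p.vm16 * glu_o / (p.kg16 + glu_o) / (1.0 + glu_m / p.kgi16)
                      - p.k16x * glu_m)
    # electron leak to O2 from the ROS-generating semiquinone species
    v[_RI["v17"]] = p.k_ros1 * nadh * nadh / (nadh * nadh + p.kf_ci ** 2)
    v[_RI["v18"]] = p.k_ros3 * qh2 * qh2 / (qh2 * qh2 + p.kf_ciii ** 2)
    v[_RI["v19"]] = p.k19 * succ

    if p.ca_enabled:
        v[_RI["v_ca"]] = _modifiers.ca_uptake_flux(ca_ext, p.ca, dpsi)

    if p.mpt_enabled:
        pore = _mpt.permeability(qh2, p.mpt)
        conc = {"oaa": oaa, "akg": akg, "succ": succ, "mal": mal,
                "glu_m": glu_m, "asp": asp}
        for s in p.mpt.solutes:
            spec = _mpt.EffluxSpec(
                solute=s, z=p.mpt.solute_charge[s],
                c_matrix=conc[s], c_external=p.mpt.c_ext[s],
                k_perm=p.mpt.k_efflux)
            v[_RI[f"mpt_{s}"]] = _mpt.ghk_efflux(spec, pore, dpsi)
        v[_RI["mpt_clamp"]] = _mpt.clamp_conductance(pore, p.mpt) * dpsi
        if p.ph_variable:
            v[_RI["mpt_h"]] = p.mpt.k_h_equil * pore * (ph - p.mpt.ph_cytosol)
    return v


def compute_rates(state: RCState, params: ModelParams) -> ReactionRates:
    """Evaluate every reduced-model reaction rate at ``state``.

    Raises :class:`NegativeConcentrationError` (naming the offending
    field) if the state violates the pool invariants.
    """
    state.validate(params)
    y = state.to_vector()
    vals = _rates_vector(y, params)
    pore = _mpt.permeability(state.qh2, params.mpt) if params.mpt_enabled else 0.0
    return ReactionRates(values=vals, pore_open=pore)


# ---------------------------------------------------------------------------
# stoichiometry and right-hand side

def stoichiometry_matrix(params: ModelParams) -> np.ndarray:
    """Dense stoichiometry map S (states × rates) such that dy/dt = S @ v.

    Charge rows are pre-scaled by 1/C_mem and the pH row by the buffering
    capacity, so the product is already in state units per second.
    """
    p = params
    S = np.zeros((len(STATE_FIELDS), len(RATE_NAMES)))
    si = {f: i for i, f in enumerate(STATE_FIELDS)}

    def put(state_name: str, **contrib: float) -> None:
        for rname, c in contrib.items():
            S[si[state_name], _RI[rname]] += c

    put("qh2", v1=+1, v2=+1, v3=-1, v18=-1)
    put("nadh", v8=+1, v10=+1, v11=+1, v12=+1, v1=-1, v17=-1)
    put("atp", v5=+1, v7=-1)
    put("oaa", v11=+1, v12=-1, v9=-1, mpt_oaa=-1)
    put("akg", v8=+1, v9=+1, v12=+1, v10=-1, mpt_akg=-1)
    put("succ", v10=+1, v2=-1, v19=-1, mpt_succ=-1)
    put("mal", v2=+1, v14=+1, v11=-1, v13=-1, mpt_mal=-1)
    put("glu_m", v16=+1, v8=-1, v9=-1, mpt_glu_m=-1)
    put("asp", v9=+1, v15=-1, mpt_asp=-1)

    # membrane-potential balance: outward charge positive
    cm = 1.0 / p.c_mem
    put("dpsi",
        v1=+p.q_per_v1 * cm, v3=+p.q_per_v3 * cm, v4=+p.q_per_v4 * cm,
        v5=-p.q_per_v5 * cm, v6=-cm, v_ca=-2.0 * cm, mpt_clamp=-cm)
    for s in EFFLUX_ROWS:
        z = p.mpt.solute_charge.get(s, 0.0)
        if z:
            S[si["dpsi"], _RI[f"mpt_{s}"]] -= z * cm

    if p.ph_variable:
        b = 1.0 / p.ph.buffering
        # the open pore is H+-permeant: its charge-dissipating current
        # returns protons to the matrix, so pumping during the MPT does
        # not alkalinize without bound
        put("ph",
            v1=+p.ph.h_per_v1 * b, v3=+p.ph.h_per_v3 * b,
            v5=-p.ph.h_per_v5 * b, v6=-p.ph.h_per_leak * b,
            v_ca=+p.ca.h_per_ca * 2.0 * b,
            mpt_clamp=-b,
            mpt_h=-1.0)
    if p.ca_enabled:
        put("ca_ext", v_ca=-1)
    if p.closed_external:
        conv = p.mg_protein_per_l * 1e-6 / p.bath_volume_ratio  # nmol/mg -> mM
        put("ext_glu", v16=-conv)
        put("ext_mal", mpt_mal=+1.0 / p.bath_volume_ratio,
            v13=+1.0 / p.bath_volume_ratio)
    return S


EFFLUX_ROWS = ("oaa", "akg", "succ", "mal", "glu_m", "asp")


def _rhs_vector(t: float, y: np.ndarray, p: ModelParams, S: np.ndarray) -> np.ndarray:
    return S @ _rates_vector(y, p)


def rhs(state: RCState, params: ModelParams, t: float = 0.0) -> np.ndarray:
    """Time derivative of the state vector (conserved pools eliminated).

    Raises ``FloatingPointError`` naming the offending reaction if any
    rate is non-finite.
    """
    state.validate(params)
    v = _rates_vector(state.to_vector(), params)
    bad = ~np.isfinite(v)
    if bad.any():
        names = [RATE_NAMES[i] for i in np.where(bad)[0]]
        raise FloatingPointError(f"non-finite reaction rate(s): {names}")
    return stoichiometry_matrix(params) @ v


# ---------------------------------------------------------------------------
# simulation

@dataclass
class Trajectory:
    """Time-ordered solution of the reduced model.

    ``times`` (s) and ``states`` (len × n_state) concatenate all event
    segments; ``segments`` records (start index, params) so rates can be
    re-evaluated with the parameters that were active at each point.
    """

    times: np.ndarray
    states: np.ndarray
    segments: List[Tuple[int, ModelParams]]

    @property
    def final_state(self) -> RCState:
        return RCState.from_vector(self.states[-1])

    def state_at(self, i: int) -> RCState:
        return RCState.from_vector(self.states[i])

    def params_at(self, i: int) -> ModelParams:
        p = self.segments[0][1]
        for start, sp in self.segments:
            if i >= start:
                p = sp
        return p

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    def to_frame(self):
        """Tidy table: time, every state, every rate, regime label."""
        import pandas as pd

        rows = np.array([_rates_vector(self.states[i], self.params_at(i))
                         for i in range(len(self.times))])
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        for j, rn in enumerate(RATE_NAMES):
            df[rn] = rows[:, j]
        df["regime"] = [classify_branch(self.state_at(i), self.params_at(i)).value
                        for i in range(len(self.times))]
        return df


def simulate(
    initial: RCState,
    params: ModelParams,
    t_span: Tuple[float, float],
    tol: Optional[Tuple[float, float]] = None,
    events: Optional[Iterable[Tuple[float, Dict[str, float]]]] = None,
    n_out: int = 600,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the model over ``t_span`` with optional mid-run parameter events.

    ``events`` is an iterable of ``(t_event, {field: value})`` updates;
    integration is segmented at each event time (no interpolation
    through the discontinuity).  Default tolerances are rtol 1e-8 /
    atol 1e-10 with a stiff (BDF) solver.

    A zero-length ``t_span`` returns the initial state unchanged.
    """
    initial.validate(params)
    rtol, atol = tol if tol is not None else (1e-8, 1e-10)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 == t0:
        return Trajectory(times=np.array([t0]),
                          states=initial.to_vector()[None, :],
                          segments=[(0, params)])
    if t1 < t0:
        raise ValueError("t_span must be non-decreasing")

    ev = sorted(events) if events else []
    for te, _ in ev:
        if not (t0 < te < t1):
            raise ValueError(f"event time {te} outside t_span {t_span}")

    breaks = [t0] + [te for te, _ in ev] + [t1]
    all_t: List[np.ndarray] = []
    all_y: List[np.ndarray] = []
    segments: List[Tuple[int, ModelParams]] = []
    y = initial.to_vector()
    p = params
    n_total = 0
    for k in range(len(breaks) - 1):
        if k > 0:
            p = p.with_updates(**ev[k - 1][1])
        S = stoichiometry_matrix(p)
        a, b = breaks[k], breaks[k + 1]
        n_seg = max(int(round(n_out * (b - a) / (t1 - t0))), 2)
        t_eval = np.linspace(a, b, n_seg)
        sol = solve_ivp(_rhs_vector, (a, b), y, method=method,
                        t_eval=t_eval, args=(p, S), rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{a}, {b}]: {sol.message}")
        segments.append((n_total, p))
        all_t.append(sol.t)
        all_y.append(sol.y.T)
        n_total += len(sol.t)
        y = sol.y[:, -1].copy()
    return Trajectory(times=np.concatenate(all_t),
                      states=np.vstack(all_y),
                      segments=segments)


# ---------------------------------------------------------------------------
# steady states, stability, regimes

def active_indices(params: ModelParams) -> np.ndarray:
    """Indices of state-vector entries that actually evolve under the flags."""
    idx = list(range(10))
    if params.ph_variable:
        idx.append(STATE_FIELDS.index("ph"))
    if params.ca_enabled:
        idx.append(STATE_FIELDS.index("ca_ext"))
    if params.closed_external:
        idx.append(STATE_FIELDS.index("ext_glu"))
        idx.append(STATE_FIELDS.index("ext_mal"))
    return np.array(idx, dtype=int)


def jacobian(y: np.ndarray, params: ModelParams,
             idx: Optional[np.ndarray] = None) -> np.ndarray:
    """Central finite-difference Jacobian of the active subsystem.

    Step per coordinate: ``max(1e-7, 1e-7·|x|)``.
    """
    if idx is None:
        idx = active_indices(params)
    S = stoichiometry_matrix(params)
    n = len(idx)
    J = np.zeros((n, n))
    for col, j in enumerate(idx):
        h = max(1e-7, 1e-7 * abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        fp = (S @ _rates_vector(yp, params))[idx]
        fm = (S @ _rates_vector(ym, params))[idx]
        J[:, col] = (fp - fm) / (2 * h)
    return J


def find_steady_state(
    guess: RCState,
    params: ModelParams,
    tol: float = 1e-9,
) -> Tuple[RCState, np.ndarray, bool]:
    """Newton-solve ‖rhs‖ → 0 from ``guess``; return (state, eigenvalues, stable).

    Stability is judged from the real parts of the Jacobian spectrum of
    the reduced (pool-eliminated) active subsystem.  Raises
    :class:`SteadyStateError` with the residual norm on failure.
    """
    guess.validate(params)
    idx = active_indices(params)
    y_full = guess.to_vector()
    S = stoichiometry_matrix(params)

    # bring all residual rows to comparable (flux-like) magnitude: the
    # dpsi row is pre-scaled by 1/C_mem and the pH row by 1/buffering
    w = np.ones(len(STATE_FIELDS))
    w[STATE_FIELDS.index("dpsi")] = params.c_mem
    w[STATE_FIELDS.index("ph")] = params.ph.buffering
    w = w[idx]

    def f(x: np.ndarray) -> np.ndarray:
        y = y_full.copy()
        y[idx] = x
        return (S @ _rates_vector(y, params))[idx] * w

    sol = root(f, y_full[idx], method="hybr", tol=tol)
    if not sol.success:
        sol = root(f, y_full[idx], method="lm", tol=tol)
    res = float(np.linalg.norm(f(sol.x)))
    if not sol.success or res > max(1e-7, tol * 100):
        raise SteadyStateError(
            f"steady-state search did not converge: {sol.message} "
            f"(residual norm {res:.3e})", res)
    y_ss = y_full.copy()
    y_ss[idx] = sol.x
    eig = np.linalg.eigvals(jacobian(y_ss, params, idx))
    stable = bool(np.max(eig.real) < 1e-8)
    return RCState.from_vector(y_ss), eig, stable


def ros_fractions(state: RCState, params: ModelParams) -> Tuple[float, float, float]:
    """Semiquinone (ROS-generating species) fractions (f_CI, f_CIII, f_CII).

    Each is a saturating Hill function of the reduction level of the
    pool feeding the complex (NADH for the complex-I flavin radical, QH₂
    for the complex-III semiubiquinone and complex-II FAD radical), so
    each lies in [0, 1], vanishes for fully oxidized pools, and is
    monotone non-decreasing in its feeding pool.
    """
    state.validate(params)

    def hill2(x: float, k: float) -> float:
        x = max(x, 0.0)
        return x * x / (x * x + k * k)

    return (hill2(state.nadh, params.kf_ci),
            hill2(state.qh2, params.kf_ciii),
            hill2(state.qh2, params.kf_cii))


class Regime(enum.Enum):
    ATP_PRODUCING = "ATP_PRODUCING"
    ROS_PRODUCING = "ROS_PRODUCING"
    UNRESOLVED = "UNRESOLVED"


def classify_branch(state: RCState, params: ModelParams) -> Regime:
    """Deterministic regime label for a (near-)steady state.

    ATP-producing requires QH₂ below the switching threshold (with a
    relative dead-band ``classify_margin``) and Δψ above ``dpsi_floor``;
    ROS-producing is the mirror image; anything in the corridor between
    the two is flagged UNRESOLVED rather than guessed.
    """
    m = params.classify_margin
    lo = params.mpt.qthr * (1 - m)
    hi = params.mpt.qthr * (1 + m)
    if state.qh2 <= lo and state.dpsi > params.dpsi_floor:
        return Regime.ATP_PRODUCING
    if state.qh2 >= hi and state.dpsi < params.dpsi_floor:
        return Regime.ROS_PRODUCING
    return Regime.UNRESOLVED


def reference_initial_state(params: Optional[ModelParams] = None) -> RCState:
    """The calibrated ATP-producing reference initial condition."""
    p = params or ModelParams()
    st = RCState()
    st.ph = p.ph.ph_init
    st.ca_ext = p.ca.ca_ext_init if p.ca_enabled else 0.0
    if p.closed_external:
        st.ext_glu = p.glu_o
    return st
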