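"""Steady-state continuation and bifurcation detection.

Two complementary routes for the reduced model:

* :func:`ivp_sweep` — repeatedly solve the initial value problem while
  stepping a parameter up and then down, seeding each solve with the
  previous steady state.  Finds the *stable* branches and exposes
  hysteresis as disagreement between the two legs.
* :func:`continue_branch` — pseudo-arclength continuation with a secant
  predictor and Newton corrector.  Rounds limit points (folds) and so
  recovers the unstable segment connecting the stable sheets.

The arclength machinery itself (:class:`ArclengthSystem`,
:func:`continue_curve`, :func:`detect_on_curve`) is generic over any
residual ``f(x, p)`` — it is exercised directly on analytic normal
forms in the test suite — and :func:`detect_bifurcations` classifies
limit points (parameter direction of the tangent reverses while a real
eigenvalue crosses zero) and Hopf points (a complex-conjugate pair
crosses the imaginary axis, refined by bracketed bisection in
arclength).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams
from .core_model import (
    RCState, STATE_FIELDS, SteadyStateError, active_indices,
    find_steady_state, jacobian, simulate, stoichiometry_matrix,
    _rates_vector,
)

__all__ = ["BranchPoint", "Branch", "BifPoint", "ivp_sweep",
           "continue_branch", "detect_bifurcations", "qthr_from_limit_point",
           "ArclengthSystem", "continue_curve", "detect_on_curve",
           "CurvePoint"]


# ---------------------------------------------------------------------------
# generic pseudo-arclength core

@dataclass
class CurvePoint:
    param: float
    x: np.ndarray
    eigvals: np.ndarray

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigvals.real) < 1e-8)


class ArclengthSystem:
    """Scaled extended system F(x, p) = 0 for arclength continuation.

    ``f(x, p)`` is any smooth residual; Jacobians are central finite
    differences with step ``max(1e-7, 1e-7·|x|)`` per coordinate.
    """

    def __init__(self, f: Callable[[np.ndarray, float], np.ndarray],
                 n: int, x_scale: Optional[np.ndarray] = None,
                 p_scale: float = 1.0):
        self.f = f
        self.n = n
        self.x_scale = np.ones(n) if x_scale is None else np.asarray(x_scale, float)
        self.p_scale = float(p_scale)

    def jac(self, x: np.ndarray, pval: float) -> Tuple[np.ndarray, np.ndarray]:
        n = self.n
        J = np.zeros((n, n))
        for c in range(n):
            h = max(1e-7, 1e-7 * abs(x[c]))
            xp, xm = x.copy(), x.copy()
            xp[c] += h
            xm[c] -= h
            J[:, c] = (self.f(xp, pval) - self.f(xm, pval)) / (2 * h)
        hp = max(1e-9, 1e-6 * abs(pval))
        fp = (self.f(x, pval + hp) - self.f(x, pval - hp)) / (2 * hp)
        return J, fp

    def eigs(self, x: np.ndarray, pval: float) -> np.ndarray:
        J, _ = self.jac(x, pval)
        return np.linalg.eigvals(J)

    # -- scaled coordinates ----------------------------------------------
    def to_z(self, x: np.ndarray, pval: float) -> np.ndarray:
        return np.concatenate([x / self.x_scale, [pval / self.p_scale]])

    def from_z(self, z: np.ndarray) -> Tuple[np.ndarray, float]:
        return z[:-1] * self.x_scale, float(z[-1] * self.p_scale)

    def correct(self, z_pred: np.ndarray, tangent: np.ndarray,
                tol: float = 1e-10, max_iter: int = 12):
        """Newton-correct ``z`` in the hyperplane orthogonal to ``tangent``."""
        z = z_pred.copy()
        for _ in range(max_iter):
            x, pv = self.from_z(z)
            r = self.f(x, pv)
            g = float(tangent @ (z - z_pred))
            if np.linalg.norm(r) < tol and abs(g) < 1e-12:
                return z, True
            J, fp = self.jac(x, pv)
            A = np.zeros((self.n + 1, self.n + 1))
            A[:self.n, :self.n] = J * self.x_scale[None, :]
            A[:self.n, -1] = fp * self.p_scale
            A[-1, :] = tangent
            try:
                dz = np.linalg.solve(A, np.concatenate([-r, [-g]]))
            except np.linalg.LinAlgError:
                return z, False
            z = z + dz
            if not np.all(np.isfinite(z)):
                return z, False
        x, pv = self.from_z(z)
        return z, bool(np.linalg.norm(self.f(x, pv)) < 1e-8)


def continue_curve(
    sys: ArclengthSystem,
    x0: np.ndarray,
    p0: float,
    p_range: Tuple[float, float],
    ds: float = 0.02,
    ds_min: float = 1e-7,
    ds_max: float = 0.08,
    max_steps: int = 400,
    direction: int = +1,
) -> List[CurvePoint]:
    """Follow the solution curve of ``f(x, p) = 0`` from ``(x0, p0)``.

    Secant predictor, Newton corrector orthogonal to the tangent, step
    halved on corrector failure (stopping with the last verified point
    once it underflows ``ds_min``), grown gently on success.  Folds are
    rounded.
    """
    z = sys.to_z(np.asarray(x0, float), p0)
    pts = [CurvePoint(p0, np.asarray(x0, float).copy(), sys.eigs(x0, p0))]

    J, fp = sys.jac(np.asarray(x0, float), p0)
    try:
        dxdp = np.linalg.solve(J, -fp)
    except np.linalg.LinAlgError:
        dxdp = np.zeros(sys.n)
    tangent = np.concatenate([dxdp / sys.x_scale * sys.p_scale, [1.0]])
    tangent = tangent / np.linalg.norm(tangent)
    if direction < 0:
        tangent = -tangent

    lo, hi = min(p_range), max(p_range)
    step = ds
    fails = 0
    while len(pts) < max_steps:
        z_pred = z + step * tangent
        z_new, ok = sys.correct(z_pred, tangent)
        if ok:
            xv, p_new = sys.from_z(z_new)
            if not (lo - 1e-12 <= p_new <= hi + 1e-12):
                break
            dz = z_new - z
            ndz = np.linalg.norm(dz)
            if ndz > 0:
                tangent = dz / ndz          # secant predictor
            z = z_new
            pts.append(CurvePoint(p_new, xv.copy(), sys.eigs(xv, p_new)))
            step = min(step * 1.3, ds_max)
            fails = 0
        else:
            step *= 0.5
            fails += 1
            if step < ds_min or fails > 60:
                break
    return pts


def _hopf_test(eig: np.ndarray) -> float:
    """Real part of the least-damped complex pair (−inf if none)."""
    cplx = eig[np.abs(eig.imag) > 1e-9]
    if len(cplx) == 0:
        return -np.inf
    return float(np.max(cplx.real))


def _real_test(eig: np.ndarray) -> float:
    """Smallest-magnitude real eigenvalue (signed; nan if none)."""
    re = eig.real[np.abs(eig.imag) < 1e-9]
    if len(re) == 0:
        return np.nan
    return float(re[np.argmin(np.abs(re))])


def detect_on_curve(sys: ArclengthSystem, pts: Sequence[CurvePoint],
                    refine_tol: float = 1e-5) -> List[Tuple[str, float, np.ndarray, float]]:
    """Locate limit points and Hopf points along a continued curve.

    Returns ``(kind, param, x, test_residual)`` tuples.  Hopf points are
    refined by bisection in arclength with the steady state re-corrected
    at every trial point; limit points are reported at the turning point
    with its near-zero real eigenvalue as the residual.
    """
    out: List[Tuple[str, float, np.ndarray, float]] = []
    if len(pts) < 3:
        return out

    def refine(z1: np.ndarray, z2: np.ndarray, test):
        f1 = test(sys.eigs(*sys.from_z(z1)))
        for _ in range(40):
            t = z2 - z1
            nt = np.linalg.norm(t)
            if nt < 1e-13:
                break
            zm, ok = sys.correct(0.5 * (z1 + z2), t / nt)
            if not ok:
                zm = 0.5 * (z1 + z2)
            fm = test(sys.eigs(*sys.from_z(zm)))
            if np.sign(fm) == np.sign(f1):
                z1, f1 = zm, fm
            else:
                z2 = zm
            _, pa = sys.from_z(z1)
            _, pb = sys.from_z(z2)
            if abs(pb - pa) <= refine_tol * max(1.0, abs(pa)):
                break
        zb = 0.5 * (z1 + z2)
        t = z2 - z1
        nt = np.linalg.norm(t)
        if nt > 0:
            zb, _ = sys.correct(zb, t / nt)
        return zb

    for i in range(1, len(pts)):
        a, b = pts[i - 1], pts[i]
        ha, hb = _hopf_test(a.eigvals), _hopf_test(b.eigvals)
        if np.isfinite(ha) and np.isfinite(hb) and ha * hb < 0:
            zh = refine(sys.to_z(a.x, a.param), sys.to_z(b.x, b.param),
                        _hopf_test)
            xv, ph = sys.from_z(zh)
            out.append(("HOPF", ph, xv, abs(_hopf_test(sys.eigs(xv, ph)))))
    for i in range(1, len(pts) - 1):
        dp1 = pts[i].param - pts[i - 1].param
        dp2 = pts[i + 1].param - pts[i].param
        if dp1 * dp2 < 0:
            e_here = _real_test(pts[i].eigvals)
            res = abs(e_here) if np.isfinite(e_here) else np.inf
            out.append(("LIMIT_POINT", pts[i].param, pts[i].x.copy(), res))

    out.sort(key=lambda t_: t_[1])
    dedup: List[Tuple[str, float, np.ndarray, float]] = []
    for item in out:
        if any(item[0] == q[0] and abs(item[1] - q[1]) <=
               10 * refine_tol * max(1.0, abs(q[1])) for q in dedup):
            continue
        dedup.append(item)
    return dedup


# ---------------------------------------------------------------------------
# model-facing containers

@dataclass
class BranchPoint:
    param: float
    state: RCState
    eigvals: np.ndarray
    stable: bool


@dataclass
class Branch:
    """Ordered steady states of the reduced model along one parameter."""

    param_name: str
    points: List[BranchPoint]
    method: str                      # "ivp_up" | "ivp_down" | "arclength"
    excluded: List[Tuple[float, str]] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    def column(self, name: str) -> np.ndarray:
        i = STATE_FIELDS.index(name)
        return np.array([pt.state.to_vector()[i] for pt in self.points])

    def to_frame(self):
        import pandas as pd
        rows = []
        for pt in self.points:
            d = {self.param_name: pt.param}
            d.update({f: getattr(pt.state, f) for f in STATE_FIELDS})
            d["max_re_eig"] = float(np.max(pt.eigvals.real))
            d["stable"] = pt.stable
            rows.append(d)
        return pd.DataFrame(rows)


@dataclass
class BifPoint:
    kind: str                       # "LIMIT_POINT" | "HOPF" | "UNCLASSIFIED"
    param: float
    state: RCState
    test_residual: float


def _model_system(params: ModelParams, param_name: str,
                  template: np.ndarray) -> Tuple[ArclengthSystem, np.ndarray]:
    """Bind the reduced model into an :class:`ArclengthSystem`."""
    idx = active_indices(params)
    w = np.ones(len(STATE_FIELDS))
    w[STATE_FIELDS.index("dpsi")] = params.c_mem
    w[STATE_FIELDS.index("ph")] = params.ph.buffering
    w = w[idx]

    def f(x: np.ndarray, pval: float) -> np.ndarray:
        y = template.copy()
        y[idx] = x
        p = params.with_updates(**{param_name: float(pval)})
        return (stoichiometry_matrix(p) @ _rates_vector(y, p))[idx] * w

    xs = np.maximum(np.abs(template[idx]), 1.0)
    xs[np.where(idx == STATE_FIELDS.index("dpsi"))[0]] = 100.0
    p0 = float(getattr(params, param_name))
    sys = ArclengthSystem(f, len(idx), x_scale=xs,
                          p_scale=max(abs(p0), 1e-2))
    return sys, idx


def _to_state(template: np.ndarray, idx: np.ndarray, x: np.ndarray) -> RCState:
    y = template.copy()
    y[idx] = x
    return RCState.from_vector(y)


def continue_branch(
    seed: RCState,
    params: ModelParams,
    param_name: str,
    p_range: Tuple[float, float],
    ds: float = 0.02,
    ds_min: float = 1e-7,
    ds_max: float = 0.08,
    max_steps: int = 400,
    direction: int = +1,
) -> Branch:
    """Pseudo-arclength continuation of a steady-state branch of the model.

    ``seed`` must be a steady state of ``params`` (it is Newton-polished
    first).  The returned branch rounds folds and includes the unstable
    segment.  Note the eigenvalues used for stability are those of the
    reduced (pool-eliminated) system with the model's *scaled* residual;
    their signs — all that stability and the bifurcation tests use —
    agree with the unscaled Jacobian spectrum.
    """
    ss, _, _ = find_steady_state(seed, params)
    template = ss.to_vector()
    sys, idx = _model_system(params, param_name, template)
    p0 = float(getattr(params, param_name))
    pts = continue_curve(sys, template[idx], p0, p_range, ds=ds,
                         ds_min=ds_min, ds_max=ds_max, max_steps=max_steps,
                         direction=direction)
    br = Branch(param_name=param_name, points=[], method="arclength")
    for cp in pts:
        # report true (unscaled) Jacobian eigenvalues for each point
        y = template.copy()
        y[idx] = cp.x
        p = params.with_updates(**{param_name: cp.param})
        ev = np.linalg.eigvals(jacobian(y, p, idx))
        br.points.append(BranchPoint(cp.param, _to_state(template, idx, cp.x),
                                     ev, bool(np.max(ev.real) < 1e-8)))
    return br


def detect_bifurcations(
    branch: Branch,
    params: ModelParams,
    refine_tol: float = 1e-5,
) -> List[BifPoint]:
    """Classify limit points and Hopf points along a continued model branch."""
    if len(branch.points) < 3:
        return []
    template = branch.points[0].state.to_vector()
    sys, idx = _model_system(params, branch.param_name, template)
    pts = [CurvePoint(pt.param, pt.state.to_vector()[idx], pt.eigvals)
           for pt in branch.points]
    found = detect_on_curve(sys, pts, refine_tol=refine_tol)
    return [BifPoint(kind, pv, _to_state(template, idx, xv), res)
            for kind, pv, xv, res in found]


# ---------------------------------------------------------------------------
# IVP sweeps

def _weighted_residual(y: np.ndarray, p: ModelParams) -> float:
    S = stoichiometry_matrix(p)
    d = S @ _rates_vector(y, p)
    d[STATE_FIELDS.index("dpsi")] *= p.c_mem
    d[STATE_FIELDS.index("ph")] *= p.ph.buffering
    return float(np.linalg.norm(d[active_indices(p)]))


def _settle(state: RCState, p: ModelParams, settle_tol: float,
            t_chunk: float, t_cap: float):
    """Integrate until ‖rhs‖ < tol or the time cap; detect oscillations.

    Returns ``(state, status)`` with status in {steady, oscillatory, slow}.
    """
    t = 0.0
    st = state
    while t < t_cap:
        tr = simulate(st, p, (0.0, t_chunk), n_out=200)
        st = tr.final_state
        t += t_chunk
        if _weighted_residual(st.to_vector(), p) < settle_tol:
            return st, "steady"
        q = tr.column("qh2")
        interior_max = (q[1:-1] > q[:-2]) & (q[1:-1] > q[2:])
        n_peaks = int(np.sum(interior_max & (q[1:-1] - q.min() > 1e-4)))
        if n_peaks >= 3 and q.max() - q.min() > 1e-3:
            return st, "oscillatory"
    return st, "slow"


def ivp_sweep(
    params: ModelParams,
    param_name: str,
    values_up_then_down: Sequence[float] | Tuple[Sequence[float], Sequence[float]],
    initial: Optional[RCState] = None,
    settle_tol: float = 1e-8,
    t_chunk: float = 200.0,
    t_cap: float = 3000.0,
) -> Tuple[Branch, Branch]:
    """Stable-branch continuation by repeated initial value problems.

    The parameter is stepped through the up leg and then the down leg;
    each solve starts from the previous steady state, so each leg tracks
    its attractor until that attractor disappears and the trajectory
    falls onto the other branch — the hysteresis loop.  Non-settling
    (oscillatory or too-slow) points are excluded from the branch and
    recorded in ``Branch.excluded``.
    """
    if isinstance(values_up_then_down, tuple) and len(values_up_then_down) == 2:
        up_vals = np.asarray(values_up_then_down[0], dtype=float)
        down_vals = np.asarray(values_up_then_down[1], dtype=float)
    else:
        vals = np.asarray(values_up_then_down, dtype=float)
        k = int(np.argmax(vals))
        up_vals, down_vals = vals[:k + 1], vals[k + 1:]
    for leg, nm in ((up_vals, "up"), (down_vals, "down")):
        if len(leg) > 1 and not (np.all(np.diff(leg) > 0) or np.all(np.diff(leg) < 0)):
            raise ValueError(f"{nm} leg of the sweep is not strictly monotone")

    st = initial if initial is not None else RCState()
    branches = []
    for leg_vals, nm in ((up_vals, "ivp_up"), (down_vals, "ivp_down")):
        br = Branch(param_name=param_name, points=[], method=nm)
        for val in leg_vals:
            p = params.with_updates(**{param_name: float(val)})
            st, status = _settle(st, p, settle_tol, t_chunk, t_cap)
            if status != "steady":
                br.excluded.append((float(val), status))
                continue
            try:
                ss, eig, stable = find_steady_state(st, p)
                st = ss
            except SteadyStateError:
                br.excluded.append((float(val), "newton_failed"))
                continue
            br.points.append(BranchPoint(float(val), ss, eig, stable))
        branches.append(br)
    return branches[0], branches[1]


def qthr_from_limit_point(params: ModelParams, seed: Optional[RCState] = None,
                          p_range: Tuple[float, float] = (0.001, 0.25)) -> float:
    """Recompute the MPT threshold as the ubiquinol level at the limit
    point of the glutamate continuation (its defining property: the
    largest QH₂ compatible with an ATP-producing steady state).

    The shipped default in :class:`~mitoswitch.params.MPTParams` was
    produced this way; use this helper after changing kinetic constants.
    """
    if seed is None:
        from .core_model import reference_initial_state
        tr = simulate(reference_initial_state(params),
                      params.with_updates(glu_o=0.01), (0.0, 600.0), n_out=60)
        seed = tr.final_state
    p01 = params.with_updates(glu_o=0.01)
    br = continue_branch(seed, p01, "glu_o", p_range,
                         ds=0.02, ds_max=0.06, max_steps=450)
    lps = [b for b in detect_bifurcations(br, p01) if b.kind == "LIMIT_POINT"]
    if not lps:
        raise RuntimeError("no limit point found on the continued branch")
    return float(lps[0].state.qh2)
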