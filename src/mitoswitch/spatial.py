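"""Convection–reaction–diffusion of glutamate and H₂O₂ on the voxel phantom.

Glutamate is released as concentration spikes on the synaptic contact
patches (Dirichlet boundary), spreads through the interstitial fluid
(ISF) by diffusion and slow convection, and is cleared by
Michaelis–Menten EAAT uptake on astrocyte and neuron membranes.  Each
mitochondrion watches the mean glutamate over a probe region of ISF
just outside its host dendrite's membrane: above the threshold
``c_glu_thr`` the mitochondrion switches from the NORMAL to the INDUCED
H₂O₂ production rate.  H₂O₂ diffuses over the whole tissue volume with
volumetric sources on mitochondrion voxels and the cell surfaces
clamped at their baseline partition level.

Numerics: finite volumes on the voxel grid; diffusion backward-Euler
(unconditionally stable, one sparse LU per solver); advection explicit
first-order upwind along +Y with a CFL guard; nonlinear surface uptake
as a positivity-preserving per-voxel implicit substep.  Every substep
reports the exact mass it moved, so the per-step mass audit closes to
linear-solver round-off.

Units: µm, ms, µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import sparse
from scipy.sparse.linalg import splu, cg

from .phantom import Phantom, LABELS, MITO_BASE

__all__ = ["SpatialParams", "FieldState", "ReleaseSchedule",
           "GlutamateSolver", "H2O2Solver", "eaat_boundary_flux",
           "run_release_scenario", "SpatialResult", "write_vtk"]


class SpatialParams(BaseModel):
    """Transport, uptake and source parameters.

    Stored in SI-flavored units as usually tabulated; converted to the
    solver's µm/ms/µM system internally.
    """

    model_config = ConfigDict(extra="forbid")

    d_glu: float = Field(1.29e-6, gt=0, description="glutamate diffusivity, cm^2/s")
    d_h2o2: float = Field(1.83e-9, gt=0, description="H2O2 diffusivity, m^2/s")
    u_convection: float = Field(5e-7, ge=0, description="ISF convection speed along +Y, m/s")
    c_glu_isf: float = Field(1.0, ge=0, description="ambient ISF glutamate, µM")
    c_eaat_ast: float = Field(1.25e-8, ge=0, description="astrocyte EAAT surface density, mol/m^2")
    c_eaat_neu: float = Field(1.25e-9, ge=0, description="neuron EAAT surface density, mol/m^2")
    tau_turnover: float = Field(41.0, gt=0, description="EAAT turnover rate, 1/s")
    km_eaat: float = Field(12.0, gt=0, description="EAAT Michaelis constant, µM")
    c_h2o2_0: float = Field(0.01, ge=0, description="baseline H2O2, µM (10 nM)")
    alpha_isf: float = Field(0.3, gt=0, le=1)
    alpha_mit: float = Field(1.0, gt=0, le=1)
    alpha_cell: float = Field(0.5, gt=0, le=1)
    j_normal: float = Field(5.05, ge=0, description="H2O2 source in NORMAL regime, µmol/l/min")
    j_induced: float = Field(106.0, ge=0, description="H2O2 source in INDUCED regime, µmol/l/min")
    c_glu_thr: float = Field(120.0, gt=0, description="probe-region glutamate threshold for the INDUCED regime, µM (surrogate value: calibrated so a single simultaneous release activates one mitochondrion on the reference phantom)")
    spike_peak_small: float = Field(1000.0, ge=0, description="peak spike concentration at small synapses, µM (surrogate)")
    spike_peak_large: float = Field(2000.0, ge=0, description="peak spike concentration at large synapses, µM (surrogate)")
    spike_tau: float = Field(0.4, gt=0, description="spike decay time constant, ms (surrogate)")
    dt: float = Field(0.01, gt=0, description="time step, ms")

    # ---- converted views -------------------------------------------------
    @property
    def D_glu(self) -> float:
        """µm²/ms"""
        return self.d_glu * 1e8 / 1e3     # cm²/s → µm²/s → µm²/ms

    @property
    def D_h2o2(self) -> float:
        return self.d_h2o2 * 1e12 / 1e3   # m²/s → µm²/ms

    @property
    def u(self) -> float:
        """µm/ms along +Y"""
        return self.u_convection * 1e6 / 1e3

    def eaat_vmax(self, membrane: str) -> float:
        """Saturating EAAT flux, µM·µm/ms (surface flux per unit area)."""
        dens = {"AST": self.c_eaat_ast, "NEU": self.c_eaat_neu}[membrane]
        # mol/m²/s → µM·µm/ms  (1 mol/m²/s = 1e6 µM·µm/ms)
        return dens * self.tau_turnover * 1e6

    def source_rate(self, induced: bool) -> float:
        """Volumetric H2O2 source, µM/ms."""
        j = self.j_induced if induced else self.j_normal
        return j / 60.0 / 1e3             # µM/min → µM/ms


def eaat_boundary_flux(c_glu_surface: float, membrane: str,
                       p: SpatialParams) -> float:
    """EAAT uptake flux at a membrane point, mol·m⁻²·s⁻¹.

    Michaelis–Menten in the local surface concentration; the astrocyte
    flux exceeds the neuron flux 10-fold at equal concentration (the
    surface-density ratio).
    """
    if c_glu_surface < 0:
        raise ValueError(f"negative surface concentration {c_glu_surface}")
    dens = {"AST": p.c_eaat_ast, "NEU": p.c_eaat_neu}[membrane]
    return dens * p.tau_turnover * c_glu_surface / (p.km_eaat + c_glu_surface)


@dataclass
class ReleaseSchedule:
    """Vesicle release times (ms) applied at every synapse of each class."""

    times_small: Tuple[float, ...] = (0.0,)
    times_large: Tuple[float, ...] = (0.0,)

    @classmethod
    def single(cls) -> "ReleaseSchedule":
        return cls((0.0,), (0.0,))

    @classmethod
    def double(cls, t_next: float) -> "ReleaseSchedule":
        """The paired-release condition: a second vesicle after ``t_next`` ms."""
        return cls((0.0, t_next), (0.0, t_next))

    @classmethod
    def none(cls) -> "ReleaseSchedule":
        return cls((), ())

    def spike(self, t: float, kind: str, p: SpatialParams) -> float:
        """Superposed spike concentration at time ``t`` (instantaneous rise,
        exponential decay)."""
        peak = (p.spike_peak_small if kind == "SYNAPSE_SMALL"
                else p.spike_peak_large)
        times = self.times_small if kind == "SYNAPSE_SMALL" else self.times_large
        c = 0.0
        for t0 in times:
            if t >= t0:
                c += peak * np.exp(-(t - t0) / p.spike_tau)
        return c


@dataclass
class FieldState:
    """Concentration fields plus per-mitochondrion regime flags."""

    c_glu: np.ndarray              # µM, per ISF voxel (flat)
    c_h2o2: np.ndarray             # µM, per domain voxel (flat)
    induced: np.ndarray            # bool, per mitochondrion (instantaneous)
    ever_induced: np.ndarray       # bool, latched
    t: float = 0.0                 # ms


# ---------------------------------------------------------------------------
# glutamate solver (ISF only)

class GlutamateSolver:
    """Backward-Euler diffusion + upwind advection + EAAT uptake on the ISF."""

    def __init__(self, phantom: Phantom, params: SpatialParams,
                 sealed: bool = False):
        self.ph = phantom
        self.p = params
        self.sealed = sealed      # diagnostic mode: pure diffusion, all
        #                           boundaries closed (no BC, no uptake)
        h = phantom.voxel
        self.h = h
        lab = phantom.labels
        isf = phantom.mask("ISF")
        self.isf_index = -np.ones(lab.shape, dtype=np.int64)
        self.vox = np.argwhere(isf)
        self.n = len(self.vox)
        self.isf_index[isf] = np.arange(self.n)

        if params.u * params.dt / h >= 1.0:
            raise ValueError(
                f"advective CFL violated: u*dt/h = {params.u * params.dt / h:.3f} >= 1")

        self._build_faces(lab, isf)
        self._build_matrix()
        self._probe_idx = [self.isf_index[r[:, 0], r[:, 1], r[:, 2]]
                           for r in phantom.probe_regions]
        self._probe_idx = [ix[ix >= 0] for ix in self._probe_idx]

    # -- topology ---------------------------------------------------------
    def _build_faces(self, lab, isf):
        ph = self.ph
        nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

        # synapse membership per ISF voxel
        syn_count = {}          # flat idx -> list of (patch index)
        for si, patch in enumerate(ph.synapse_faces):
            for v in patch["voxels"]:
                fi = self.isf_index[tuple(v)]
                if fi >= 0:
                    syn_count.setdefault(fi, []).append(si)
        self.syn_voxels = syn_count

        inter_i, inter_j = [], []
        n_ast = np.zeros(self.n)
        n_neu = np.zeros(self.n)
        adv_in, adv_out = [], []
        up_pairs = (np.array([], dtype=int), np.array([], dtype=int))
        idx = self.vox
        for (dx, dy, dz) in nbrs:
            ni = idx + np.array([dx, dy, dz])
            inb = ((ni >= 0).all(1)
                   & (ni[:, 0] < lab.shape[0]) & (ni[:, 1] < lab.shape[1])
                   & (ni[:, 2] < lab.shape[2]))
            me = np.arange(self.n)
            ni_c = np.clip(ni, 0, np.array(lab.shape) - 1)
            nl = lab[ni_c[:, 0], ni_c[:, 1], ni_c[:, 2]]
            nl = np.where(inb, nl, LABELS["VOID"])
            is_isf_n = nl == LABELS["ISF"]
            j = self.isf_index[ni_c[:, 0], ni_c[:, 1], ni_c[:, 2]]
            m = is_isf_n & (j >= 0)
            inter_i.append(me[m])
            inter_j.append(j[m])
            n_ast += (nl == LABELS["ASTROCYTE"]).astype(float)
            n_neu += ((nl == LABELS["NEURON"]) | (nl >= MITO_BASE)).astype(float)
            if (dx, dy, dz) == (0, -1, 0):
                adv_in = me[nl == LABELS["VOID"]]
            if (dx, dy, dz) == (0, 1, 0):
                adv_out = me[nl == LABELS["VOID"]]
                up_pairs = (me[m], j[m])     # donor me → receiver j along +Y
        self.inter_i = np.concatenate(inter_i)
        self.inter_j = np.concatenate(inter_j)
        self.n_ast_faces = n_ast
        self.n_neu_faces = n_neu
        self.adv_in = np.asarray(adv_in)
        self.adv_out = np.asarray(adv_out)
        self.up_donor, self.up_recv = up_pairs

    def _build_matrix(self):
        p, h = self.p, self.h
        dt = p.dt
        k = p.D_glu / h ** 2
        n = self.n
        rows, cols, vals = [self.inter_i], [self.inter_j], [-dt * k * np.ones(len(self.inter_i))]
        diag = np.zeros(n)
        np.add.at(diag, self.inter_i, dt * k)
        # synapse Dirichlet faces: ghost value at distance h/2
        self.syn_coeff = 0.0 if self.sealed else 2.0 * dt * k
        syn_faces = np.zeros(n)
        for fi, patches in self.syn_voxels.items():
            syn_faces[fi] += len(patches)
        self.syn_faces = syn_faces
        diag += self.syn_coeff * syn_faces
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(1.0 + diag)
        A = sparse.csr_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(n, n))
        self._lu = splu(A.tocsc())

    # -- stepping ---------------------------------------------------------
    def initial_field(self) -> np.ndarray:
        return np.full(self.n, self.p.c_glu_isf)

    def spike_values(self, t: float, schedule: ReleaseSchedule) -> Dict[int, float]:
        """Dirichlet value per synapse-adjacent ISF voxel at time t."""
        out = {}
        for fi, patches in self.syn_voxels.items():
            vals = [schedule.spike(t, self.ph.synapse_faces[si]["kind"], self.p)
                    for si in patches]
            out[fi] = float(np.mean(vals)) if vals else 0.0
        return out

    def step(self, c: np.ndarray, t: float,
             schedule: ReleaseSchedule) -> Tuple[np.ndarray, Dict[str, float]]:
        """One operator-split step; returns (c_new, mass ledger in µM·voxel)."""
        p, dt, h = self.p, self.p.dt, self.h
        ledger: Dict[str, float] = {}
        m0 = float(c.sum())

        # 1) explicit upwind advection along +Y
        cu = c.copy()
        a = 0.0 if self.sealed else p.u * dt / h
        if a > 0:
            flux = a * c[self.up_donor]          # donor-cell upwind
            np.subtract.at(cu, self.up_donor, flux)
            np.add.at(cu, self.up_recv, flux)
            fin = a * p.c_glu_isf
            cu[self.adv_in] += fin
            ledger["advect_in"] = fin * len(self.adv_in)
            fout = a * c[self.adv_out]
            cu[self.adv_out] -= fout
            ledger["advect_out"] = -float(fout.sum())
        else:
            ledger["advect_in"] = ledger["advect_out"] = 0.0

        # 2) implicit diffusion with synapse Dirichlet ghosts
        b = cu.copy()
        spikes = self.spike_values(t + dt, schedule)
        for fi, cbc in spikes.items():
            b[fi] += self.syn_coeff * self.syn_faces[fi] * cbc
        cd = self._lu.solve(b)
        syn_flux = 0.0
        for fi, cbc in spikes.items():
            syn_flux += self.syn_coeff * self.syn_faces[fi] * (cbc - cd[fi])
        ledger["synapse"] = syn_flux

        # 3) EAAT uptake (implicit per-voxel; exact positive root)
        if self.sealed:
            kup = np.zeros(self.n)
        else:
            kup = (self.n_ast_faces * p.eaat_vmax("AST")
                   + self.n_neu_faces * p.eaat_vmax("NEU")) / h
        km = p.km_eaat
        kdt = kup * dt
        cn = cd.copy()
        act = kdt > 0
        co = cd[act]
        bq = km + kdt[act] - co
        cn[act] = 0.5 * (-bq + np.sqrt(bq * bq + 4.0 * km * co))
        ledger["eaat"] = float((cn - cd).sum())

        m1 = float(cn.sum())
        ledger["audit_residual"] = m1 - m0 - sum(
            v for k_, v in ledger.items() if k_ != "audit_residual")
        return cn, ledger

    def probe_means(self, c: np.ndarray) -> np.ndarray:
        return np.array([float(c[ix].mean()) if len(ix) else 0.0
                         for ix in self._probe_idx])


# ---------------------------------------------------------------------------
# H2O2 solver (whole tissue domain)

class H2O2Solver:
    """Diffusion over the full tissue with threshold-switched mitochondrial
    sources, membrane-clamped cell surfaces and ISF advection."""

    def __init__(self, phantom: Phantom, params: SpatialParams):
        self.ph = phantom
        self.p = params
        h = phantom.voxel
        self.h = h
        lab = phantom.labels
        domain = lab != LABELS["VOID"]
        self.index = -np.ones(lab.shape, dtype=np.int64)
        self.vox = np.argwhere(domain)
        self.n = len(self.vox)
        self.index[domain] = np.arange(self.n)

        isf = phantom.mask("ISF")
        ast = phantom.mask("ASTROCYTE")
        neu = phantom.mask("NEURON")
        mito = phantom.mask("MITO")

        # membrane clamp: cell voxels in contact with ISF are held at
        # alpha_cell * c0 (the cells buffer H2O2 at their surface)
        from scipy import ndimage
        touch_isf = ndimage.binary_dilation(isf)
        clamp = (ast | neu) & touch_isf
        self.clamp_idx = self.index[clamp]
        self.clamp_value = params.alpha_cell * params.c_h2o2_0

        self.isf_flat = self.index[isf]
        self.mito_flat = [self.index[phantom.mito_mask(k)]
                          for k in range(phantom.spec.n_mito)]

        self._build(lab, domain, isf)

    def _build(self, lab, domain, isf):
        p, h = self.p, self.h
        dt = p.dt
        k = p.D_h2o2 / h ** 2
        idx = self.vox
        n = self.n
        nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        adv_in, adv_out = [], []
        up_d, up_r = [], []
        isf_here = isf[idx[:, 0], idx[:, 1], idx[:, 2]]
        me_all = np.arange(n)
        for (dx, dy, dz) in nbrs:
            ni = idx + np.array([dx, dy, dz])
            inb = ((ni >= 0).all(1)
                   & (ni[:, 0] < lab.shape[0]) & (ni[:, 1] < lab.shape[1])
                   & (ni[:, 2] < lab.shape[2]))
            ni_c = np.clip(ni, 0, np.array(lab.shape) - 1)
            dom_n = domain[ni_c[:, 0], ni_c[:, 1], ni_c[:, 2]] & inb
            j = self.index[ni_c[:, 0], ni_c[:, 1], ni_c[:, 2]]
            m = dom_n & (j >= 0)
            rows.append(me_all[m])
            cols.append(j[m])
            vals.append(-dt * k * np.ones(int(m.sum())))
            np.add.at(diag, me_all[m], dt * k)
            isf_n = isf[ni_c[:, 0], ni_c[:, 1], ni_c[:, 2]] & inb
            if (dx, dy, dz) == (0, -1, 0):
                adv_in = me_all[isf_here & ~dom_n]
            if (dx, dy, dz) == (0, 1, 0):
                adv_out = me_all[isf_here & ~dom_n]
                mm = isf_here & isf_n & (j >= 0)
                up_d, up_r = me_all[mm], j[mm]
        rows.append(me_all)
        cols.append(me_all)
        vals.append(1.0 + diag)
        R = np.concatenate(rows)
        C = np.concatenate(cols)
        V = np.concatenate(vals)
        # eliminate the Dirichlet-clamped voxels: the reduced system is
        # symmetric positive definite, solved by preconditioned CG with
        # warm starts (the full-domain LU is prohibitively fill-heavy)
        clamped = np.zeros(n, dtype=bool)
        clamped[self.clamp_idx] = True
        self.free = np.where(~clamped)[0]
        remap = -np.ones(n, dtype=np.int64)
        remap[self.free] = np.arange(len(self.free))
        both_free = ~clamped[R] & ~clamped[C]
        A_rr = sparse.csr_matrix(
            (V[both_free], (remap[R[both_free]], remap[C[both_free]])),
            shape=(len(self.free), len(self.free)))
        into_clamp = ~clamped[R] & clamped[C]
        g = np.zeros(len(self.free))
        np.add.at(g, remap[R[into_clamp]], -V[into_clamp] * self.clamp_value)
        self._A_rr = A_rr
        self._g = g
        self._Minv = sparse.diags(1.0 / A_rr.diagonal())
        self._x_prev = None
        self.adv_in, self.adv_out = np.asarray(adv_in), np.asarray(adv_out)
        self.up_donor, self.up_recv = np.asarray(up_d), np.asarray(up_r)

    def initial_field(self) -> np.ndarray:
        p = self.p
        lab = self.ph.labels
        alpha = np.full(self.n, p.alpha_cell)
        flat_labels = lab[self.vox[:, 0], self.vox[:, 1], self.vox[:, 2]]
        alpha[flat_labels == LABELS["ISF"]] = p.alpha_isf
        alpha[flat_labels >= MITO_BASE] = p.alpha_mit
        return alpha * p.c_h2o2_0

    def step(self, c: np.ndarray, induced: np.ndarray) -> np.ndarray:
        p, dt, h = self.p, self.p.dt, self.h
        # advection in ISF
        cu = c.copy()
        a = p.u * dt / h
        if a > 0 and len(self.up_donor):
            flux = a * c[self.up_donor]
            np.subtract.at(cu, self.up_donor, flux)
            np.add.at(cu, self.up_recv, flux)
            cu[self.adv_in] += a * p.alpha_cell * p.c_h2o2_0
            cu[self.adv_out] -= a * c[self.adv_out]
        # mitochondrial sources
        for k_, flat in enumerate(self.mito_flat):
            cu[flat] += dt * p.source_rate(bool(induced[k_]))
        # clamped surfaces held fixed; solve the reduced SPD system
        b = cu[self.free] + self._g
        x0 = self._x_prev if self._x_prev is not None else cu[self.free]
        x, info = cg(self._A_rr, b, x0=x0, rtol=1e-10, atol=1e-14,
                     M=self._Minv, maxiter=500)
        if info != 0:
            raise RuntimeError(f"H2O2 diffusion CG did not converge (info={info})")
        self._x_prev = x
        out = cu.copy()
        out[self.free] = x
        out[self.clamp_idx] = self.clamp_value
        return out


# ---------------------------------------------------------------------------
# scenario driver

@dataclass
class SpatialResult:
    times: np.ndarray                  # ms
    mean_isf_glu: np.ndarray           # µM
    probe_means: np.ndarray            # (nt, n_mito)
    induced_count: np.ndarray          # instantaneous count per time
    ever_induced: np.ndarray           # (n_mito,) bool
    max_audit_residual: float
    final: FieldState

    @property
    def activated_count(self) -> int:
        return int(self.ever_induced.sum())

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({"time_ms": self.times,
                           "mean_isf_glu_uM": self.mean_isf_glu,
                           "induced_count": self.induced_count})
        for k in range(self.probe_means.shape[1]):
            df[f"probe_glu_mito{k}"] = self.probe_means[:, k]
        return df


def run_release_scenario(
    phantom: Phantom,
    params: SpatialParams,
    schedule: ReleaseSchedule,
    t_end: float = 5.0,
    record_every: int = 5,
    glu_solver: Optional[GlutamateSolver] = None,
    h2o2_solver: Optional[H2O2Solver] = None,
) -> SpatialResult:
    """Run a vesicle-release scenario over ``t_end`` ms.

    Pre-built solvers may be passed in to amortize the sparse
    factorizations across scenarios on the same phantom.
    """
    gs = glu_solver or GlutamateSolver(phantom, params)
    hs = h2o2_solver or H2O2Solver(phantom, params)
    c_glu = gs.initial_field()
    c_h = hs.initial_field()
    n_mito = phantom.spec.n_mito
    induced = np.zeros(n_mito, dtype=bool)
    ever = np.zeros(n_mito, dtype=bool)

    times, means, probes, counts = [], [], [], []
    max_resid = 0.0
    nsteps = int(round(t_end / params.dt))
    t = 0.0
    for i in range(nsteps):
        c_glu, ledger = gs.step(c_glu, t, schedule)
        rel = abs(ledger["audit_residual"]) / max(float(c_glu.sum()), 1e-300)
        max_resid = max(max_resid, rel)
        pm = gs.probe_means(c_glu)
        induced = pm >= params.c_glu_thr
        ever |= induced
        c_h = hs.step(c_h, induced)
        t += params.dt
        if i % record_every == 0 or i == nsteps - 1:
            times.append(t)
            means.append(float(c_glu.mean()))
            probes.append(pm)
            counts.append(int(induced.sum()))

    final = FieldState(c_glu=c_glu, c_h2o2=c_h, induced=induced,
                       ever_induced=ever, t=t)
    return SpatialResult(times=np.array(times), mean_isf_glu=np.array(means),
                         probe_means=np.array(probes),
                         induced_count=np.array(counts),
                         ever_induced=ever, max_audit_residual=max_resid,
                         final=final)


# ---------------------------------------------------------------------------
# output

def write_vtk(path: str, phantom: Phantom, solver, c_flat: np.ndarray,
              name: str = "concentration") -> None:
    """Write a field as a legacy-VTK ASCII STRUCTURED_POINTS file."""
    grid = np.zeros(phantom.labels.shape)
    grid[solver.vox[:, 0], solver.vox[:, 1], solver.vox[:, 2]] = c_flat
    nx, ny, nz = grid.shape
    h = phantom.voxel
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name} field on tissue phantom\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {phantom.origin[0]} {phantom.origin[1]} {phantom.origin[2]}\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        flat = grid.transpose(2, 1, 0).ravel()
        np.savetxt(f, flat.reshape(-1, 9) if flat.size % 9 == 0 else flat[None].T,
                   fmt="%.6g")
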