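"""Implicit finite-volume solver for the modified Pennes bioheat equation.

The energy balance per unit tissue volume is

    C'(T) dT/dt = div(k(T) grad T) - rho_b C_b w_b(T, Omega) (T - T_b)
                  + Q_met + Q_laser,

where the volumetric heat capacity C'(T) = rho*C already carries the
apparent-capacity peak that absorbs the latent heat of water evaporation
(so the h_fg dW/dt term is implicit in the storage term), and the perfusion
rate w_b depends on temperature through piecewise-polynomial multipliers
and shuts down where the necrotic fraction Omega reaches 1.

Discretization: conservative finite volumes on the structured phantom grid
(uniform voxels in 3-D, graded node-centred mesh in axisymmetric mode) with
harmonic-mean interface conductivity; backward-Euler time stepping with
coefficients lagged one step (single Picard iteration by default, dt = 2 s);
Dirichlet 37 degC on the embedding cube surface and series
conduction-convection (Robin) transmissibilities on vessel surfaces.  The
scheme is deterministic and, because the energy ledger is accumulated from
the same discrete fluxes as the solve, closes the energy balance to solver
precision.

Temperatures are capped at 150 degC with a warning: the model carries no
charring chemistry, and beyond water depletion its property curves are
extrapolations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

#: Above this many unknowns the per-step solves use preconditioned CG
#: (the backward-Euler matrix is SPD and diagonally dominant) instead of a
#: direct factorization, whose 3-D fill-in is prohibitive.
_DIRECT_SOLVE_LIMIT = 20000


def _linear_solve(A, b, x0=None):
    A = A.tocsr()
    if A.shape[0] <= _DIRECT_SOLVE_LIMIT or x0 is None:
        return spsolve(A, b)
    M = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, b, x0=x0, rtol=1e-10, atol=0.0, M=M, maxiter=2000)
    if info != 0:
        return spsolve(A, b)
    return x

from littplan.dosimetry import DamageField, DamageModelConfig
from littplan.errors import SolverError
from littplan.optics import LaserConfig, OpticalProps, SourceField, build_source_field, \
    effective_attenuation
from littplan.phantom import VoxelPhantom, build_axisymmetric_phantom, PhantomSpec
from littplan.tissue import (
    BLOOD_DENSITY,
    BLOOD_SPECIFIC_HEAT,
    BLOOD_TEMPERATURE,
    TissueModelSet,
)

__all__ = [
    "SolverConfig",
    "BoundarySpec",
    "SimulationResult",
    "solve",
    "steady_solve",
    "mesh_convergence_check",
    "ConvergenceReport",
    "analytic_perfused_point_source",
]


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration settings."""

    dt: float = 2.0  # s
    total_time: float = 600.0  # s
    picard_iterations: int = 3  # lagged predictor + chord-capacity correctors
    temperature_cap: float = 150.0  # degC
    store_final_only: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.total_time <= 0:
            raise ValueError("dt and total_time must be positive")
        if self.picard_iterations < 1:
            raise ValueError("picard_iterations must be >= 1")


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary and initial conditions.

    By default every outer face of the embedding cube (or the r_max/z ends of
    the axisymmetric half-plane) holds a fixed 37 degC, vessels carry Robin
    convective fluxes h*(T_b - T) with their per-vessel coefficients, and the
    initial temperature is uniform 37 degC.  ``faces`` overrides individual
    outer faces with ("dirichlet", T), ("robin", h) or ("insulated",); the
    symmetry axis in axisymmetric mode is always a natural zero-flux face.
    """

    cube_temperature: float = 37.0
    blood_temperature: float = BLOOD_TEMPERATURE
    initial_temperature: float = 37.0
    faces: dict = field(default_factory=dict)

    def face(self, name: str):
        return self.faces.get(name, ("dirichlet", self.cube_temperature))


# ---------------------------------------------------------------------------
# discretization

class _Discretization:
    """Precomputed FV topology: interior faces, boundary faces, volumes."""

    def __init__(self, phantom: VoxelPhantom, boundary: BoundarySpec):
        self.phantom = phantom
        self.boundary = boundary
        if phantom.mode == "axisymmetric":
            self._build_axisym()
        else:
            self._build_voxel()

    # interior faces: arrays ia, ib (unknown indices), area_m2, da_m, db_m
    # dirichlet faces: cell, area_m2, d_m, tval
    # robin faces: cell, area_m2, d_m, h, tval

    def _build_axisym(self) -> None:
        ph = self.phantom
        nr, nz = ph.shape
        n = nr * nz
        self.active = np.ones(n, dtype=bool)
        self.n_active = n
        idx = np.arange(n).reshape(nr, nz)
        rn, re = ph.r_nodes_mm, ph.r_edges_mm
        zn, ze = ph.z_nodes_mm, ph.z_edges_mm
        dz = np.diff(ze)
        ring = np.pi * (re[1:] ** 2 - re[:-1] ** 2)

        ia, ib, area, da, db = [], [], [], [], []
        # radial faces between rings i and i+1
        for i in range(nr - 1):
            rf = re[i + 1]
            a = 2.0 * np.pi * rf * dz * 1e-6
            ia.append(idx[i, :]); ib.append(idx[i + 1, :])
            area.append(a)
            da.append(np.full(nz, (rf - rn[i]) * 1e-3))
            db.append(np.full(nz, (rn[i + 1] - rf) * 1e-3))
        # axial faces between j and j+1
        for j in range(nz - 1):
            zf = ze[j + 1]
            a = ring * 1e-6
            ia.append(idx[:, j]); ib.append(idx[:, j + 1])
            area.append(a)
            da.append(np.full(nr, (zf - zn[j]) * 1e-3))
            db.append(np.full(nr, (zn[j + 1] - zf) * 1e-3))
        self.f_ia = np.concatenate(ia)
        self.f_ib = np.concatenate(ib)
        self.f_area = np.concatenate(area)
        self.f_da = np.concatenate(da)
        self.f_db = np.concatenate(db)

        dir_c, dir_a, dir_d, dir_t = [], [], [], []
        rob_c, rob_a, rob_d, rob_h, rob_t = [], [], [], [], []

        def add_face(cells, areas, dists, spec):
            kind = spec[0]
            if kind == "insulated":
                return
            if kind == "dirichlet":
                dir_c.append(cells); dir_a.append(areas)
                dir_d.append(dists); dir_t.append(np.full(len(cells), spec[1]))
            elif kind == "robin":
                rob_c.append(cells); rob_a.append(areas); rob_d.append(dists)
                rob_h.append(np.full(len(cells), spec[1]))
                rob_t.append(np.full(len(cells), self.boundary.blood_temperature))
            else:
                raise ValueError(f"unknown boundary kind {kind!r}")

        add_face(idx[nr - 1, :], 2.0 * np.pi * re[-1] * dz * 1e-6,
                 np.full(nz, (re[-1] - rn[-1]) * 1e-3), self.boundary.face("rmax"))
        add_face(idx[:, 0], ring * 1e-6, np.full(nr, (zn[0] - ze[0]) * 1e-3),
                 self.boundary.face("zmin"))
        add_face(idx[:, nz - 1], ring * 1e-6,
                 np.full(nr, (ze[-1] - zn[-1]) * 1e-3), self.boundary.face("zmax"))

        self._finish_bc(dir_c, dir_a, dir_d, dir_t, rob_c, rob_a, rob_d, rob_h, rob_t)
        self.volumes = ph.cell_volumes_m3.ravel()
        self.unknown_of_cell = np.arange(n)
        self.labels_flat = ph.label_grid.ravel()

    def _build_voxel(self) -> None:
        ph = self.phantom
        shape = ph.shape
        n = int(np.prod(shape))
        spacing = np.asarray(ph.spacing_mm, dtype=float)
        vessel_codes = set(ph.vessel_h_by_label)
        labels = ph.label_grid
        active3 = ~np.isin(labels, list(vessel_codes)) if vessel_codes else \
            np.ones(shape, dtype=bool)
        idx = np.full(shape, -1, dtype=np.int64)
        idx[active3] = np.arange(int(active3.sum()))
        self.active = active3.ravel()
        self.n_active = int(active3.sum())

        ia, ib, area, da, db = [], [], [], [], []
        rob_c, rob_a, rob_d, rob_h, rob_t = [], [], [], [], []
        dir_c, dir_a, dir_d, dir_t = [], [], [], []
        voxel_area = [float(np.prod(spacing) / spacing[ax]) * 1e-6 for ax in range(3)]
        half = spacing * 0.5e-3  # m

        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            A = idx[tuple(sl_a)].ravel()
            B = idx[tuple(sl_b)].ravel()
            actA = active3[tuple(sl_a)].ravel()
            actB = active3[tuple(sl_b)].ravel()
            labA = labels[tuple(sl_a)].ravel()
            labB = labels[tuple(sl_b)].ravel()
            both = actA & actB
            ia.append(A[both]); ib.append(B[both])
            area.append(np.full(both.sum(), voxel_area[ax]))
            da.append(np.full(both.sum(), half[ax]))
            db.append(np.full(both.sum(), half[ax]))
            # tissue next to a vessel cell: Robin face with the vessel's h
            for sel, cells, vlab in ((actA & ~actB, A, labB), (~actA & actB, B, labA)):
                if not sel.any():
                    continue
                cc = cells[sel]
                hh = np.asarray([ph.vessel_h_by_label[int(c)] for c in vlab[sel]])
                rob_c.append(cc)
                rob_a.append(np.full(len(cc), voxel_area[ax]))
                rob_d.append(np.full(len(cc), half[ax]))
                rob_h.append(hh)
                rob_t.append(np.full(len(cc), self.boundary.blood_temperature))

        face_names = (("xmin", "xmax"), ("ymin", "ymax"), ("zmin", "zmax"))
        for ax in range(3):
            for side, name in enumerate(face_names[ax]):
                sl = [slice(None)] * 3
                sl[ax] = 0 if side == 0 else -1
                cells = idx[tuple(sl)].ravel()
                act = active3[tuple(sl)].ravel()
                cells = cells[act]
                spec = self.boundary.face(name)
                if spec[0] == "insulated" or len(cells) == 0:
                    continue
                if spec[0] == "dirichlet":
                    dir_c.append(cells)
                    dir_a.append(np.full(len(cells), voxel_area[ax]))
                    dir_d.append(np.full(len(cells), half[ax]))
                    dir_t.append(np.full(len(cells), spec[1]))
                elif spec[0] == "robin":
                    rob_c.append(cells)
                    rob_a.append(np.full(len(cells), voxel_area[ax]))
                    rob_d.append(np.full(len(cells), half[ax]))
                    rob_h.append(np.full(len(cells), spec[1]))
                    rob_t.append(np.full(len(cells), self.boundary.blood_temperature))
                else:
                    raise ValueError(f"unknown boundary kind {spec[0]!r}")

        self.f_ia = np.concatenate(ia) if ia else np.empty(0, dtype=np.int64)
        self.f_ib = np.concatenate(ib) if ib else np.empty(0, dtype=np.int64)
        self.f_area = np.concatenate(area) if area else np.empty(0)
        self.f_da = np.concatenate(da) if da else np.empty(0)
        self.f_db = np.concatenate(db) if db else np.empty(0)
        self._finish_bc(dir_c, dir_a, dir_d, dir_t, rob_c, rob_a, rob_d, rob_h, rob_t)
        self.volumes = ph.cell_volumes_m3.ravel()[self.active]
        self.unknown_of_cell = idx.ravel()
        self.labels_flat = labels.ravel()[self.active]

    def _finish_bc(self, dir_c, dir_a, dir_d, dir_t,
                   rob_c, rob_a, rob_d, rob_h, rob_t) -> None:
        cat = lambda xs: np.concatenate(xs) if xs else np.empty(0)
        self.d_cell = cat(dir_c).astype(np.int64)
        self.d_area = cat(dir_a)
        self.d_dist = cat(dir_d)
        self.d_tval = cat(dir_t)
        self.r_cell = cat(rob_c).astype(np.int64)
        self.r_area = cat(rob_a)
        self.r_dist = cat(rob_d)
        self.r_h = cat(rob_h)
        self.r_tval = cat(rob_t)

    # -- per-step operator assembly ----------------------------------------

    def conduction_matrix(self, k_cell: np.ndarray):
        """SPD conduction operator and Dirichlet/Robin couplings.

        Returns (K, u_diag, u_rhs): K the interior conduction matrix,
        u_diag the boundary transmissibilities added to the diagonal and
        u_rhs their right-hand-side contribution.
        """
        n = self.n_active
        cond = self.f_area / (self.f_da / k_cell[self.f_ia]
                              + self.f_db / k_cell[self.f_ib])
        rows = np.concatenate([self.f_ia, self.f_ib, self.f_ia, self.f_ib])
        cols = np.concatenate([self.f_ia, self.f_ib, self.f_ib, self.f_ia])
        vals = np.concatenate([cond, cond, -cond, -cond])
        K = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

        u_diag = np.zeros(n)
        u_rhs = np.zeros(n)
        if len(self.d_cell):
            u = self.d_area * k_cell[self.d_cell] / self.d_dist
            np.add.at(u_diag, self.d_cell, u)
            np.add.at(u_rhs, self.d_cell, u * self.d_tval)
        if len(self.r_cell):
            u = self.r_area / (1.0 / self.r_h + self.r_dist / k_cell[self.r_cell])
            np.add.at(u_diag, self.r_cell, u)
            np.add.at(u_rhs, self.r_cell, u * self.r_tval)
        return K, u_diag, u_rhs

    def boundary_outflow(self, T: np.ndarray, k_cell: np.ndarray) -> float:
        """Instantaneous heat flow (W) out through Dirichlet+Robin faces."""
        out = 0.0
        if len(self.d_cell):
            u = self.d_area * k_cell[self.d_cell] / self.d_dist
            out += float(np.sum(u * (T[self.d_cell] - self.d_tval)))
        if len(self.r_cell):
            u = self.r_area / (1.0 / self.r_h + self.r_dist / k_cell[self.r_cell])
            out += float(np.sum(u * (T[self.r_cell] - self.r_tval)))
        return out


class _TissueGroups:
    """Active cells grouped by tissue material for vectorized property eval."""

    def __init__(self, disc: _Discretization, models: TissueModelSet):
        ph = disc.phantom
        self.items = []
        for code in np.unique(disc.labels_flat):
            tname = ph.tissue_name_of_label(int(code))
            cells = np.nonzero(disc.labels_flat == code)[0]
            self.items.append((tname, cells, models[tname]))

        n = disc.n_active
        self.omega0 = np.zeros(n)
        self.qmet = np.zeros(n)
        for tname, cells, tm in self.items:
            self.omega0[cells] = tm.baseline.baseline_perfusion
            self.qmet[cells] = tm.baseline.metabolic_heat
        # volumetric enthalpy H(T) = int C'(T) dT per tissue, for the chord
        # (secant) capacity that books the evaporation latent heat exactly
        # across a time step regardless of dt
        self._h_grid = np.arange(0.0, 200.0 + 1e-9, 0.05)
        self._enthalpy = {}
        for tname, _, tm in self.items:
            cap = tm.curves.heat_capacity(self._h_grid)
            H = np.concatenate([[0.0], np.cumsum(
                0.5 * (cap[1:] + cap[:-1]) * np.diff(self._h_grid))])
            self._enthalpy[tname] = H

    def conductivity(self, T: np.ndarray) -> np.ndarray:
        k = np.empty_like(T)
        for _, cells, tm in self.items:
            k[cells] = tm.curves.conductivity(T[cells])
        return k

    def heat_capacity(self, T: np.ndarray) -> np.ndarray:
        c = np.empty_like(T)
        for _, cells, tm in self.items:
            c[cells] = tm.curves.heat_capacity(T[cells])
        return c

    def chord_capacity(self, T_new: np.ndarray, T_old: np.ndarray) -> np.ndarray:
        """Secant capacity (H(T_new)-H(T_old))/(T_new-T_old) per active cell,
        falling back to the pointwise capacity where the step is tiny."""
        c = np.empty_like(T_new)
        dT = T_new - T_old
        for tname, cells, tm in self.items:
            Hn = np.interp(T_new[cells], self._h_grid, self._enthalpy[tname])
            Ho = np.interp(T_old[cells], self._h_grid, self._enthalpy[tname])
            d = dT[cells]
            point = tm.curves.heat_capacity(T_new[cells])
            with np.errstate(divide="ignore", invalid="ignore"):
                chord = (Hn - Ho) / d
            c[cells] = np.where(np.abs(d) > 1e-8, chord, point)
        return c

    def perfusion_rate(self, T: np.ndarray, omega: np.ndarray) -> np.ndarray:
        """w_b = w0 * multiplier(T, Omega), 1/s per active cell."""
        w = np.zeros_like(T)
        for _, cells, tm in self.items:
            mult = tm.perfusion.multiplier(T[cells], omega[cells])
            w[cells] = self.omega0[cells] * np.asarray(mult)
        return w


# ---------------------------------------------------------------------------
# results

@dataclass
class SimulationResult:
    """Spatiotemporal solution summary of one LITT exposure."""

    times: np.ndarray
    temperature: np.ndarray  # final T on the full grid (degC; NaN in vessels)
    t_max: np.ndarray  # per-cell max over time
    damage: DamageField
    probe_traces: pd.DataFrame
    trace_means: pd.DataFrame | None
    ledger: dict
    checkpoints: list
    oar_max: dict

    @property
    def energy_closure_fraction(self) -> float:
        return self.ledger["closure_fraction"]


def _full_grid(shape, active, values, fill=np.nan):
    out = np.full(int(np.prod(shape)), fill)
    out[active] = values
    return out.reshape(shape)


def _probe_indices(phantom: VoxelPhantom, disc: _Discretization):
    """Unknown index of the active cell nearest each probe point."""
    out = []
    for p in phantom.probe_points_mm:
        if phantom.mode == "axisymmetric":
            i = int(np.argmin(np.abs(phantom.r_nodes_mm - p[0])))
            j = int(np.argmin(np.abs(phantom.z_nodes_mm - p[1])))
            flat = i * phantom.shape[1] + j
        else:
            h = np.asarray(phantom.spacing_mm)
            ijk = np.clip((np.asarray(p) / h).astype(int), 0,
                          np.asarray(phantom.shape) - 1)
            flat = int(np.ravel_multi_index(tuple(ijk), phantom.shape))
        u = disc.unknown_of_cell[flat]
        if u < 0:
            raise SolverError("probe point falls inside an excluded vessel cell")
        out.append(int(u))
    return out


def default_oar_masks(phantom: VoxelPhantom) -> dict[str, np.ndarray]:
    """Organ-at-risk masks: duodenum cells, and the tissue shell one cell
    thick around each vessel (the vessel interior is not part of the
    conduction domain, so its wall temperature is read on the adjacent
    tissue cells)."""
    masks: dict[str, np.ndarray] = {}
    if phantom.mode == "axisymmetric":
        return masks
    labels = phantom.label_grid
    for code in phantom.vessel_labels:
        vm = labels == code
        shell = np.zeros_like(vm)
        for ax in range(3):
            for shift in (1, -1):
                shell |= np.roll(vm, shift, axis=ax)
        shell &= ~np.isin(labels, phantom.vessel_labels)
        masks[phantom.label_names[code]] = shell
    duo = labels == 5
    if duo.any():
        masks["duodenum"] = duo
    return masks


# ---------------------------------------------------------------------------
# drivers

def solve(
    phantom: VoxelPhantom,
    models: TissueModelSet,
    laser: LaserConfig | None = None,
    optics: OpticalProps | None = None,
    config: SolverConfig | None = None,
    boundary: BoundarySpec | None = None,
    damage: DamageModelConfig | None = None,
    external_source: SourceField | None = None,
    checkpoint_times=None,
    trace_masks: dict[str, np.ndarray] | None = None,
    oar_masks: dict[str, np.ndarray] | None = None,
    target_mask: np.ndarray | None = None,
) -> SimulationResult:
    """Time-march the bioheat equation over one laser exposure.

    Each backward-Euler step lags the temperature- and damage-dependent
    coefficients (k, C', perfusion, blended optics) at the previous step's
    state, rebuilds the Beer-Lambert source from the coagulation-blended
    attenuation, solves the sparse linear system, then accumulates the
    dwell-time damage field.  ``checkpoint_times`` (s) record ablation and
    organ-at-risk metrics along the way so a single run serves a whole
    duration sweep at fixed power.
    """
    config = config or SolverConfig()
    boundary = boundary or BoundarySpec()
    damage = damage or DamageModelConfig(irradiation_time=config.total_time)
    optics = optics or OpticalProps()

    disc = _Discretization(phantom, boundary)
    groups = _TissueGroups(disc, models)
    n = disc.n_active
    V = disc.volumes
    rho_cb = BLOOD_DENSITY * BLOOD_SPECIFIC_HEAT

    T = np.full(n, boundary.initial_temperature)
    theta = np.zeros(n)
    t_max = T.copy()

    probe_idx = _probe_indices(phantom, disc)
    probe_rows = []
    mean_rows = []
    trace_items = []
    if trace_masks:
        for name, m in trace_masks.items():
            cells = disc.unknown_of_cell[m.ravel()]
            trace_items.append((name, cells[cells >= 0]))

    oar_masks = default_oar_masks(phantom) if oar_masks is None else oar_masks
    oar_items = []
    for name, m in oar_masks.items():
        cells = disc.unknown_of_cell[m.ravel()]
        oar_items.append((name, cells[cells >= 0]))
    oar_running = {name: float(boundary.initial_temperature) for name, _ in oar_items}

    if target_mask is None:
        tm = (phantom.label_grid == 2) | (phantom.label_grid == 3)
        target_mask = tm if tm.any() else None
    target_cells = None
    target_volume = None
    if target_mask is not None:
        tc = disc.unknown_of_cell[target_mask.ravel()]
        target_cells = tc[tc >= 0]
        target_volume = float(np.sum(V[target_cells]))

    ledger = dict(deposited=0.0, metabolic=0.0, stored=0.0, boundary=0.0,
                  perfusion=0.0, capped=0.0, lost_to_inactive=0.0)

    n_steps = max(1, int(round(config.total_time / config.dt)))
    dt = config.total_time / n_steps
    times = dt * np.arange(n_steps + 1)
    cp_iter = iter(sorted(checkpoint_times)) if checkpoint_times else iter(())
    next_cp = next(cp_iter, None)
    checkpoints: list[dict] = []
    warned_cap = False
    cap_pinned = np.zeros(n, dtype=bool)

    native_alpha = effective_attenuation(optics.native.absorption,
                                         optics.native.scattering,
                                         optics.native.anisotropy)
    coag_alpha_coeffs = optics.coagulated

    def record_traces(t_now, Tvec):
        row = {"time_s": t_now}
        for i, u in enumerate(probe_idx):
            row[f"probe_{i}"] = float(Tvec[u])
        probe_rows.append(row)
        if trace_items:
            mrow = {"time_s": t_now}
            for name, cells in trace_items:
                mrow[name] = float(Tvec[cells].mean()) if len(cells) else np.nan
            mean_rows.append(mrow)

    record_traces(0.0, T)

    for step_i in range(n_steps):
        t_new = times[step_i + 1]
        omega = np.minimum(theta, 1.0)

        # laser source from coagulation-blended optics
        if external_source is not None:
            src = external_source
            q_active = src.q.ravel()[disc.active]
        elif laser is not None:
            om_full = _full_grid(phantom.shape, disc.active, omega, fill=0.0)
            nat, coa = optics.native, coag_alpha_coeffs
            a = nat.absorption * (1 - om_full) + coa.absorption * om_full
            s = nat.scattering * (1 - om_full) + coa.scattering * om_full
            g = nat.anisotropy * (1 - om_full) + coa.anisotropy * om_full
            alpha_eff = np.sqrt(3.0 * a * (a + s * (1.0 - g)))
            src = build_source_field(phantom, laser, alpha_eff)
            q_active = src.q.ravel()[disc.active]
            ledger["lost_to_inactive"] += dt * (src.deposited_power
                                                - float(np.sum(q_active * V)))
        else:
            q_active = np.zeros(n)

        T_old = T
        T_iter = T_old
        for it in range(config.picard_iterations):
            k_cell = groups.conductivity(T_iter)
            # first pass lags the capacity; later passes use the chord
            # capacity so the latent-heat booking is dt-independent
            c_cell = (groups.heat_capacity(T_iter) if it == 0
                      else groups.chord_capacity(T_iter, T_old))
            w_cell = groups.perfusion_rate(T_iter, omega)
            K, u_diag, u_rhs = disc.conduction_matrix(k_cell)
            S = c_cell * V / dt
            P = rho_cb * w_cell * V
            A = K + sparse.diags(S + P + u_diag)
            b = S * T_old + P * boundary.blood_temperature + u_rhs \
                + q_active * V + groups.qmet * V
            # graded 2-D meshes factorize cheaply and condition poorly for CG
            x0 = None if phantom.mode == "axisymmetric" else T_old
            T_new = _linear_solve(A, b, x0=x0)
            if not np.all(np.isfinite(T_new)):
                raise SolverError(
                    f"linear solve produced non-finite temperatures at t={t_new:.1f}s "
                    f"(|T|max={np.nanmax(np.abs(T_new)):.3g})")
            T_iter = T_new

        # temperature cap as an obstacle constraint (T <= cap with a
        # non-negative extraction multiplier): primal active-set iteration,
        # warm-started from the previous step's pinned set.  A hard
        # post-solve clip would make the extracted energy depend on dt.
        cap = config.temperature_cap
        pinned = cap_pinned.copy()
        if pinned.any() or np.any(T_new > cap):
            if not warned_cap:
                warnings.warn(
                    f"temperature capped at {cap} degC; the model has no "
                    "charring physics beyond water depletion", stacklevel=2)
                warned_cap = True
            A_csr = A.tocsr()
            big = 1e8 * float(A_csr.diagonal().max())
            tol_r = 1e-10 * float(np.abs(b).max())
            for _ in range(40):
                if pinned.any():
                    Ap = A_csr + sparse.diags(big * pinned.astype(float))
                    x0 = None if phantom.mode == "axisymmetric" else T_new
                    T_try = _linear_solve(Ap, b + big * cap * pinned, x0=x0)
                else:
                    T_try = T_new
                lam = b - A_csr @ T_try  # extraction rate (W) on pinned cells
                release = pinned & (lam < -tol_r)
                add = ~pinned & (T_try > cap + 1e-9)
                if not release.any() and not add.any():
                    T_new = T_try
                    break
                pinned = (pinned & ~release) | add
            else:
                T_new = np.minimum(T_try, cap)
            T_new = np.minimum(T_new, cap + 1e-9)
            cap_pinned = pinned

        # ledger from the same discrete fluxes; with pinned cells the step
        # imbalance is exactly the heat the cap extracted
        stored = float(np.sum(S * dt * (T_new - T_old)))
        bound = dt * (float(np.sum(u_diag * T_new) - np.sum(u_rhs)))
        perf = dt * float(np.sum(P * (T_new - boundary.blood_temperature)))
        depo = dt * float(np.sum(q_active * V))
        met = dt * float(np.sum(groups.qmet * V))
        ledger["stored"] += stored
        ledger["boundary"] += bound
        ledger["perfusion"] += perf
        ledger["deposited"] += depo
        ledger["metabolic"] += met
        if pinned.any():
            ledger["capped"] += depo + met - stored - bound - perf

        T = T_new
        theta = theta + (dt / damage.necrosis_time) * (T > damage.damage_temperature)
        t_max = np.maximum(t_max, T)
        for name, cells in oar_items:
            if len(cells):
                oar_running[name] = max(oar_running[name], float(T[cells].max()))
        record_traces(t_new, T)

        while next_cp is not None and t_new >= next_cp - 0.5 * dt:
            omega_now = np.minimum(theta, 1.0)
            ablated = omega_now >= 1.0
            cp = {
                "time_s": float(next_cp),
                "ablated_volume_mm3": float(np.sum(V[ablated]) * 1e9),
                "oar_max_c": (max(oar_running.values()) if oar_running else np.nan),
            }
            if target_cells is not None and target_volume:
                cp["ablated_fraction_pct"] = 100.0 * float(
                    np.sum(V[target_cells][ablated[target_cells]])) / target_volume
            checkpoints.append(cp)
            next_cp = next(cp_iter, None)

    residual = (ledger["deposited"] + ledger["metabolic"]
                - ledger["stored"] - ledger["boundary"]
                - ledger["perfusion"] - ledger["capped"])
    denom = max(abs(ledger["deposited"]) + abs(ledger["metabolic"]), 1e-30)
    ledger["closure_residual_j"] = residual
    ledger["closure_fraction"] = abs(residual) / denom

    shape = phantom.shape
    return SimulationResult(
        times=times,
        temperature=_full_grid(shape, disc.active, T),
        t_max=_full_grid(shape, disc.active, t_max),
        damage=DamageField(theta=_full_grid(shape, disc.active, theta, fill=0.0)),
        probe_traces=pd.DataFrame(probe_rows),
        trace_means=pd.DataFrame(mean_rows) if mean_rows else None,
        ledger=ledger,
        checkpoints=checkpoints,
        oar_max=dict(oar_running),
    )


def steady_solve(
    phantom: VoxelPhantom,
    models: TissueModelSet,
    source: SourceField | None = None,
    boundary: BoundarySpec | None = None,
    picard_iterations: int = 1,
) -> np.ndarray:
    """Steady-state solution (time derivative dropped); returns T on the grid.

    With temperature-independent models the problem is linear and one solve
    suffices; otherwise a few Picard iterations refine the coefficients.
    """
    boundary = boundary or BoundarySpec()
    disc = _Discretization(phantom, boundary)
    groups = _TissueGroups(disc, models)
    n = disc.n_active
    V = disc.volumes
    rho_cb = BLOOD_DENSITY * BLOOD_SPECIFIC_HEAT
    q_active = source.q.ravel()[disc.active] if source is not None else np.zeros(n)
    T = np.full(n, boundary.initial_temperature)
    omega = np.zeros(n)
    for _ in range(max(1, picard_iterations)):
        k_cell = groups.conductivity(T)
        w_cell = groups.perfusion_rate(T, omega)
        K, u_diag, u_rhs = disc.conduction_matrix(k_cell)
        P = rho_cb * w_cell * V
        A = K + sparse.diags(P + u_diag)
        b = P * boundary.blood_temperature + u_rhs + q_active * V + groups.qmet * V
        T = spsolve(A.tocsr(), b)
        if not np.all(np.isfinite(T)):
            raise SolverError("steady solve produced non-finite temperatures")
    return _full_grid(phantom.shape, disc.active, T)


def analytic_perfused_point_source(q: float, k: float, rho_b: float, c_b: float,
                                   omega_b: float, r_mm, t_b: float = 37.0):
    """Steady temperature of a point source in an infinite perfused medium.

    T(r) = q / (4 pi k r) * exp(-r / delta) + T_b with
    delta = sqrt(k / (rho_b c_b w_b)); the pure-conduction limit is
    recovered as w_b -> 0.  Used as the closed-form oracle for the solver's
    steady homogeneous limit.  r = 0 is singular.
    """
    if min(q, k, rho_b, c_b) <= 0 or omega_b < 0:
        raise ValueError("q, k, rho_b, c_b must be positive and omega_b >= 0")
    r = np.asarray(r_mm, dtype=float) * 1e-3
    if np.any(r <= 0):
        raise ValueError("r must be positive (the point source is singular)")
    if omega_b > 0:
        delta = np.sqrt(k / (rho_b * c_b * omega_b))
        decay = np.exp(-r / delta)
    else:
        decay = 1.0
    out = q / (4.0 * np.pi * k * r) * decay + t_b
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# mesh independence

@dataclass
class ConvergenceReport:
    """Result of the axial source-profile refinement sweep."""

    spacings_mm: list
    peak_q_w_m3: list
    relative_changes: list  # between successive refinements, coarse->fine
    tolerance: float
    converged_at_mm: float | None

    @property
    def converged(self) -> bool:
        return self.converged_at_mm is not None


def mesh_convergence_check(spacings_mm, laser: LaserConfig | None = None,
                           optics: OpticalProps | None = None,
                           tolerance: float = 0.02) -> ConvergenceReport:
    """Refinement sweep of the discretized laser source.

    For each maximum element size the axisymmetric source grid is rebuilt
    (axial spacing = the element size, core radial spacing = half of it,
    node on the axis) and the peak of the axial heat-source profile is
    recorded.  Successive relative changes below ``tolerance`` flag
    convergence; the reported converged spacing is the coarser member of
    the first converged pair.
    """
    spacings = list(spacings_mm)
    if len(spacings) < 2:
        raise ValueError("at least two spacings are required")
    spacings = sorted(spacings, reverse=True)
    laser = laser or LaserConfig(power=3.0)
    optics = optics or OpticalProps()
    alpha = optics.native.effective_attenuation  # 1/mm

    peaks = []
    for dx in spacings:
        spec = PhantomSpec(
            mode="axisymmetric",
            domain_size_mm=(5.0, 30.0),
            fine_spacing_mm=dx,
            core_radius_mm=0.3,
            fine_band_mm=(1.0, 4.0),
            fiber_entry_mm=(0.0, 2.0),
            probe_lateral_mm=None,
        )
        ph = build_axisymmetric_phantom(spec)
        src = build_source_field(ph, laser, alpha)
        peaks.append(float(src.q[0, :].max()))

    changes = [abs(peaks[i + 1] - peaks[i]) / peaks[i + 1]
               for i in range(len(peaks) - 1)]
    converged_at = None
    for i, ch in enumerate(changes):
        if ch < tolerance:
            converged_at = spacings[i]
            break
    return ConvergenceReport(
        spacings_mm=spacings,
        peak_q_w_m3=peaks,
        relative_changes=changes,
        tolerance=tolerance,
        converged_at_mm=converged_at,
    )
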