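"""Bioheat solver: analytic oracles, conservation, stability properties."""

import numpy as np
import pytest

import littplan as lp
from littplan.optics import SourceField
from littplan.solver import (
    BoundarySpec,
    SolverConfig,
    analytic_perfused_point_source,
    solve,
    steady_solve,
)
from littplan.tissue import BLOOD_DENSITY, BLOOD_SPECIFIC_HEAT, BaselineProps


class TestAnalyticOracle:
    def test_conduction_limit(self):
        T = analytic_perfused_point_source(1.0, 0.52, 1050.0, 3617.0, 0.0, 5.0)
        assert T == pytest.approx(1.0 / (4 * np.pi * 0.52 * 5e-3) + 37.0)

    def test_linearity_in_source(self):
        t1 = analytic_perfused_point_source(1.0, 0.52, 1050.0, 3617.0, 0.018, 5.0)
        t2 = analytic_perfused_point_source(2.0, 0.52, 1050.0, 3617.0, 0.018, 5.0)
        assert t2 - 37.0 == pytest.approx(2 * (t1 - 37.0))

    def test_singular_at_origin(self):
        with pytest.raises(ValueError):
            analytic_perfused_point_source(1.0, 0.52, 1050.0, 3617.0, 0.018, 0.0)

    def test_against_independent_spherical_finite_difference(self):
        # 1-D spherically-symmetric steady solve at 10 um resolution:
        # (1/r^2) d/dr(r^2 k dT/dr) = rho_b c_b w_b (T - Tb), point source at 0
        k, wb = 0.52, 0.018
        s = BLOOD_DENSITY * BLOOD_SPECIFIC_HEAT * wb
        n = 4000
        dr = 1e-5
        r = dr * (np.arange(n) + 0.5)
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        rhs = np.zeros(n)
        for i in range(n):
            r_in, r_out = i * dr, (i + 1) * dr
            a_in, a_out = 4 * np.pi * r_in**2, 4 * np.pi * r_out**2
            vol = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
            if i > 0:
                main[i] += k * a_in / dr
                lower[i - 1] -= k * a_in / dr
            if i < n - 1:
                main[i] += k * a_out / dr
                upper[i] -= k * a_out / dr
            else:
                main[i] += k * a_out / (dr / 2)  # far Dirichlet at Tb
            main[i] += s * vol
        rhs[0] = 1.0  # 1 W point source in the innermost shell
        from scipy.sparse import diags
        from scipy.sparse.linalg import spsolve
        A = diags([lower, main, upper], [-1, 0, 1], format="csr")
        T = spsolve(A, rhs) + 37.0
        for r_mm in (2.0, 5.0, 8.0):
            i = int(round(r_mm * 1e-3 / dr - 0.5))
            ana = analytic_perfused_point_source(1.0, k, BLOOD_DENSITY,
                                                 BLOOD_SPECIFIC_HEAT, wb, r_mm)
            assert T[i] - 37.0 == pytest.approx(ana - 37.0, rel=0.01)


class TestSteadySolve:
    def test_robin_slab_matches_series_resistance_solution(self):
        # uniform slab: hot Dirichlet on one face, vessel-style Robin on the
        # other, insulated sides; the steady profile is linear with flux
        # q = (T_hot - T_b) / (L/k + 1/h)
        props = BaselineProps(1128.0, 0.52, 3164.0, 0.0)
        spec = lp.PhantomSpec(mode="voxel3d", domain_size_mm=(10.0, 2.0, 2.0),
                              voxel_spacing_mm=0.25,
                              tumor_semi_axes_mm=(0.6, 0.6, 0.6),
                              tumor_center_mm=(5.0, 1.0, 1.0),
                              margin_thickness_mm=0.3, pancreas_padding_mm=0.5,
                              probe_lateral_mm=None)
        ph = lp.build_voxel_phantom(spec)
        models = lp.TissueModelSet.uniform(props)
        h, t_hot, t_b, k, L = 750.0, 50.0, 37.0, 0.52, 0.01
        bc = BoundarySpec(faces={"xmin": ("dirichlet", t_hot),
                                 "xmax": ("robin", h),
                                 "ymin": ("insulated",), "ymax": ("insulated",),
                                 "zmin": ("insulated",), "zmax": ("insulated",)})
        T = steady_solve(ph, models, boundary=bc)
        x = (np.arange(ph.shape[0]) + 0.5) * 0.25e-3
        q = (t_hot - t_b) / (L / k + 1.0 / h)
        expected = t_hot - q * x / k
        rel = np.abs(T[:, 4, 4] - expected) / (expected - t_b)
        assert rel.max() < 0.005


class TestTransient:
    def test_equilibrium_is_preserved(self, axisym_phantom, default_models):
        res = solve(axisym_phantom, default_models,
                    config=SolverConfig(dt=2.0, total_time=10.0))
        assert np.nanmax(np.abs(res.temperature - 37.0)) < 1e-9

    def test_probe_heating_is_monotone_during_exposure(self, axisym_phantom,
                                                       ex_vivo_models):
        res = solve(axisym_phantom, ex_vivo_models,
                    laser=lp.LaserConfig(power=3.0),
                    config=SolverConfig(dt=2.0, total_time=120.0))
        probe = res.probe_traces["probe_0"].to_numpy()
        assert np.all(np.diff(probe) >= -1e-9)
        assert probe[-1] > probe[0]

    def test_energy_ledger_closes(self, axisym_phantom, default_models):
        res = solve(axisym_phantom, default_models,
                    laser=lp.LaserConfig(power=3.0),
                    config=SolverConfig(dt=2.0, total_time=60.0))
        assert res.ledger["closure_fraction"] < 0.02
        assert res.ledger["deposited"] > 0

    def test_maximum_principle_without_source(self):
        # implicit diffusion of a random initial field: the new extrema lie
        # inside the old ones (plus boundary temperature)
        spec = lp.PhantomSpec(mode="voxel3d", domain_size_mm=(10.0,) * 3,
                              voxel_spacing_mm=1.0,
                              tumor_semi_axes_mm=(2.0,) * 3,
                              margin_thickness_mm=1.0, pancreas_padding_mm=1.0,
                              probe_lateral_mm=None)
        ph = lp.build_voxel_phantom(spec)
        rng = np.random.default_rng(7)
        t_init = 37.0 + 20.0 * rng.random(ph.shape)
        bc = BoundarySpec(initial_temperature=37.0)
        models = lp.TissueModelSet.uniform()
        from littplan.solver import _Discretization, _TissueGroups, _linear_solve
        from scipy import sparse
        disc = _Discretization(ph, bc)
        groups = _TissueGroups(disc, models)
        T0 = t_init.ravel()[disc.active]
        k = groups.conductivity(T0)
        c = groups.heat_capacity(T0)
        K, u_diag, u_rhs = disc.conduction_matrix(k)
        S = c * disc.volumes / 2.0
        A = K + sparse.diags(S + u_diag)
        T1 = _linear_solve(A, S * T0 + u_rhs)
        assert T1.max() <= T0.max() + 1e-9
        assert T1.min() >= 37.0 - 1e-9

    def test_time_step_robustness(self, axisym_phantom, ex_vivo_models):
        # halving dt changes the final ablated volume by < 2 %
        vols = []
        for dt in (2.0, 1.0):
            res = solve(axisym_phantom, ex_vivo_models,
                        laser=lp.LaserConfig(power=3.0),
                        config=SolverConfig(dt=dt, total_time=60.0))
            v = float(np.sum(axisym_phantom.cell_volumes_m3[res.damage.ablated]))
            vols.append(v)
        assert vols[0] == pytest.approx(vols[1], rel=0.02)

    def test_vessel_robin_cools_nearby_tissue(self, voxel_phantom, default_models):
        res = solve(voxel_phantom, default_models,
                    laser=lp.LaserConfig(power=5.0),
                    config=SolverConfig(dt=2.0, total_time=30.0))
        assert "vessel:splenic_vein" in res.oar_max
        assert res.oar_max["vessel:splenic_vein"] < 45.0
        assert np.isnan(res.temperature[voxel_phantom.mask("vessel:splenic_vein")]).all()

    def test_point_source_steady_against_closed_form(self):
        # refined axisymmetric steady solve vs the perfused Green's function
        spec = lp.PhantomSpec(mode="axisymmetric", domain_size_mm=(40.0, 80.0),
                              fine_spacing_mm=0.1, core_radius_mm=1.0,
                              fine_band_mm=(2.0, 2.0), growth=1.2,
                              max_spacing_mm=0.5, fiber_entry_mm=(0.0, 40.0),
                              probe_lateral_mm=None)
        ph = lp.build_axisymmetric_phantom(spec)
        models = lp.TissueModelSet.constant()  # pancreas w0 = 0.018 1/s
        q = np.zeros(ph.shape)
        j = int(np.argmin(np.abs(ph.z_nodes_mm - 40.0)))
        q[0, j] = 1.0 / ph.cell_volumes_m3[0, j]
        src = SourceField(q=q, deposited_power=1.0, beam_power=1.0)
        T = steady_solve(ph, models, source=src)
        for r_mm in (2.0, 3.0, 5.0, 8.0, 10.0):
            i = int(np.argmin(np.abs(ph.r_nodes_mm - r_mm)))
            ana = analytic_perfused_point_source(
                1.0, 0.52, BLOOD_DENSITY, BLOOD_SPECIFIC_HEAT, 0.018,
                ph.r_nodes_mm[i])
            assert T[i, j] - 37.0 == pytest.approx(ana - 37.0, rel=0.02)


class TestMeshConvergence:
    def test_sweep_converges_at_004(self):
        rep = lp.mesh_convergence_check([0.12, 0.08, 0.04, 0.02])
        assert rep.converged_at_mm == pytest.approx(0.04)
        assert rep.relative_changes[0] > rep.tolerance
        assert rep.relative_changes[-1] < rep.tolerance

    def test_single_spacing_rejected(self):
        with pytest.raises(ValueError):
            lp.mesh_convergence_check([0.04])

    def test_identical_spacings_give_zero_change(self):
        rep = lp.mesh_convergence_check([0.08, 0.08])
        assert rep.relative_changes == [0.0]
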