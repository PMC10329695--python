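"""Damage accumulation, ablation metrics, dose grid and selection logic."""

import numpy as np
import pandas as pd
import pytest

import littplan as lp
from littplan.dosimetry import (
    DamageField,
    DamageModelConfig,
    DoseGrid,
    accumulate_damage,
    select_optimal_dose,
)


def _grid(abl: dict, oar: dict | None = None):
    """Synthetic DoseGrid from {(power, duration): value} mappings."""
    powers = sorted({p for p, _ in abl})
    durations = sorted({t for _, t in abl})
    a = pd.DataFrame(np.nan, index=durations, columns=powers)
    o = pd.DataFrame(np.nan, index=durations, columns=powers)
    for (p, t), v in abl.items():
        a.loc[t, p] = v
    for (p, t), v in (oar or {}).items():
        o.loc[t, p] = v
    return DoseGrid(ablated_pct=a, oar_max_c=o, ablated_volume_mm3=a.copy())


class TestDamageModel:
    def test_exact_dwell_time_gives_full_necrosis(self):
        cfg = DamageModelConfig(damage_temperature=60.0, necrosis_time=1.0)
        hist = np.array([[37.0], [65.0], [65.0]])  # two 0.5 s steps above
        dmg = accumulate_damage(hist, cfg, dt=0.5)
        assert dmg.omega[0] == pytest.approx(1.0)

    def test_never_above_threshold_gives_zero(self):
        cfg = DamageModelConfig()
        hist = np.full((100, 3), 55.0)
        assert np.all(accumulate_damage(hist, cfg, dt=1.0).omega == 0.0)

    def test_theta_linear_in_dwell_time(self):
        cfg = DamageModelConfig(necrosis_time=4.0)
        hist = np.array([37.0, 61.0, 61.0, 37.0])[:, None]  # 2 s above
        dmg = accumulate_damage(hist, cfg, dt=1.0)
        assert dmg.theta[0] == pytest.approx(0.5)
        assert dmg.omega[0] == pytest.approx(0.5)

    def test_omega_saturates_at_one(self):
        cfg = DamageModelConfig()
        hist = np.full((100, 1), 70.0)
        dmg = accumulate_damage(hist, cfg, dt=1.0)
        assert dmg.theta[0] == pytest.approx(99.0)
        assert dmg.omega[0] == 1.0


class TestAblationMetrics:
    def test_half_ablated_target(self, axisym_phantom, ex_vivo_models):
        # synthetic damage: ablate the tumor-sized inner half of a target
        # whose margin half equals the tumor half -> 50 % ablated fraction
        ph = axisym_phantom
        res = lp.solve(ph, ex_vivo_models,
                       config=lp.SolverConfig(dt=2.0, total_time=4.0))
        R, Z = np.meshgrid(ph.r_nodes_mm, ph.z_nodes_mm, indexing="ij")
        vols = ph.cell_volumes_m3
        r2 = R**2 + (Z - 15.0) ** 2
        inner = r2 <= 4.0**2
        # choose outer radius so the shell volume matches the inner volume
        from dataclasses import replace
        label = ph.label_grid.copy()
        label[inner] = 2  # tumor
        shell = (r2 > 4.0**2) & (r2 <= (4.0 * 2 ** (1 / 3)) ** 2)
        label[shell] = 3  # margin
        ph2 = replace(ph, label_grid=label)
        dmg = DamageField(theta=np.where(inner, 1.0, 0.0))
        met = lp.ablation_metrics(res, ph2, damage=dmg)
        v_in = vols[inner].sum()
        v_sh = vols[shell].sum()
        expected = 100.0 * v_in / (v_in + v_sh)
        assert expected == pytest.approx(50.0, abs=2.0)  # voxelization error
        assert met.ablated_fraction_pct == pytest.approx(expected, rel=1e-9)

    def test_zero_damage_zero_metrics(self, axisym_phantom, ex_vivo_models):
        res = lp.solve(axisym_phantom, ex_vivo_models,
                       config=lp.SolverConfig(dt=2.0, total_time=4.0))
        met = lp.ablation_metrics(res, axisym_phantom)
        assert met.ablated_volume_mm3 == 0.0

    def test_ablated_region_tracks_60c_isotherm(self, axisym_phantom,
                                                ex_vivo_models):
        # with t_n << exposure, the Omega=1 area approximates the 60 degC
        # region at end of exposure
        res = lp.solve(axisym_phantom, ex_vivo_models,
                       laser=lp.LaserConfig(power=3.0),
                       config=lp.SolverConfig(dt=2.0, total_time=120.0))
        met = lp.ablation_metrics(res, axisym_phantom)
        from littplan.dosimetry import _cross_section_area
        abl_area = _cross_section_area(axisym_phantom, res.damage.ablated)
        assert abl_area == pytest.approx(met.isotherm_areas_mm2[60.0], rel=0.25)


class TestDoseSelection:
    def test_minimum_power_preferred(self):
        g = _grid({(7.0, 550.0): 58.0, (8.0, 450.0): 60.0},
                  {(7.0, 550.0): 41.0, (8.0, 450.0): 41.5})
        sel = select_optimal_dose(g)
        assert (sel.power_w, sel.duration_s) == (7.0, 550.0)

    def test_none_when_nothing_qualifies(self):
        g = _grid({(2.0, 100.0): 10.0, (3.0, 200.0): 30.0})
        assert select_optimal_dose(g) is None

    def test_single_qualifier_selected(self):
        g = _grid({(5.0, 550.0): 56.0}, {(5.0, 550.0): 39.0})
        sel = select_optimal_dose(g)
        assert (sel.power_w, sel.duration_s) == (5.0, 550.0)
        assert sel.energy_j == 2750.0

    def test_oar_limit_disqualifies(self):
        g = _grid({(5.0, 550.0): 70.0, (6.0, 300.0): 60.0},
                  {(5.0, 550.0): 43.5, (6.0, 300.0): 41.0})
        sel = select_optimal_dose(g, oar_limit_c=42.0)
        assert sel.power_w == 6.0

    def test_tie_broken_by_minimum_duration(self):
        g = _grid({(5.0, 300.0): 56.0, (5.0, 550.0): 60.0})
        sel = select_optimal_dose(g)
        assert sel.duration_s == 300.0

    def test_selection_never_dominated(self):
        g = _grid({(5.0, 300.0): 56.0, (5.0, 250.0): 55.5, (6.0, 100.0): 57.0})
        sel = select_optimal_dose(g)
        assert (sel.power_w, sel.duration_s) == (5.0, 250.0)

    def test_raising_threshold_never_lowers_power(self):
        g = _grid({(4.0, 500.0): 55.0, (6.0, 500.0): 70.0, (8.0, 500.0): 85.0})
        powers = []
        for thr in (55.0, 65.0, 80.0):
            sel = select_optimal_dose(g, ablation_threshold_pct=thr)
            powers.append(sel.power_w)
        assert powers == sorted(powers)

    def test_energy_is_exact_product(self):
        for p, t, e in ((5.0, 550.0, 2750.0), (8.0, 550.0, 4400.0)):
            g = _grid({(p, t): 60.0})
            assert select_optimal_dose(g).energy_j == e


class TestDoseGridSearch:
    def test_grid_monotonicity_and_selection(self, axisym_phantom,
                                             default_models, target_ball):
        grid = lp.dose_grid_search(axisym_phantom, default_models,
                                   powers=[2.0, 5.0, 8.0],
                                   durations=[60.0, 120.0, 180.0],
                                   target_mask=target_ball)
        a = grid.ablated_pct
        assert a.notna().all().all()
        # non-decreasing in duration at fixed power and in power at fixed time
        assert (a.diff().fillna(0) >= -1e-9).all().all()
        assert (a.diff(axis=1).fillna(0) >= -1e-9).all().all()
        sel = select_optimal_dose(grid, ablation_threshold_pct=2.5)
        assert sel is not None
        assert sel.energy_j == sel.power_w * sel.duration_s

    def test_singleton_grid(self, axisym_phantom, ex_vivo_models, target_ball):
        grid = lp.dose_grid_search(axisym_phantom, ex_vivo_models,
                                   powers=[2.0], durations=[50.0],
                                   target_mask=target_ball)
        assert grid.ablated_pct.shape == (1, 1)
        assert np.isfinite(grid.ablated_pct.iloc[0, 0])
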