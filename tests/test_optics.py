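"""Laser source: attenuation, Gaussian irradiance, blending, deposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import littplan as lp
from littplan.optics import OpticalProps


class TestEffectiveAttenuation:
    def test_native_table_value(self):
        assert lp.effective_attenuation(0.018, 4.34, 0.93) == pytest.approx(
            0.1318, abs=2e-4)

    def test_coagulated_table_value(self):
        assert lp.effective_attenuation(0.011, 30.46, 0.92) == pytest.approx(
            0.2842, abs=2e-4)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(1e-4, 10.0), g=st.floats(0.0, 1.0))
    def test_scattering_free_limit(self, a, g):
        assert lp.effective_attenuation(a, 0.0, g) == pytest.approx(a * np.sqrt(3))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lp.effective_attenuation(-0.1, 1.0, 0.9)


class TestIrradiance:
    def test_peak_value(self):
        cfg = lp.LaserConfig(power=3.0, sigma_um=50.0)
        assert lp.irradiance(0.0, 0.0, cfg) == pytest.approx(1.910e8, rel=1e-3)

    def test_plane_integral_equals_power(self):
        cfg = lp.LaserConfig(power=3.0, sigma_um=50.0)
        x = np.linspace(-400, 400, 801)  # um
        X, Y = np.meshgrid(x, x)
        integral = np.trapezoid(np.trapezoid(lp.irradiance(X, Y, cfg), x * 1e-6),
                                x * 1e-6)
        assert integral == pytest.approx(cfg.power, rel=1e-3)

    def test_core_containment_is_99_percent(self):
        cfg = lp.LaserConfig(power=3.0, sigma_um=50.0, fiber_radius_um=150.0)
        frac = lp.enclosed_power_fraction(cfg.fiber_radius_um, cfg)
        assert frac == pytest.approx(1 - np.exp(-4.5), rel=1e-12)
        assert round(100 * frac) == 99

    def test_sigma_must_fit_in_core(self):
        with pytest.raises(ValueError):
            lp.LaserConfig(power=3.0, sigma_um=200.0, fiber_radius_um=150.0)


class TestBlending:
    def test_endpoints_exact(self):
        props = OpticalProps()
        assert lp.blend_optics(0.0, props) == props.native
        assert lp.blend_optics(1.0, props) == props.coagulated

    def test_midpoint_means(self):
        c = lp.blend_optics(0.5, OpticalProps())
        assert c.absorption == pytest.approx(0.0145)
        assert c.scattering == pytest.approx(17.4)
        assert c.anisotropy == pytest.approx(0.925)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.blend_optics(1.5, OpticalProps())

    @settings(max_examples=50, derandomize=True)
    @given(om=st.floats(0.0, 1.0))
    def test_blend_is_convex_and_raises_attenuation(self, om):
        props = OpticalProps()
        c = lp.blend_optics(om, props)
        lo = min(props.native.effective_attenuation,
                 props.coagulated.effective_attenuation)
        hi = max(props.native.effective_attenuation,
                 props.coagulated.effective_attenuation)
        assert lo - 1e-12 <= c.effective_attenuation <= hi + 1e-12


class TestSourceField:
    def test_semi_infinite_conservation(self):
        # long homogeneous axisymmetric domain captures the whole beam
        spec = lp.PhantomSpec(mode="axisymmetric", domain_size_mm=(10.0, 60.0),
                              fine_spacing_mm=0.04, fiber_entry_mm=(0.0, 2.0),
                              probe_lateral_mm=None)
        ph = lp.build_axisymmetric_phantom(spec)
        alpha = OpticalProps().native.effective_attenuation
        src = lp.build_source_field(ph, lp.LaserConfig(power=3.0), alpha)
        assert src.deposited_power == pytest.approx(3.0, rel=0.01)
        assert src.deposited_power <= 3.0 + 1e-9
        assert np.all(src.q >= 0)

    def test_no_source_upstream_of_tip(self):
        spec = lp.PhantomSpec(mode="axisymmetric", domain_size_mm=(10.0, 60.0),
                              fine_spacing_mm=0.08, fiber_entry_mm=(0.0, 30.0),
                              probe_lateral_mm=None)
        ph = lp.build_axisymmetric_phantom(spec)
        src = lp.build_source_field(ph, lp.LaserConfig(power=3.0), 0.13)
        upstream = ph.z_edges_mm[1:] <= 30.0 - 1e-9
        assert np.all(src.q[:, upstream] == 0.0)

    def test_axial_decay_one_attenuation_length(self):
        alpha = 0.2  # 1/mm
        spec = lp.PhantomSpec(mode="axisymmetric", domain_size_mm=(10.0, 60.0),
                              fine_spacing_mm=0.02, fine_band_mm=(1.0, 8.0),
                              fiber_entry_mm=(0.0, 2.0), probe_lateral_mm=None)
        ph = lp.build_axisymmetric_phantom(spec)
        src = lp.build_source_field(ph, lp.LaserConfig(power=3.0), alpha)
        prof = src.q[0, :]
        j0 = np.argmax(prof)
        z = ph.z_nodes_mm - 2.0
        j1 = np.argmin(np.abs(z - 1.0 / alpha))
        assert prof[j1] / prof[j0] == pytest.approx(np.exp(-1.0), rel=0.02)

    def test_voxel_mode_conserves_power(self, voxel_phantom):
        src = lp.build_source_field(voxel_phantom, lp.LaserConfig(power=5.0), 0.1318)
        vol = voxel_phantom.cell_volumes_m3
        assert src.deposited_power == pytest.approx(float((src.q * vol).sum()))
        assert src.deposited_power <= 5.0
        # the 40 mm path from the center captures most of the beam
        assert src.deposited_power >= 5.0 * (1 - np.exp(-0.1318 * 20) ) * 0.98

    def test_oblique_direction_rejected(self, voxel_phantom):
        from dataclasses import replace
        ph = replace(voxel_phantom,
                     fiber_direction=np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        with pytest.raises(lp.UnsupportedModeError):
            lp.build_source_field(ph, lp.LaserConfig(power=3.0), 0.13)

    def test_coagulation_shifts_deposition_toward_fiber(self):
        spec = lp.PhantomSpec(mode="axisymmetric", domain_size_mm=(10.0, 60.0),
                              fine_spacing_mm=0.08, fiber_entry_mm=(0.0, 5.0),
                              probe_lateral_mm=None)
        ph = lp.build_axisymmetric_phantom(spec)
        props = OpticalProps()
        nat = lp.build_source_field(ph, lp.LaserConfig(power=3.0),
                                    props.native.effective_attenuation)
        coa = lp.build_source_field(ph, lp.LaserConfig(power=3.0),
                                    props.coagulated.effective_attenuation)
        near = ph.z_nodes_mm < 10.0
        vols = ph.cell_volumes_m3
        assert (coa.q[:, near] * vols[:, near]).sum() > \
            (nat.q[:, near] * vols[:, near]).sum()
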