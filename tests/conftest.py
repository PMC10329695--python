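"""Shared fixtures: small phantoms and model sets built at test time."""

import numpy as np
import pytest

import littplan as lp


@pytest.fixture(scope="session")
def axisym_phantom():
    """Small homogeneous (r, z) phantom, moderately refined near the source."""
    spec = lp.PhantomSpec(
        mode="axisymmetric",
        domain_size_mm=(20.0, 50.0),
        fine_spacing_mm=0.08,
        fiber_entry_mm=(0.0, 15.0),
        probe_lateral_mm=10.0,
    )
    return lp.build_axisymmetric_phantom(spec)


@pytest.fixture(scope="session")
def voxel_phantom():
    """40 mm cube with a 6 mm spherical tumor, 3 mm margin and one vessel."""
    vessel = lp.VesselSpec("splenic_vein", (32.0, 20.0, 0.0),
                           (32.0, 20.0, 40.0), 2.5, 750.0)
    spec = lp.PhantomSpec(
        mode="voxel3d",
        domain_size_mm=(40.0, 40.0, 40.0),
        voxel_spacing_mm=1.0,
        tumor_semi_axes_mm=(6.0, 6.0, 6.0),
        tumor_center_mm=(20.0, 20.0, 20.0),
        margin_thickness_mm=3.0,
        vessels=(vessel,),
        probe_lateral_mm=15.0,
    )
    return lp.build_voxel_phantom(spec)


@pytest.fixture(scope="session")
def default_models():
    return lp.TissueModelSet.default()


@pytest.fixture(scope="session")
def ex_vivo_models():
    return lp.TissueModelSet.ex_vivo()


@pytest.fixture
def target_ball(axisym_phantom):
    """8 mm spherical target around the fiber tip (stand-in tumor+margin)."""
    ph = axisym_phantom
    R, Z = np.meshgrid(ph.r_nodes_mm, ph.z_nodes_mm, indexing="ij")
    return R**2 + (Z - ph.fiber_tip_mm[1])**2 <= 8.0**2
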