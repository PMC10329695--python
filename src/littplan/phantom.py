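"""Synthetic anatomies for LITT planning.

Two phantom families stand in for patient imaging:

* ``voxel3d`` — a labeled uniform voxel grid holding an ellipsoidal tumor,
  a safety-margin shell obtained by true Euclidean dilation of the tumor,
  a surrounding pancreas ellipsoid, optional cylindrical vessels (whose
  surfaces carry convective Robin boundaries and whose interiors are
  excluded from the conduction domain), an optional duodenum slab, a
  soft-tissue shell between pancreas and vessels, and an embedding
  background cube whose outer surface is the fixed-temperature boundary.

* ``axisymmetric`` — a homogeneous (r, z) half-plane with the fiber on the
  axis and a graded mesh refined near the source, matching bench
  experiments on excised tissue and used for fast dose sweeps.

Coordinates are physical millimetres measured from the domain corner
(3-D) or from (r=0, z=0) (axisymmetric); voxel values live at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from littplan.errors import GeometryError, ResolutionError, UnsupportedModeError

__all__ = [
    "VesselSpec",
    "DuodenumSpec",
    "PhantomSpec",
    "VoxelPhantom",
    "build_voxel_phantom",
    "build_axisymmetric_phantom",
    "place_probes",
]

# Fixed label codes; vessels are appended from 6 upward.
LABEL_BACKGROUND = 0
LABEL_PANCREAS = 1
LABEL_TUMOR = 2
LABEL_MARGIN = 3
LABEL_SOFT_TISSUE = 4
LABEL_DUODENUM = 5
_FIRST_VESSEL_LABEL = 6

_BASE_LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_PANCREAS: "pancreas",
    LABEL_TUMOR: "tumor",
    LABEL_MARGIN: "margin",
    LABEL_SOFT_TISSUE: "soft_tissue",
    LABEL_DUODENUM: "duodenum",
}

#: Material used for thermal properties of each non-vessel label.  The
#: margin is pancreatic parenchyma by definition; the background cube is
#: generic soft tissue.
TISSUE_OF_LABEL = {
    "background": "soft_tissue",
    "pancreas": "pancreas",
    "tumor": "tumor",
    "margin": "pancreas",
    "soft_tissue": "soft_tissue",
    "duodenum": "duodenum",
}


@dataclass(frozen=True)
class VesselSpec:
    """Cylindrical vessel segment carrying a convective boundary."""

    name: str
    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    h: float  # convective coefficient, W/(m^2 K)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("vessel radius must be positive")
        if self.h < 0:
            raise ValueError("vessel h must be non-negative")


@dataclass(frozen=True)
class DuodenumSpec:
    """Duodenum slab normal to x, offset from the tumor surface."""

    thickness_mm: float = 5.0
    offset_mm: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic phantom."""

    mode: str = "voxel3d"  # voxel3d | axisymmetric
    domain_size_mm: tuple = (60.0, 60.0, 60.0)  # (Lx,Ly,Lz) or (r_max, z_len)
    voxel_spacing_mm: float = 0.5
    tumor_semi_axes_mm: tuple[float, float, float] | None = None
    tumor_center_mm: tuple[float, float, float] | None = None
    margin_thickness_mm: float = 5.0
    pancreas_padding_mm: float = 10.0
    soft_tissue_shell_mm: float = 1.0
    vessels: tuple[VesselSpec, ...] = ()
    duodenum: DuodenumSpec | None = None
    fiber_entry_mm: tuple | None = None  # emitting tip position
    fiber_direction: tuple = (0.0, 0.0, 1.0)
    fiber_radius_um: float = 150.0
    probe_lateral_mm: float | None = 15.0
    # axisymmetric grading parameters
    fine_spacing_mm: float = 0.04  # axial spacing near the source
    core_radius_mm: float = 0.3  # radially fine out to here
    fine_band_mm: tuple[float, float] = (2.0, 5.0)  # fine axial band before/after tip
    growth: float = 1.3
    max_spacing_mm: float = 1.0

    def validated(self) -> "PhantomSpec":
        if self.mode not in ("voxel3d", "axisymmetric"):
            raise ValueError(f"unknown phantom mode {self.mode!r}")
        if self.voxel_spacing_mm <= 0 or self.fine_spacing_mm <= 0:
            raise ResolutionError("grid spacing must be positive")
        d = np.asarray(self.fiber_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise GeometryError("fiber direction must be a unit vector")
        if self.margin_thickness_mm < 0:
            raise GeometryError("margin thickness must be non-negative")
        for v in self.vessels:
            if v.radius_mm <= 0:
                raise GeometryError(f"vessel {v.name} has non-positive radius")
        if self.mode == "voxel3d":
            if self.tumor_semi_axes_mm is None:
                raise GeometryError("voxel3d phantom requires tumor_semi_axes_mm")
            if len(self.domain_size_mm) != 3:
                raise GeometryError("voxel3d domain_size_mm must have 3 entries")
            if (self.margin_thickness_mm > 0
                    and self.voxel_spacing_mm > self.margin_thickness_mm):
                raise ResolutionError(
                    "voxel spacing coarser than the safety-margin thickness")
            center = self.resolved_tumor_center()
            axes = np.asarray(self.tumor_semi_axes_mm, dtype=float)
            size = np.asarray(self.domain_size_mm, dtype=float)
            clearance = self.margin_thickness_mm
            if np.any(center - axes - clearance < 0) or np.any(
                    center + axes + clearance > size):
                raise GeometryError(
                    "tumor plus margin clearance does not fit inside the domain")
        else:
            if len(self.domain_size_mm) != 2:
                raise GeometryError("axisymmetric domain_size_mm is (r_max, z_len)")
            if self.vessels or self.duodenum is not None:
                raise UnsupportedModeError(
                    "vessels/duodenum are not supported in axisymmetric mode")
        return self

    def resolved_tumor_center(self) -> np.ndarray:
        if self.tumor_center_mm is not None:
            return np.asarray(self.tumor_center_mm, dtype=float)
        return np.asarray(self.domain_size_mm, dtype=float) / 2.0


@dataclass
class VoxelPhantom:
    """Labeled synthetic geometry, either a 3-D voxel grid or an (r, z) mesh."""

    mode: str
    label_grid: np.ndarray  # int labels; (nx,ny,nz) or (nr,nz)
    label_names: dict[int, str]
    fiber_tip_mm: np.ndarray  # (3,) or (2,) = (0, z_tip)
    fiber_direction: np.ndarray
    spacing_mm: tuple | None = None  # uniform spacing, voxel3d only
    r_nodes_mm: np.ndarray | None = None  # axisymmetric node/edge geometry
    r_edges_mm: np.ndarray | None = None
    z_nodes_mm: np.ndarray | None = None
    z_edges_mm: np.ndarray | None = None
    vessel_h_by_label: dict[int, float] = field(default_factory=dict)
    probe_points_mm: list = field(default_factory=list)
    fiber_axis_voxels: list = field(default_factory=list)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.label_grid.shape

    @property
    def domain_size_mm(self) -> np.ndarray:
        if self.mode == "voxel3d":
            return np.asarray(self.spacing_mm) * np.asarray(self.shape)
        return np.asarray([self.r_edges_mm[-1], self.z_edges_mm[-1]])

    @property
    def cell_volumes_m3(self) -> np.ndarray:
        """Cell volumes in m^3, broadcast to the grid shape."""
        if self.mode == "voxel3d":
            v = float(np.prod(self.spacing_mm)) * 1e-9
            return np.full(self.shape, v)
        ring = np.pi * (self.r_edges_mm[1:] ** 2 - self.r_edges_mm[:-1] ** 2)
        dz = np.diff(self.z_edges_mm)
        return ring[:, None] * dz[None, :] * 1e-9

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {name: self.label_grid == code
                for code, name in self.label_names.items()}

    def mask(self, name: str) -> np.ndarray:
        for code, nm in self.label_names.items():
            if nm == name:
                return self.label_grid == code
        raise KeyError(name)

    @property
    def vessel_labels(self) -> list[int]:
        return sorted(self.vessel_h_by_label)

    def label_volumes_mm3(self) -> dict[str, float]:
        vols = self.cell_volumes_m3 * 1e9
        return {name: float(vols[self.label_grid == code].sum())
                for code, name in self.label_names.items()}

    def tissue_name_of_label(self, code: int) -> str:
        name = self.label_names[code]
        if code in self.vessel_h_by_label:
            return "blood"
        return TISSUE_OF_LABEL.get(name, "soft_tissue")


def _voxel_centers(shape, spacing):
    axes = [spacing[i] * (np.arange(shape[i]) + 0.5) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(coords, center, semi_axes):
    x, y, z = coords
    a, b, c = semi_axes
    return ((x - center[0]) / a) ** 2 + ((y - center[1]) / b) ** 2 + (
        (z - center[2]) / c) ** 2 <= 1.0


def _cylinder_mask(coords, start, end, radius):
    p = np.stack([c.ravel() for c in coords], axis=1)
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise GeometryError("vessel segment has zero length")
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    d2 = np.sum((p - closest) ** 2, axis=1)
    return (d2 <= radius * radius).reshape(coords[0].shape)


def build_voxel_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Build the labeled 3-D voxel phantom from its spec.

    The tumor is an analytic ellipsoid voxelized at cell centers; the safety
    margin is the Euclidean dilation of the tumor by the margin thickness
    (distance-transform based), minus the tumor itself.
    """
    spec = spec.validated()
    if spec.mode != "voxel3d":
        raise UnsupportedModeError("build_voxel_phantom requires mode='voxel3d'")
    h = float(spec.voxel_spacing_mm)
    size = np.asarray(spec.domain_size_mm, dtype=float)
    shape = tuple(int(round(s / h)) for s in size)
    coords = _voxel_centers(shape, (h, h, h))
    center = spec.resolved_tumor_center()

    label = np.full(shape, LABEL_BACKGROUND, dtype=np.int16)

    tumor = _ellipsoid_mask(coords, center, spec.tumor_semi_axes_mm)
    if not tumor.any():
        raise GeometryError("tumor ellipsoid contains no voxels at this spacing")

    panc_axes = np.asarray(spec.tumor_semi_axes_mm) + spec.margin_thickness_mm \
        + spec.pancreas_padding_mm
    pancreas = _ellipsoid_mask(coords, center, panc_axes)
    label[pancreas] = LABEL_PANCREAS

    if spec.margin_thickness_mm > 0:
        dist = ndimage.distance_transform_edt(~tumor, sampling=(h, h, h))
        margin = (dist <= spec.margin_thickness_mm) & ~tumor
    else:
        margin = np.zeros(shape, dtype=bool)
    label[margin] = LABEL_MARGIN
    label[tumor] = LABEL_TUMOR

    if spec.duodenum is not None:
        x0 = center[0] + spec.tumor_semi_axes_mm[0] + spec.duodenum.offset_mm
        duo = (coords[0] >= x0) & (coords[0] <= x0 + spec.duodenum.thickness_mm)
        duo &= ~tumor & ~margin
        label[duo] = LABEL_DUODENUM

    label_names = dict(_BASE_LABEL_NAMES)
    vessel_h: dict[int, float] = {}
    vessel_masks = []
    for i, v in enumerate(spec.vessels):
        code = _FIRST_VESSEL_LABEL + i
        mask = _cylinder_mask(coords, v.start_mm, v.end_mm, v.radius_mm)
        if not mask.any():
            raise GeometryError(f"vessel {v.name} contains no voxels")
        vessel_masks.append(mask)
        label_names[code] = f"vessel:{v.name}"
        vessel_h[code] = v.h

    if vessel_masks and spec.soft_tissue_shell_mm > 0:
        allv = np.logical_or.reduce(vessel_masks)
        dshell = ndimage.distance_transform_edt(~allv, sampling=(h, h, h))
        shell = (dshell <= spec.soft_tissue_shell_mm) & ~allv
        shell &= ~tumor & ~margin
        label[shell] = LABEL_SOFT_TISSUE
    for i, mask in enumerate(vessel_masks):
        label[mask] = _FIRST_VESSEL_LABEL + i

    direction = np.asarray(spec.fiber_direction, dtype=float)
    direction /= np.linalg.norm(direction)
    tip = (np.asarray(spec.fiber_entry_mm, dtype=float)
           if spec.fiber_entry_mm is not None else center.copy())
    if np.any(tip < 0) or np.any(tip > size):
        raise GeometryError("fiber tip lies outside the domain")

    phantom = VoxelPhantom(
        mode="voxel3d",
        label_grid=label,
        label_names=label_names,
        fiber_tip_mm=tip,
        fiber_direction=direction,
        spacing_mm=(h, h, h),
        vessel_h_by_label=vessel_h,
    )
    phantom.fiber_axis_voxels = _trace_fiber_voxels(phantom)
    if spec.probe_lateral_mm is not None:
        phantom = place_probes(phantom, spec.probe_lateral_mm)
    return phantom


def _trace_fiber_voxels(phantom: VoxelPhantom) -> list:
    """Ordered voxel indices along the beam from the tip to the boundary."""
    h = np.asarray(phantom.spacing_mm, dtype=float)
    size = phantom.domain_size_mm
    pos = phantom.fiber_tip_mm.astype(float).copy()
    d = phantom.fiber_direction
    step = float(min(h)) / 2.0
    seen: list = []
    while np.all(pos >= 0) and np.all(pos <= size):
        idx = tuple(np.clip((pos // h).astype(int), 0, np.asarray(phantom.shape) - 1))
        if not seen or seen[-1] != idx:
            seen.append(idx)
        pos = pos + step * d
    return seen


def _graded_nodes_1d(start, stop, fine, fine_until, growth, max_step):
    """Ascending nodes from ``start``: spacing ``fine`` until ``fine_until``,
    then geometric growth capped at ``max_step``, ending before ``stop``."""
    nodes = [start]
    step = fine
    while nodes[-1] + step < stop - 1e-12:
        if nodes[-1] >= fine_until:
            step = min(step * growth, max_step)
        nodes.append(nodes[-1] + step)
    return np.asarray(nodes)


def build_axisymmetric_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Homogeneous (r, z) phantom with the fiber on the axis.

    The radial mesh is node-centred (a node sits exactly on the axis, so the
    first cell spans half the fine spacing) and graded geometrically away
    from the core; the axial mesh is fine in a band around the fiber tip.
    The transverse beam scale (sigma = 50 um) is far below the axial
    attenuation length, so the core radial spacing is half the axial fine
    spacing.  All cells are pancreatic tissue.
    """
    spec = spec.validated()
    if spec.mode != "axisymmetric":
        raise UnsupportedModeError(
            "build_axisymmetric_phantom requires mode='axisymmetric'")
    r_max, z_len = (float(v) for v in spec.domain_size_mm)
    z_tip = (spec.fiber_entry_mm[-1] if spec.fiber_entry_mm is not None
             else z_len / 3.0)
    if not (0.0 <= z_tip <= z_len):
        raise GeometryError("fiber tip lies outside the axial domain")

    fine_r = spec.fine_spacing_mm / 2.0
    r_nodes = _graded_nodes_1d(0.0, r_max, fine_r, spec.core_radius_mm,
                               spec.growth, spec.max_spacing_mm)
    r_edges = np.concatenate([[0.0], 0.5 * (r_nodes[:-1] + r_nodes[1:]), [r_max]])

    before, after = spec.fine_band_mm
    up = _graded_nodes_1d(0.0, z_tip, spec.fine_spacing_mm, before,
                          spec.growth, spec.max_spacing_mm)
    down = _graded_nodes_1d(0.0, z_len - z_tip, spec.fine_spacing_mm, after,
                            spec.growth, spec.max_spacing_mm)
    z_nodes = np.unique(np.concatenate([z_tip - up, z_tip + down]))
    z_nodes = z_nodes[(z_nodes >= 0.0) & (z_nodes <= z_len)]
    z_edges = np.concatenate([[0.0], 0.5 * (z_nodes[:-1] + z_nodes[1:]), [z_len]])

    label = np.full((len(r_nodes), len(z_nodes)), LABEL_PANCREAS, dtype=np.int16)
    phantom = VoxelPhantom(
        mode="axisymmetric",
        label_grid=label,
        label_names=dict(_BASE_LABEL_NAMES),
        fiber_tip_mm=np.asarray([0.0, z_tip]),
        fiber_direction=np.asarray([0.0, 1.0]),
        r_nodes_mm=r_nodes,
        r_edges_mm=r_edges,
        z_nodes_mm=z_nodes,
        z_edges_mm=z_edges,
    )
    if spec.probe_lateral_mm is not None:
        phantom = place_probes(phantom, spec.probe_lateral_mm)
    return phantom


def place_probes(phantom: VoxelPhantom, lateral_distance_mm: float) -> VoxelPhantom:
    """Place temperature probes at a perpendicular distance from the fiber axis.

    In 3-D two probes are placed symmetrically about the axis in the plane
    through the tip; in axisymmetric mode the two symmetric probes coincide
    at (r = distance, z = tip).  Probes outside the domain raise
    :class:`GeometryError`.
    """
    if lateral_distance_mm < 0:
        raise GeometryError("lateral distance must be non-negative")
    if phantom.mode == "axisymmetric":
        r_max = float(phantom.r_edges_mm[-1])
        if lateral_distance_mm > r_max:
            raise GeometryError("probe lies outside the radial domain")
        pts = [np.asarray([lateral_distance_mm, phantom.fiber_tip_mm[1]])]
    else:
        d = phantom.fiber_direction
        ref = np.eye(3)[int(np.argmin(np.abs(d)))]
        perp = np.cross(d, ref)
        perp /= np.linalg.norm(perp)
        size = phantom.domain_size_mm
        pts = []
        for s in (+1.0, -1.0):
            p = phantom.fiber_tip_mm + s * lateral_distance_mm * perp
            if np.any(p < 0) or np.any(p > size):
                raise GeometryError("probe lies outside the domain")
            pts.append(p)
    return replace(phantom, probe_points_mm=pts)
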