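"""Configuration loading, NIfTI/VTK/CSV/JSON writers, provenance.

File conventions: YAML run configs; one integer NIfTI label volume per 3-D
phantom plus a JSON sidecar holding spacing, fiber, probes and per-vessel
convective coefficients; legacy-ASCII VTK for field snapshots (diffable
text); CSV for traces, ledgers and dose tables; JSON for scalar results.
All lengths are mm measured from the domain corner, voxel values at cell
centers; every output carries a provenance block (config hash, package
version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from littplan import __version__ as _version
from littplan.errors import ConfigError, UnsupportedModeError
from littplan.phantom import DuodenumSpec, PhantomSpec, VesselSpec, VoxelPhantom

__all__ = [
    "RunConfig",
    "load_run_config",
    "phantom_to_nifti",
    "phantom_from_nifti",
    "write_vtk",
    "provenance",
]


@dataclass
class RunConfig:
    """Bundle of everything one run needs, as parsed from YAML."""

    phantom: PhantomSpec
    laser_power_w: float = 3.0
    laser_duration_s: float = 300.0
    sigma_um: float = 50.0
    fiber_radius_um: float = 150.0
    dt_s: float = 2.0
    temperature_cap_c: float = 150.0
    damage_temperature_c: float = 60.0
    necrosis_time_s: float = 1.0
    tissues: str = "default"  # default | ex_vivo | constant
    powers_w: tuple = tuple(float(p) for p in range(2, 11))
    durations_s: tuple = tuple(float(t) for t in range(50, 601, 50))
    ablation_threshold_pct: float = 55.0
    oar_limit_c: float = 42.0
    target_radius_mm: float | None = None  # homogeneous-phantom target ball
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def _get(d: dict, key: str, default=None, required=False, context=""):
    if key in d:
        return d[key]
    if required:
        raise ConfigError(f"missing required config key {context}{key!r}")
    return default


def _parse_phantom(blk: dict) -> PhantomSpec:
    vessels = []
    for v in blk.get("vessels", []) or []:
        try:
            vessels.append(VesselSpec(
                name=v["name"], start_mm=tuple(v["start_mm"]),
                end_mm=tuple(v["end_mm"]), radius_mm=float(v["radius_mm"]),
                h=float(v["h"])))
        except KeyError as e:
            raise ConfigError(f"vessel entry missing key {e.args[0]!r}") from e
    duo = None
    if blk.get("duodenum"):
        d = blk["duodenum"]
        duo = DuodenumSpec(thickness_mm=float(d.get("thickness_mm", 5.0)),
                           offset_mm=float(d.get("offset_mm", 8.0)))
    kwargs = dict(
        mode=_get(blk, "mode", "voxel3d"),
        domain_size_mm=tuple(_get(blk, "domain_size_mm", required=True,
                                  context="phantom.")),
        vessels=tuple(vessels),
        duodenum=duo,
    )
    for key in ("voxel_spacing_mm", "margin_thickness_mm", "pancreas_padding_mm",
                "soft_tissue_shell_mm", "fine_spacing_mm", "core_radius_mm",
                "growth", "max_spacing_mm", "probe_lateral_mm", "fiber_radius_um"):
        if key in blk:
            kwargs[key] = blk[key] if blk[key] is None else float(blk[key])
    for key in ("tumor_semi_axes_mm", "tumor_center_mm", "fiber_entry_mm",
                "fiber_direction", "fine_band_mm"):
        if key in blk and blk[key] is not None:
            kwargs[key] = tuple(float(x) for x in blk[key])
    try:
        return PhantomSpec(**kwargs).validated()
    except TypeError as e:
        raise ConfigError(f"invalid phantom config: {e}") from e


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("run config must be a mapping")
    phantom = _parse_phantom(_get(doc, "phantom", required=True) or {})
    laser = doc.get("laser", {}) or {}
    solver = doc.get("solver", {}) or {}
    damage = doc.get("damage", {}) or {}
    dose = doc.get("dose", {}) or {}
    tissues = doc.get("tissues", "default")
    if tissues not in ("default", "ex_vivo", "constant"):
        raise ConfigError("tissues must be one of default|ex_vivo|constant")
    power = float(_get(laser, "power_w", 3.0))
    if power <= 0:
        raise ConfigError("laser.power_w must be positive")
    duration = float(_get(laser, "duration_s", 300.0))
    if duration <= 0:
        raise ConfigError("laser.duration_s must be positive")
    cfg = RunConfig(
        phantom=phantom,
        laser_power_w=power,
        laser_duration_s=duration,
        sigma_um=float(_get(laser, "sigma_um", 50.0)),
        fiber_radius_um=float(_get(laser, "fiber_radius_um", 150.0)),
        dt_s=float(_get(solver, "dt_s", 2.0)),
        temperature_cap_c=float(_get(solver, "temperature_cap_c", 150.0)),
        damage_temperature_c=float(_get(damage, "damage_temperature_c", 60.0)),
        necrosis_time_s=float(_get(damage, "necrosis_time_s", 1.0)),
        tissues=tissues,
        powers_w=tuple(float(p) for p in _get(dose, "powers_w",
                                              list(range(2, 11)))),
        durations_s=tuple(float(t) for t in _get(dose, "durations_s",
                                                 list(range(50, 601, 50)))),
        ablation_threshold_pct=float(_get(dose, "ablation_threshold_pct", 55.0)),
        oar_limit_c=float(_get(dose, "oar_limit_c", 42.0)),
        target_radius_mm=(float(dose["target_radius_mm"])
                          if dose.get("target_radius_mm") is not None else None),
        raw=doc,
    )
    if cfg.dt_s <= 0:
        raise ConfigError("solver.dt_s must be positive")
    return cfg


def load_run_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` maps dotted paths to values."""
    doc = yaml.safe_load(Path(path).read_text())
    for dotted, value in (overrides or {}).items():
        node = doc
        parts = dotted.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(str(value))
    return config_from_dict(doc)


def provenance(config: RunConfig | None = None) -> dict:
    out = {"package": "littplan", "version": _version}
    if config is not None:
        out["config_sha256_16"] = config.config_hash
    return out


# ---------------------------------------------------------------------------
# NIfTI

def phantom_to_nifti(phantom: VoxelPhantom, path) -> Path:
    """Write the label volume as NIfTI plus a JSON sidecar; returns the path."""
    if phantom.mode != "voxel3d":
        raise UnsupportedModeError("NIfTI export requires a voxel3d phantom")
    path = Path(path)
    affine = np.diag(list(phantom.spacing_mm) + [1.0])
    img = nib.Nifti1Image(phantom.label_grid.astype(np.int16), affine)
    nib.save(img, str(path))
    sidecar = {
        "coordinate_convention": "voxel centers, mm from the domain corner",
        "spacing_mm": list(phantom.spacing_mm),
        "label_names": {str(k): v for k, v in phantom.label_names.items()},
        "vessel_h_by_label": {str(k): v for k, v in phantom.vessel_h_by_label.items()},
        "fiber_tip_mm": phantom.fiber_tip_mm.tolist(),
        "fiber_direction": phantom.fiber_direction.tolist(),
        "probe_points_mm": [np.asarray(p).tolist() for p in phantom.probe_points_mm],
        "provenance": provenance(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def phantom_from_nifti(path) -> VoxelPhantom:
    """Round-trip loader for :func:`phantom_to_nifti` outputs."""
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    phantom = VoxelPhantom(
        mode="voxel3d",
        label_grid=np.asarray(img.dataobj, dtype=np.int16),
        label_names={int(k): v for k, v in meta["label_names"].items()},
        fiber_tip_mm=np.asarray(meta["fiber_tip_mm"], dtype=float),
        fiber_direction=np.asarray(meta["fiber_direction"], dtype=float),
        spacing_mm=tuple(meta["spacing_mm"]),
        vessel_h_by_label={int(k): float(v)
                           for k, v in meta["vessel_h_by_label"].items()},
        probe_points_mm=[np.asarray(p, dtype=float)
                         for p in meta["probe_points_mm"]],
    )
    from littplan.phantom import _trace_fiber_voxels
    phantom.fiber_axis_voxels = _trace_fiber_voxels(phantom)
    return phantom


# ---------------------------------------------------------------------------
# VTK (legacy ASCII)

def write_vtk(path, phantom: VoxelPhantom, fields: dict[str, np.ndarray]) -> Path:
    """Write scalar fields on the phantom grid as legacy-ASCII VTK.

    3-D phantoms become STRUCTURED_POINTS; axisymmetric phantoms become a
    2-D STRUCTURED_GRID over the (r, z) node coordinates.  Values are cell-
    centred but exported as point data on the node lattice for simplicity.
    """
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0",
             f"littplan fields (mm); {provenance()['version']}",
             "ASCII"]
    first = next(iter(fields.values()))
    if phantom.mode == "voxel3d":
        nx, ny, nz = phantom.shape
        sx, sy, sz = phantom.spacing_mm
        lines += [
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx} {ny} {nz}",
            f"ORIGIN {sx / 2} {sy / 2} {sz / 2}",
            f"SPACING {sx} {sy} {sz}",
            f"POINT_DATA {nx * ny * nz}",
        ]
        order = lambda a: np.asarray(a).transpose(2, 1, 0).ravel()  # x fastest
    else:
        nr, nz = phantom.shape
        lines += [
            "DATASET STRUCTURED_GRID",
            f"DIMENSIONS {nr} {nz} 1",
            f"POINTS {nr * nz} float",
        ]
        R, Z = np.meshgrid(phantom.r_nodes_mm, phantom.z_nodes_mm, indexing="ij")
        pts = np.stack([R.ravel(order="F"), Z.ravel(order="F"),
                        np.zeros(nr * nz)], axis=1)
        lines += [" ".join(f"{v:.6g}" for v in row) for row in pts]
        lines.append(f"POINT_DATA {nr * nz}")
        order = lambda a: np.asarray(a).ravel(order="F")
    for name, arr in fields.items():
        if arr.shape != first.shape:
            raise ValueError("all exported fields must share the grid shape")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        vals = order(np.nan_to_num(arr, nan=-1.0))
        lines += [" ".join(f"{v:.6g}" for v in vals[i:i + 9])
                  for i in range(0, len(vals), 9)]
    path.write_text("\n".join(lines) + "\n")
    return path
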