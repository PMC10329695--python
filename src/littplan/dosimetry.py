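"""Thermal damage accumulation, ablation metrics and laser dose optimization.

Damage follows a temperature-threshold dwell-time model: the injury
indicator theta integrates the time spent above the damage temperature
T_d, normalized by the necrosis dwell time t_n, and the necrotic fraction
is Omega = min(theta, 1).  With the defaults T_d = 60 degC and t_n = 1 s the
Omega = 1 region closely tracks the end-of-exposure 60 degC isotherm
(ablation at 60 degC is effectively instantaneous on the timescale of an
exposure), while 42 degC bounds the sublethal hyperthermia band that must
not reach vessels or the duodenum.

The dose planner sweeps laser power x exposure time, reading the ablated
percentage of the tumor-plus-safety-margin volume and the organ-at-risk
maximum temperature at each duration of a single time-marching run per
power, then selects the minimum power (ties broken by minimum duration,
i.e. minimum energy E = P*t) among the combinations that ablate at least
the threshold percentage while keeping the organ at risk at or below the
temperature limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from littplan.errors import LittplanError
from littplan.phantom import VoxelPhantom

__all__ = [
    "DamageModelConfig",
    "DamageField",
    "AblationMetrics",
    "DoseGrid",
    "OptimalDose",
    "accumulate_damage",
    "ablation_metrics",
    "dose_grid_search",
    "select_optimal_dose",
]

DEFAULT_POWERS_W = tuple(float(p) for p in range(2, 11))
DEFAULT_DURATIONS_S = tuple(float(t) for t in range(50, 601, 50))


@dataclass(frozen=True)
class DamageModelConfig:
    """Threshold dwell-time damage parameters."""

    damage_temperature: float = 60.0  # degC, T_d
    necrosis_time: float = 1.0  # s, t_n
    irradiation_time: float | None = None  # s, informational

    def __post_init__(self) -> None:
        if self.damage_temperature <= 37.0:
            raise ValueError("damage temperature must exceed body temperature")
        if self.necrosis_time <= 0:
            raise ValueError("necrosis dwell time must be positive")


@dataclass
class DamageField:
    """Injury indicator theta >= 0 and necrotic fraction Omega = min(theta, 1)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.theta < -1e-12):
            raise ValueError("theta must be non-negative")

    @property
    def omega(self) -> np.ndarray:
        return np.minimum(self.theta, 1.0)

    @property
    def ablated(self) -> np.ndarray:
        return self.omega >= 1.0


def accumulate_damage(temperature_history: np.ndarray,
                      config: DamageModelConfig, dt: float) -> DamageField:
    """Integrate the dwell-time injury indicator over a temperature history.

    ``temperature_history`` has time on axis 0 with uniform step ``dt`` (s);
    the first sample is the initial condition and does not contribute (the
    indicator integrates the time spent above threshold after each step, as
    the solver does).
    """
    hist = np.asarray(temperature_history, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    above = hist[1:] > config.damage_temperature
    theta = (dt / config.necrosis_time) * above.sum(axis=0)
    return DamageField(theta=np.asarray(theta, dtype=float))


@dataclass
class AblationMetrics:
    """Summary metrics of one exposure."""

    ablated_volume_mm3: float
    ablated_fraction_pct: float | None
    isotherm_areas_mm2: dict  # threshold degC -> cross-section area
    organ_at_risk: str | None
    organ_at_risk_max_c: float | None
    probe_max_c: dict
    margin_surface_mean_trace: pd.DataFrame | None


def _cross_section_area(phantom: VoxelPhantom, above: np.ndarray) -> float:
    """Area (mm^2) of a thresholded region on the plane through the fiber axis."""
    if phantom.mode == "axisymmetric":
        dr = np.diff(phantom.r_edges_mm)
        dz = np.diff(phantom.z_edges_mm)
        cell_area = dr[:, None] * dz[None, :]
        return 2.0 * float(np.sum(cell_area[above]))  # both sides of the axis
    h = np.asarray(phantom.spacing_mm)
    d = np.abs(np.asarray(phantom.fiber_direction))
    beam_axis = int(np.argmax(d))
    # slice normal: transverse axis closest to the tip's own plane
    normal = [a for a in range(3) if a != beam_axis][0]
    j = int(np.clip(phantom.fiber_tip_mm[normal] / h[normal], 0,
                    phantom.shape[normal] - 1))
    sl = [slice(None)] * 3
    sl[normal] = j
    plane = above[tuple(sl)]
    axes = [a for a in range(3) if a != normal]
    return float(np.sum(plane) * h[axes[0]] * h[axes[1]])


def ablation_metrics(result, phantom: VoxelPhantom,
                     damage: DamageField | None = None,
                     thresholds=(42.0, 60.0)) -> AblationMetrics:
    """Compute ablation/hyperthermia metrics from a simulation result.

    Volumes count cells with Omega = 1 times the cell volume; isotherm
    cross-section areas are measured on the plane through the fiber axis
    from the end-of-exposure temperature field; the organ at risk is the
    vessel/duodenum mask with the highest recorded maximum temperature.
    """
    damage = damage or result.damage
    masks = phantom.masks
    if not any(m.any() for m in masks.values()):
        raise LittplanError("phantom has no labeled masks")
    vols = phantom.cell_volumes_m3 * 1e9
    ablated = damage.ablated
    ablated_volume = float(np.sum(vols[ablated]))

    target = masks.get("tumor", np.zeros(phantom.shape, bool)) | \
        masks.get("margin", np.zeros(phantom.shape, bool))
    frac = None
    if target.any():
        frac = 100.0 * float(np.sum(vols[ablated & target])) / float(np.sum(vols[target]))

    T_end = result.temperature
    areas = {thr: _cross_section_area(phantom, np.nan_to_num(T_end, nan=-np.inf) >= thr)
             for thr in thresholds}

    oar_name = oar_max = None
    if result.oar_max:
        oar_name = max(result.oar_max, key=result.oar_max.get)
        oar_max = float(result.oar_max[oar_name])

    probe_max = {}
    for col in result.probe_traces.columns:
        if col.startswith("probe_"):
            probe_max[col] = float(result.probe_traces[col].max())

    margin_trace = None
    if result.trace_means is not None and "margin_surface" in result.trace_means:
        margin_trace = result.trace_means[["time_s", "margin_surface"]]

    return AblationMetrics(
        ablated_volume_mm3=ablated_volume,
        ablated_fraction_pct=frac,
        isotherm_areas_mm2=areas,
        organ_at_risk=oar_name,
        organ_at_risk_max_c=oar_max,
        probe_max_c=probe_max,
        margin_surface_mean_trace=margin_trace,
    )


def margin_surface_mask(phantom: VoxelPhantom) -> np.ndarray:
    """Cells of the safety margin adjacent to tissue outside tumor+margin."""
    masks = phantom.masks
    region = masks.get("tumor", 0) | masks.get("margin", 0)
    if not np.any(region):
        return np.zeros(phantom.shape, dtype=bool)
    interior = region.copy()
    for ax in range(region.ndim):
        interior &= np.roll(region, 1, axis=ax) & np.roll(region, -1, axis=ax)
    return region & ~interior & masks.get("margin", np.zeros_like(region))


# ---------------------------------------------------------------------------
# dose planning

@dataclass
class DoseGrid:
    """Ablated % and organ-at-risk max temperature per (power, duration).

    Both tables are indexed by duration (s, rows) with powers (W) as
    columns, mirroring a treatment-planning dose table.
    """

    ablated_pct: pd.DataFrame
    oar_max_c: pd.DataFrame
    ablated_volume_mm3: pd.DataFrame
    failed: list = field(default_factory=list)

    @property
    def powers(self):
        return list(self.ablated_pct.columns)

    @property
    def durations(self):
        return list(self.ablated_pct.index)


@dataclass(frozen=True)
class OptimalDose:
    """Selected laser setting; energy is exactly power x duration."""

    power_w: float
    duration_s: float
    ablated_pct: float
    oar_max_c: float

    @property
    def energy_j(self) -> float:
        return self.power_w * self.duration_s

    def to_json(self) -> str:
        oar = self.oar_max_c
        return json.dumps({
            "power_w": self.power_w,
            "duration_s": self.duration_s,
            "energy_j": self.energy_j,
            "ablated_pct": self.ablated_pct,
            "oar_max_c": None if oar != oar else oar,  # NaN -> null
        }, indent=2)


def dose_grid_search(
    phantom: VoxelPhantom,
    models,
    powers=DEFAULT_POWERS_W,
    durations=DEFAULT_DURATIONS_S,
    optics=None,
    solver_config=None,
    boundary=None,
    damage_config=None,
    target_mask: np.ndarray | None = None,
    oar_masks: dict | None = None,
    sigma_um: float = 50.0,
    fiber_radius_um: float = 150.0,
) -> DoseGrid:
    """One bioheat simulation per power, reading every duration along the way.

    Damage is cumulative in time, so a single time-marching run to the
    longest duration yields the ablated percentage and the running
    organ-at-risk maximum at every intermediate duration checkpoint.  A
    power whose run fails is flagged and left as NaN; the grid continues.
    """
    from littplan.optics import LaserConfig, OpticalProps
    from littplan.solver import SolverConfig, solve

    powers = sorted(float(p) for p in powers)
    durations = sorted(float(t) for t in durations)
    if not powers or not durations:
        raise ValueError("powers and durations must be non-empty")

    base = solver_config or SolverConfig()
    optics = optics or OpticalProps()
    abl = pd.DataFrame(np.nan, index=durations, columns=powers)
    oar = pd.DataFrame(np.nan, index=durations, columns=powers)
    vol = pd.DataFrame(np.nan, index=durations, columns=powers)
    abl.index.name = oar.index.name = vol.index.name = "duration_s"
    failed = []

    for p in powers:
        laser = LaserConfig(power=p, sigma_um=sigma_um, fiber_radius_um=fiber_radius_um)
        cfg = SolverConfig(dt=base.dt, total_time=max(durations),
                           picard_iterations=base.picard_iterations,
                           temperature_cap=base.temperature_cap)
        try:
            res = solve(phantom, models, laser=laser, optics=optics, config=cfg,
                        boundary=boundary, damage=damage_config,
                        checkpoint_times=durations, target_mask=target_mask,
                        oar_masks=oar_masks)
        except Exception as exc:  # noqa: BLE001 - flagged, grid continues
            failed.append((p, str(exc)))
            continue
        for cp in res.checkpoints:
            t = cp["time_s"]
            vol.loc[t, p] = cp["ablated_volume_mm3"]
            abl.loc[t, p] = cp.get("ablated_fraction_pct", np.nan)
            oar.loc[t, p] = cp.get("oar_max_c", np.nan)
    return DoseGrid(ablated_pct=abl, oar_max_c=oar, ablated_volume_mm3=vol,
                    failed=failed)


def select_optimal_dose(grid: DoseGrid, ablation_threshold_pct: float = 55.0,
                        oar_limit_c: float = 42.0) -> OptimalDose | None:
    """Minimum-power qualifying dose, ties broken by minimum duration.

    A combination qualifies when its ablated percentage reaches the
    threshold and its organ-at-risk maximum stays at or below the limit
    (a phantom without an organ at risk imposes no constraint).  Returns
    None when nothing within the operating range qualifies.
    """
    best = None
    for p in grid.powers:
        for t in grid.durations:
            a = grid.ablated_pct.loc[t, p]
            o = grid.oar_max_c.loc[t, p]
            if np.isnan(a) or a < ablation_threshold_pct:
                continue
            if not np.isnan(o) and o > oar_limit_c:
                continue
            cand = (p, t)
            if best is None or cand < best:
                best = cand
        if best is not None:
            break  # powers ascend; the first qualifying power wins
    if best is None:
        return None
    p, t = best
    o = grid.oar_max_c.loc[t, p]
    return OptimalDose(power_w=p, duration_s=t,
                       ablated_pct=float(grid.ablated_pct.loc[t, p]),
                       oar_max_c=float(o) if not np.isnan(o) else np.nan)
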