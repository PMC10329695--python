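"""Constitutive tissue models.

Baseline thermal properties at 37 degC per tissue, temperature-dependent
thermal conductivity k(T) and volumetric heat capacity C'(T) = rho*C with an
apparent-heat-capacity peak that absorbs the latent heat of tissue-water
evaporation, the remaining water-content curve W(T), and the
piecewise-polynomial blood-perfusion multipliers for healthy and tumorous
tissue.

Units follow the bioheat-transfer convention: temperatures in degC, densities
in kg/m^3, conductivities in W/(m*K), specific heats in J/(kg*K), perfusion
rates in 1/s (volumetric blood flow per tissue volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "BaselineProps",
    "WaterModel",
    "PropertyCurves",
    "PerfusionModel",
    "TissueModelSet",
    "BLOOD_DENSITY",
    "BLOOD_SPECIFIC_HEAT",
    "BLOOD_TEMPERATURE",
    "LATENT_HEAT_VAPORIZATION",
    "water_fraction",
    "thermal_conductivity",
    "volumetric_heat_capacity",
    "perfusion_multiplier",
    "perfusion_peak_temperature",
]

#: Blood properties entering the Pennes perfusion sink rho_b*C_b*w_b*(T - T_b).
BLOOD_DENSITY = 1050.0  # kg/m^3
BLOOD_SPECIFIC_HEAT = 3617.0  # J/(kg K)
BLOOD_TEMPERATURE = 37.0  # degC

#: Latent heat of water vaporization, J/kg.
LATENT_HEAT_VAPORIZATION = 2.260e6


@dataclass(frozen=True)
class BaselineProps:
    """Native tissue properties at normal body temperature (37 degC)."""

    density: float  # kg/m^3
    thermal_conductivity: float  # W/(m K)
    specific_heat: float  # J/(kg K)
    baseline_perfusion: float  # 1/s
    metabolic_heat: float = 0.0  # W/m^3

    def __post_init__(self) -> None:
        for name in ("density", "thermal_conductivity", "specific_heat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.baseline_perfusion < 0:
            raise ValueError("baseline_perfusion must be non-negative")
        if self.metabolic_heat < 0:
            raise ValueError("metabolic_heat must be non-negative")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * C at 37 degC, J/(m^3 K)."""
        return self.density * self.specific_heat


#: Native thermal properties at 37 degC per tissue.  The tumor shares the
#: healthy-pancreas thermal values but is less perfused; "soft_tissue" is the
#: filler material between the pancreas and the vessels, and also the default
#: material of the embedding background cube.
BASELINE_TABLE: dict[str, BaselineProps] = {
    "pancreas": BaselineProps(1128.0, 0.52, 3164.0, 0.018),
    "tumor": BaselineProps(1128.0, 0.52, 3164.0, 0.005),
    "duodenum": BaselineProps(1126.0, 0.53, 3690.0, 0.015),
    "soft_tissue": BaselineProps(1050.0, 0.49, 3400.0, 0.003),
}


@dataclass(frozen=True)
class WaterModel:
    """Remaining tissue water content W(T), as a mass fraction.

    W equals ``w0`` below the evaporation onset, declines with an
    accelerating exponential approach so that exactly half the water is gone
    at ``half_loss_temperature`` (103 degC by default), and decays
    exponentially toward zero above it, which is where carbonization would
    begin.  ``scale`` (degC) sets both the acceleration below and the decay
    above the half-loss point, keeping dW/dT continuous there.
    """

    w0: float = 0.7
    onset: float = 80.0  # degC
    half_loss_temperature: float = 103.0  # degC
    scale: float = 2.0  # degC

    def __post_init__(self) -> None:
        if not (0.0 < self.w0 <= 1.0):
            raise ValueError("w0 must lie in (0, 1]")
        if self.onset >= self.half_loss_temperature:
            raise ValueError("onset must lie below half_loss_temperature")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def fraction(self, temperature):
        """Remaining water mass fraction at ``temperature`` (degC)."""
        T = np.asarray(temperature, dtype=float)
        Th, s = self.half_loss_temperature, self.scale
        below = 1.0 - 0.5 * np.exp(np.minimum(T - Th, 0.0) / s)
        above = 0.5 * np.exp(-np.maximum(T - Th, 0.0) / s)
        w = np.where(T <= Th, below, above) * self.w0
        w = np.where(T <= self.onset, self.w0, w)
        return w if w.ndim else float(w)

    def dfraction_dT(self, temperature):
        """dW/dT (1/degC); non-positive everywhere."""
        T = np.asarray(temperature, dtype=float)
        Th, s = self.half_loss_temperature, self.scale
        mag = 0.5 / s * np.exp(-np.abs(T - Th) / s) * self.w0
        d = np.where(T <= self.onset, 0.0, -mag)
        return d if d.ndim else float(d)


def water_fraction(temperature, model: WaterModel | None = None):
    """Remaining tissue water fraction W(T); ``model`` defaults to WaterModel()."""
    return (model or WaterModel()).fraction(temperature)


@dataclass(frozen=True)
class PropertyCurves:
    """Temperature dependence of k and C' = rho*C for one tissue.

    Both are piecewise-linear in temperature, anchored so that the 37 degC
    value reproduces the native baseline.  The volumetric heat capacity
    additionally carries the apparent-heat-capacity term
    ``h_fg * rho * (-dW/dT)`` derived from the water model, so the integral
    of the excess capacity across the evaporation band equals the latent
    heat of the water actually lost.  Values outside the anchor support hold
    the boundary value.

    The relative anchor shapes below 100 degC follow the qualitative
    behaviour measured ex vivo on heated liver: a mild rise up to the
    evaporation onset, a stronger rise up to ~100 degC, and a decline once
    the water is gone.
    """

    conductivity_anchors: tuple[tuple[float, float], ...]  # (degC, W/(m K))
    base_capacity_anchors: tuple[tuple[float, float], ...]  # (degC, J/(m^3 K))
    water: WaterModel = field(default_factory=WaterModel)
    latent_heat: float = LATENT_HEAT_VAPORIZATION  # J/kg
    density: float = 1128.0  # kg/m^3, converts water mass fraction to mass/volume

    #: Relative anchor shapes (temperature degC, multiple of the 37 degC value).
    _K_SHAPE = ((0.0, 1.0), (37.0, 1.0), (80.0, 1.05), (100.0, 1.30),
                (105.0, 1.15), (150.0, 1.05))
    _C_SHAPE = ((0.0, 1.0), (37.0, 1.0), (80.0, 1.05), (100.0, 1.10),
                (104.0, 0.75), (150.0, 0.70))

    @classmethod
    def for_tissue(cls, props: BaselineProps,
                   water: WaterModel | None = None) -> "PropertyCurves":
        """Default curves scaled so the 37 degC values match ``props``."""
        water = water or WaterModel()
        k0 = props.thermal_conductivity
        c0 = props.volumetric_heat_capacity
        return cls(
            conductivity_anchors=tuple((t, m * k0) for t, m in cls._K_SHAPE),
            base_capacity_anchors=tuple((t, m * c0) for t, m in cls._C_SHAPE),
            water=water,
            density=props.density,
        )

    @classmethod
    def constant(cls, props: BaselineProps) -> "PropertyCurves":
        """Temperature-independent curves (for analytic benchmarks)."""
        k0 = props.thermal_conductivity
        c0 = props.volumetric_heat_capacity
        return cls(
            conductivity_anchors=((0.0, k0), (150.0, k0)),
            base_capacity_anchors=((0.0, c0), (150.0, c0)),
            water=WaterModel(),
            latent_heat=0.0,
            density=props.density,
        )

    def conductivity(self, temperature):
        T = np.asarray(temperature, dtype=float)
        xs, ys = zip(*self.conductivity_anchors)
        k = np.interp(T, xs, ys)
        return k if k.ndim else float(k)

    def heat_capacity(self, temperature):
        """C'(T) = rho*C baseline shape + h_fg * rho * (-dW/dT), J/(m^3 K)."""
        T = np.asarray(temperature, dtype=float)
        xs, ys = zip(*self.base_capacity_anchors)
        base = np.interp(T, xs, ys)
        latent = self.latent_heat * self.density * (-np.asarray(self.water.dfraction_dT(T)))
        c = base + latent
        return c if c.ndim else float(c)


def thermal_conductivity(temperature, curves: PropertyCurves):
    """k(T) in W/(m K)."""
    return curves.conductivity(temperature)


def volumetric_heat_capacity(temperature, curves: PropertyCurves):
    """C'(T) = rho*C(T) in J/(m^3 K), including the evaporation peak."""
    return curves.heat_capacity(temperature)


# --- blood perfusion -------------------------------------------------------

#: Piecewise quadratic multipliers of the baseline perfusion w0 as a function
#: of temperature, fitted to hyperthermia animal data.  Each branch is
#: (T_low, T_high, (a, b, c)) meaning a*T^2 + b*T + c on (T_low, T_high].
HEALTHY_BRANCHES: tuple[tuple[float, float, tuple[float, float, float]], ...] = (
    (37.0, 42.0, (4.7167e-2, -3.5367, 67.2974)),
    (42.0, 45.0, (-7.7906e-2, 9.6329, -267.0257)),
    (45.0, 48.0, (-15.6972e-2, 11.8435, -205.5134)),
)
TUMOR_BRANCHES: tuple[tuple[float, float, tuple[float, float, float]], ...] = (
    (37.0, 42.0, (3.40e-2, -2.5276, 47.9933)),
    (42.0, 44.0, (-0.6891, 58.5436, -1241.5792)),
)


@dataclass(frozen=True)
class PerfusionModel:
    """Temperature- and coagulation-dependent blood perfusion multiplier.

    ``kind`` selects the healthy or tumor branch set; ``constant`` keeps the
    multiplier at 1 for analytic benchmarks.  Below 37 degC the multiplier is
    1 (baseline); above the last printed branch the branch-end value is held,
    since the vasculature destruction beyond that range has no printed
    functional form; wherever the necrotic fraction Omega reaches 1 the
    perfusion shuts down to 0.
    """

    kind: str = "healthy"  # healthy | tumor | constant
    blood_density: float = BLOOD_DENSITY
    blood_specific_heat: float = BLOOD_SPECIFIC_HEAT
    blood_temperature: float = BLOOD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kind not in ("healthy", "tumor", "constant"):
            raise ValueError(f"unknown perfusion kind {self.kind!r}")

    @property
    def branches(self):
        if self.kind == "healthy":
            return HEALTHY_BRANCHES
        if self.kind == "tumor":
            return TUMOR_BRANCHES
        return ()

    def multiplier(self, temperature, omega=0.0):
        return perfusion_multiplier(temperature, self, omega)


def _poly(coeffs, T):
    a, b, c = coeffs
    return a * T * T + b * T + c


def perfusion_multiplier(temperature, model: PerfusionModel, omega=0.0):
    """Dimensionless multiplier of the baseline perfusion rate w0.

    Total function of temperature: 1 at and below 37 degC, the printed
    quadratic branch on its own (T_low, T_high] range, the last branch-end
    value held above the final breakpoint, and 0 wherever ``omega`` (the
    necrotic fraction) has reached 1.
    """
    T = np.asarray(temperature, dtype=float)
    om = np.asarray(omega, dtype=float)
    if model.kind == "constant":
        mult = np.ones_like(T)
    else:
        mult = np.ones_like(T)
        for lo, hi, coeffs in model.branches:
            sel = (T > lo) & (T <= hi)
            mult = np.where(sel, _poly(coeffs, T), mult)
        lo, hi, coeffs = model.branches[-1]
        mult = np.where(T > hi, _poly(coeffs, hi), mult)
        mult = np.maximum(mult, 0.0)
    mult = np.where(om >= 1.0, 0.0, mult)
    return mult if mult.ndim else float(mult)


def perfusion_peak_temperature(kind: str, step: float = 0.01) -> int:
    """Temperature (degC, nearest degree) of the perfusion-multiplier maximum.

    Scans the printed branch support (37, T_last] on a uniform grid of the
    given step and returns the grid argmax rounded to the nearest degree.
    """
    model = PerfusionModel(kind=kind)
    if not model.branches:
        raise ValueError("constant perfusion has no peak")
    upper = model.branches[-1][1]
    n = int(round((upper - 37.0) / step))
    grid = 37.0 + step * np.arange(1, n + 1)
    values = perfusion_multiplier(grid, model)
    return int(round(grid[int(np.argmax(values))]))


# --- per-tissue bundles ----------------------------------------------------

@dataclass(frozen=True)
class TissueModel:
    """All constitutive models for one tissue type."""

    baseline: BaselineProps
    curves: PropertyCurves
    perfusion: PerfusionModel


@dataclass
class TissueModelSet:
    """Mapping from tissue name to its constitutive models.

    ``default()`` builds the native in-vivo set (tumor uses the tumor
    perfusion branches; every other perfused tissue uses the healthy ones).
    ``ex_vivo()`` zeroes perfusion and metabolic heat, matching bench
    experiments on excised tissue.  ``constant(...)`` freezes properties at
    their 37 degC values for analytic benchmarks.
    """

    tissues: dict[str, TissueModel]

    @classmethod
    def default(cls, water: WaterModel | None = None) -> "TissueModelSet":
        water = water or WaterModel()
        out: dict[str, TissueModel] = {}
        for name, props in BASELINE_TABLE.items():
            kind = "tumor" if name == "tumor" else "healthy"
            out[name] = TissueModel(
                baseline=props,
                curves=PropertyCurves.for_tissue(props, water),
                perfusion=PerfusionModel(kind=kind),
            )
        return cls(out)

    @classmethod
    def ex_vivo(cls, water: WaterModel | None = None) -> "TissueModelSet":
        base = cls.default(water)
        out = {}
        for name, tm in base.tissues.items():
            props = replace(tm.baseline, baseline_perfusion=0.0, metabolic_heat=0.0)
            out[name] = TissueModel(props, PropertyCurves.for_tissue(props, tm.curves.water),
                                    tm.perfusion)
        return cls(out)

    @classmethod
    def constant(cls, perfusion_rate: float | None = None) -> "TissueModelSet":
        """Temperature-independent properties; optional uniform perfusion rate."""
        out = {}
        for name, props in BASELINE_TABLE.items():
            if perfusion_rate is not None:
                props = replace(props, baseline_perfusion=perfusion_rate)
            out[name] = TissueModel(props, PropertyCurves.constant(props),
                                    PerfusionModel(kind="constant"))
        return cls(out)

    @classmethod
    def uniform(cls, props: BaselineProps | None = None) -> "TissueModelSet":
        """Every tissue shares one constant property set (analytic benchmarks)."""
        props = props or BASELINE_TABLE["pancreas"]
        tm = TissueModel(props, PropertyCurves.constant(props),
                         PerfusionModel(kind="constant"))
        return cls({name: tm for name in BASELINE_TABLE})

    def __getitem__(self, name: str) -> TissueModel:
        return self.tissues[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tissues

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        doc = {}
        for name, tm in self.tissues.items():
            doc[name] = {
                "baseline": {
                    "density": tm.baseline.density,
                    "thermal_conductivity": tm.baseline.thermal_conductivity,
                    "specific_heat": tm.baseline.specific_heat,
                    "baseline_perfusion": tm.baseline.baseline_perfusion,
                    "metabolic_heat": tm.baseline.metabolic_heat,
                },
                "perfusion_kind": tm.perfusion.kind,
                "conductivity_anchors": [list(a) for a in tm.curves.conductivity_anchors],
                "base_capacity_anchors": [list(a) for a in tm.curves.base_capacity_anchors],
                "water": {
                    "w0": tm.curves.water.w0,
                    "onset": tm.curves.water.onset,
                    "half_loss_temperature": tm.curves.water.half_loss_temperature,
                    "scale": tm.curves.water.scale,
                },
                "latent_heat": tm.curves.latent_heat,
            }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TissueModelSet":
        doc = yaml.safe_load(text)
        out = {}
        for name, blk in doc.items():
            props = BaselineProps(**blk["baseline"])
            water = WaterModel(**blk["water"])
            curves = PropertyCurves(
                conductivity_anchors=tuple(tuple(a) for a in blk["conductivity_anchors"]),
                base_capacity_anchors=tuple(tuple(a) for a in blk["base_capacity_anchors"]),
                water=water,
                latent_heat=blk["latent_heat"],
                density=props.density,
            )
            out[name] = TissueModel(props, curves, PerfusionModel(kind=blk["perfusion_kind"]))
        return cls(out)
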