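# littplan

Planning simulator for **laser interstitial thermal therapy (LITT)** of
soft-tissue tumors — built around the pancreatic (PDAC) use case of a bare
300 µm Nd:YAG fiber (1064 nm, continuous wave, 2–10 W) inserted into the
tumor. The package is aimed at researchers in thermal-therapy modeling who
need a transparent, fully scriptable alternative to commercial FEM for
studying dose–response behaviour on synthetic anatomies.

## The model

Tissue temperature follows a modified Pennes bioheat equation

```
C'(T) ∂T/∂t = ∇·(k(T) ∇T) − ρ_b C_b ω_b(T, Ω) (T − T_b) + Q_met + Q_laser
```

* `C'(T) = ρC` is the volumetric heat capacity with an *apparent-capacity*
  peak across the water-evaporation band, so the latent term `h_fg dW/dt`
  is booked implicitly: the water content `W(T)` starts falling above
  80 °C, is half gone at 103 °C and decays to ~0 above 104 °C.
* `ω_b(T, Ω)` is the blood perfusion rate: baseline `ω₀` per tissue scaled
  by piecewise-quadratic multipliers that peak near 45 °C (healthy) and
  42 °C (tumor) before vascular destruction, and shut off where the
  necrotic fraction Ω reaches 1.
* `Q_laser = α_eff · I(x,y) · exp(−α_eff z)` is a Beer–Lambert source with
  Gaussian transverse irradiance `I = I₀ exp(−(x²+y²)/2σ²)`,
  `I₀ = P/2πσ²`, σ = 50 µm = r_f/3 (≈99 % of power inside the fiber
  core), and `α_eff = √(3α(α + α_s(1−g)))` blended between native and
  coagulated optical properties by Ω.
* Damage: `θ = ∫ (1/t_n)·(T > T_d) dt`, `Ω = min(θ, 1)`, with T_d = 60 °C
  and dwell time t_n = 1 s — the Ω = 1 zone closely tracks the 60 °C
  isotherm; 42 °C bounds the band that must not reach organs at risk.

The solver is a conservative finite-volume scheme (harmonic-mean interface
conductivity, backward Euler at dt = 2 s, chord-capacity Picard handling of
the evaporation nonlinearity, active-set treatment of the 150 °C safeguard
cap) with Dirichlet 37 °C on the embedding box and convective Robin
conditions `h (T_b − T)` on vessel surfaces. Geometries are synthetic: a
labeled 3-D voxel phantom (ellipsoidal tumor, 5 mm dilated safety margin,
cylindrical vessels, optional duodenum slab) or a fast axisymmetric (r, z)
mode for homogeneous-tissue benchmarks.

The dose planner sweeps power × exposure time (defaults 2–10 W ×
50–600 s), reads the ablated percentage of the tumor+margin volume and the
organ-at-risk maximum temperature at every duration of one run per power,
and selects the **minimum power** (then minimum duration) whose combination
ablates ≥ 55 % while keeping the organ at risk ≤ 42 °C.

## Worked example

A homogeneous excised-tissue benchmark: 3 W for 300 s on an axisymmetric
phantom, probes 10 mm lateral of the fiber.

```yaml
# demo.yaml
phantom:
  mode: axisymmetric
  domain_size_mm: [20.0, 50.0]
  fine_spacing_mm: 0.08
  fiber_entry_mm: [0.0, 15.0]
  probe_lateral_mm: 10.0
laser: {power_w: 3.0, duration_s: 300.0}
tissues: ex_vivo
dose:
  powers_w: [2.0, 3.0, 5.0]
  durations_s: [100.0, 200.0, 300.0]
  target_radius_mm: 6.0
  ablation_threshold_pct: 20.0
```

```
$ littplan simulate --config demo.yaml --out demo_out
{
  "ablated_volume_mm3": 346.8688835260491,
  "ablated_fraction_pct": null
}
```

346.9 mm³ of tissue reached full necrosis (Ω = 1); the fraction is null
because a homogeneous phantom has no tumor/margin labels. `metrics.json`
additionally reports the 42 °C and 60 °C cross-section areas (352.2 and
76.3 mm²), the probe maximum (40.1 °C at 10 mm — below the 42 °C damage
threshold) and an energy ledger that closes to machine precision
(deposited 899.4 J; closure fraction ~1e-15).

```
$ littplan optimize --config demo.yaml --out demo_opt
{
  "power_w": 3.0,
  "duration_s": 300.0,
  "energy_j": 900.0,
  "ablated_pct": 21.752477550121792,
  "oar_max_c": null
}
```

Of the grid, only 3 W × 300 s and 5 W × 300 s ablate ≥ 20 % of the 6 mm
target ball; the minimum-power rule picks 3 W, i.e. 900 J. The full dose
tables land in `demo_opt/dose_ablated_pct.csv` (ablated % rises
monotonically along both axes, from 10.3 % at 2 W × 100 s to 24.0 % at
5 W × 300 s).

The same configs drive `littplan phantom` (NIfTI label volume + JSON
sidecar for 3-D phantoms) and the library API (`littplan.solve`,
`littplan.dose_grid_search`, `littplan.select_optimal_dose`, ...).

## Layout

| module | contents |
| --- | --- |
| `littplan.phantom` | synthetic voxel / axisymmetric anatomies, probes |
| `littplan.tissue` | baseline properties, k(T), C'(T), W(T), perfusion |
| `littplan.optics` | Gaussian beam, Beer–Lambert source, Ω-blended optics |
| `littplan.solver` | finite-volume Pennes solver, oracles, mesh checks |
| `littplan.dosimetry` | damage model, ablation metrics, dose optimization |
| `littplan.io` / `littplan.cli` | YAML configs, NIfTI/VTK/CSV/JSON, CLI |

See `docs/methods.md` for the numerical and modeling choices in detail.
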