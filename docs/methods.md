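# Methods

This note records the model equations as implemented, the defaults and the
reasoning behind the genuinely open design choices. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Governing equation

The solver integrates the Pennes bioheat equation with an evaporation
energy term folded into the storage coefficient:

C'(T) ∂T/∂t = ∇·(k(T)∇T) − ρ_b C_b ω_b(T, Ω)(T − T_b) + Q_met + Q_laser.

Blood properties are ρ_b = 1050 kg/m³, C_b = 3617 J/(kg·K), T_b = 37 °C
(configurable; typical literature values — the source tables list none).
Q_met defaults to 0 W/m³ per tissue (the term is carried but no value is
tabulated for pancreatic tissue; it is negligible against laser deposition
of order 10⁸–10¹⁰ W/m³ near the fiber).

### Baseline properties (37 °C)

| tissue | ρ kg/m³ | k W/(m·K) | C J/(kg·K) | ω₀ 1/s |
| --- | --- | --- | --- | --- |
| pancreas | 1128 | 0.52 | 3164 | 0.018 |
| tumor | 1128 | 0.52 | 3164 | 0.005 |
| duodenum | 1126 | 0.53 | 3690 | 0.015 |
| soft tissue | 1050 | 0.49 | 3400 | 0.003 |

The tumor shares the healthy-pancreas thermal values but is less perfused.
"Soft tissue" fills the shell between pancreas and vessels (default 1 mm)
and the embedding background cube.

### Water content and apparent heat capacity

W(T) is a mass fraction: W = W₀ below the 80 °C onset, then
W = W₀·(1 − ½·e^((T−103)/s)) up to 103 °C and W = ½W₀·e^(−(T−103)/s)
above, with s = 2 °C. This reproduces the stated anchors — onset at 80 °C,
evaporation accelerating near 100 °C, exactly 50 % lost at 103 °C, an
exponential drop to near zero above 104 °C — with a continuous dW/dT whose
peak sits at 103 °C. W₀ defaults to 0.7, a typical soft-tissue water mass
fraction (no value is printed in the source tables).

The volumetric heat capacity is C'(T) = C'_base(T) + h_fg·ρ·(−dW/dT) with
h_fg = 2260 kJ/kg, so the integral of the apparent-capacity excess across
the evaporation band equals the latent heat of the water actually lost *by
construction* (the test suite verifies this to 1 %). C'_base and k(T) are
piecewise-linear anchor curves scaled so their 37 °C values match the
table above; their relative shapes (mild rise to 80 °C, stronger rise to
100 °C, decline once the water is gone) follow the qualitative behaviour
measured ex vivo on heated liver. The measured curves are not tabulated in
the source, so all anchors live in configuration and users may substitute
digitized data. Outside the anchor support both curves hold their boundary
values.

### Perfusion

ω_b = ω₀ × multiplier(T, Ω). The multipliers are the printed piecewise
quadratics: healthy tissue on (37, 42], (42, 45], (45, 48]; tumor on
(37, 42], (42, 44]. They are evaluated exactly as printed — the branches
are *not* continuous across breakpoints and are deliberately not smoothed.
Below 37 °C the multiplier is 1; above the last branch the branch-end
value is held (the vasculature-destruction regime has no printed form);
where Ω = 1 the multiplier is 0 (coagulated tissue has no perfusion).
Healthy-branch coefficients are applied to pancreas, duodenum, soft tissue
and background alike; only the tumor uses the tumor branches. The grid
argmax of the multipliers (0.01 °C spacing) lands at 45 °C (healthy,
left edge of the third branch) and 42 °C (tumor, interior vertex at
58.5436/(2·0.6891) ≈ 42.48 °C).

A caveat inherited from the source data: the multipliers were fitted to
animals heated for 30–40 min, while simulated exposures are ~10 min; no
duration correction is applied.

## Laser source

Irradiance I(x,y) = I₀·exp(−(x²+y²)/2σ²) with I₀ = P/(2πσ²); σ = 50 µm =
r_f/3 for the 150 µm-radius bare fiber, putting ~99 % of the power through
the core. Axial decay follows Beer–Lambert with
α_eff = √(3α(α + α_s(1−g))); the native/coagulated coefficient sets
(1064 nm) are blended linearly by Ω per cell. Native α_eff = 0.1318 /mm,
coagulated 0.2842 /mm, so coagulation pulls deposition toward the fiber.
The same optical properties are applied to all soft tissues (no
tissue-resolved optics are tabulated). z is measured from the fiber *tip*
(end-firing bare fiber); the configured entry point is the tip.

Deposition is integrated conservatively: each cell receives the transverse
Gaussian mass over its footprint times the attenuation-depth difference
across it, so total deposited power is conserved on grids much coarser
than σ, and with heterogeneous Ω the exponent is the path integral of the
cell-local α_eff from the tip (which collapses to the single-exponential
form in homogeneous media). The transverse profile is not re-spread with
depth. In voxel mode the beam must be grid-axis-aligned; the axisymmetric
mode has it on the axis by construction.

## Discretization

Conservative finite volumes on the structured grid with harmonic-mean
interface conductivity; backward Euler at dt = 2 s. Boundary conditions:
Dirichlet 37 °C on the outermost layer of the embedding box (configurable
per face, including Robin and insulated variants — the Robin slab oracle
uses these), series conduction–convection transmissibility
1/(1/h + d/k) per face on vessel surfaces. Vessel interiors are excluded
from the conduction domain: the model treats vessels as convective
surfaces (h = 511 W/m²K aorta-calibre, 1000 superior mesenteric artery,
750 portal/splenic/renal-calibre), not as resolved flow.

Nonlinearity: three Picard passes per step — a predictor with coefficients
lagged at the previous temperature, then correctors that replace the
storage coefficient with the *chord* (secant) capacity
(H(T_new) − H(T_old))/(T_new − T_old), H being the enthalpy integral of
C'. The chord form books the evaporation latent heat exactly across a
step, making results nearly independent of dt (halving dt from 2 s to 1 s
changes the ablated volume by well under 2 % in the test suite); a purely
lagged capacity under-resolves the narrow evaporation peak and shows
several-percent dt sensitivity.

Temperatures are limited to 150 °C: the model has no charring chemistry,
and beyond water depletion its property curves are extrapolations. The
limit is enforced as an *obstacle constraint* (primal active-set: cells
are pinned at the cap while their extraction multiplier stays
non-negative), not as a post-solve clip — clipping discards an energy
amount that depends on dt, whereas the complementarity solution converges.
The extracted heat appears in the energy ledger as `capped`.

Linear systems: direct sparse LU for 2-D and small 3-D problems; Jacobi-
preconditioned conjugate gradients with warm starts above 20 000 unknowns
(the matrix is SPD and strongly diagonally dominant at dt = 2 s).

The energy ledger (deposited, metabolic, stored, boundary, perfusion,
capped) is accumulated from the same discrete fluxes as the solve, so the
balance closes to solver precision on every run; the 2 % closure bound in
the tests is therefore a guard against implementation regressions, not a
numerical tolerance.

### Grids

*Axisymmetric*: node-centred radial mesh with a node exactly on the axis
(first cell spans half the fine spacing) graded geometrically outward;
axial mesh fine in a band around the tip. The core radial spacing is half
the axial fine spacing because the transverse beam scale (σ = 50 µm) is
far below the axial attenuation length (1/α_eff ≈ 7.6 mm). The
mesh-independence sweep over maximum element sizes
{0.12, 0.08, 0.04, 0.02} mm tracks the peak of the axial source profile;
successive changes fall below 2 % at 0.04 mm (≈ one tenth of the fiber
diameter), which is the default fine spacing.

*Voxel*: uniform spacing (default 0.5 mm) with sub-voxel analytic source
integration, since a uniform 0.04 mm 3-D grid is not desk-scale. The
safety margin is the true Euclidean dilation of the tumor (distance
transform), the tumor an analytic ellipsoid voxelized at cell centers.

## Damage and dosimetry

θ accumulates (dt/t_n) per step spent above T_d = 60 °C; Ω = min(θ, 1).
t_n defaults to 1 s — at 60 °C ablation is effectively instantaneous on
exposure timescales, which makes the Ω = 1 region track the
end-of-exposure 60 °C isotherm (verified in the tests at coarse
tolerance) — and is configurable since no value is printed. No Arrhenius
kinetics are modeled.

Metrics are read at end of exposure (no cooling interval by default). The
ablated fraction divides by the union volume of tumor and margin masks.
The organ at risk is the vessel/duodenum mask with the highest recorded
maximum temperature; vessel-wall temperature is read on the one-cell
tissue shell around the excluded vessel interior.

The dose grid defaults to 2–10 W × 50–600 s in 1 W / 50 s steps. One
time-marching run per power serves every duration (damage is cumulative).
Selection: among combinations with ablated ≥ 55 % and organ-at-risk
≤ 42 °C, minimum power first, then minimum duration (= minimum energy;
no other tie-break is specified). An empty selection is a valid outcome.

## Synthetic phantoms vs. real anatomy

The phantoms reproduce the *structure* of the clinical setting (tumor,
5 mm margin, vessels with heat-sink boundaries, duodenum, embedding box
with fixed far-field temperature) with analytic shapes. What they do not
reproduce: patient-specific organ geometry, fiber placement relative to
real structures, heterogeneous perfusion, or imaging-derived boundaries.
Passing tests therefore demonstrate correct physics and dose-logic
behaviour (oracles, conservation, monotonicity, selection), not
patient-level predictions; quantitative patient outcomes depend on
geometries this package deliberately does not model.

## Problem sizes

Defaults used by the test suite were chosen to keep the full run at
desk scale: axisymmetric grids of roughly 5 000–25 000 cells (fine spacing
0.08–0.1 mm for transient runs, 0.1 mm core for the steady point-source
oracle), 3-D grids of 30–64 thousand 1 mm voxels, exposures of 1–5 min,
and dose grids of 3 × 3. All spatial and temporal parameters scale up by
configuration only.

## Known limitations

- No carbonization chemistry, tissue shrinkage or vapor transport; above
  water depletion the 150 °C obstacle cap stands in for all of them, and
  with several watts focused at a 50 µm sigma it extracts a substantial
  share of the deposited power — peak-zone quantities should be read as
  model artifacts, isotherm/damage extents as the meaningful outputs.
- No photon transport beyond the fixed-profile Beer–Lambert form (no
  Monte-Carlo, no diffusion-theory beam spreading).
- Single fiber, continuous wave only; no pull-back or multi-fiber plans.
- Perfusion multipliers are deterministic and tissue-uniform; no
  stochastic heterogeneity, no Arrhenius-coupled shutdown below Ω = 1.
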