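# Methods

`melanosim` is a 2D agent-based model of melanosome dispersion by
cooperative actin nucleation (Rab27a–SPIRE1/2–FMN1) and myosin-Va
transport, together with the quantification procedures used to read the
model (and the corresponding experiments) out: dispersion metrics on
positions and rendered images, saturation-binding fits, qPCR absolute
quantification, Pearson/Costes colocalisation and BiFC table statistics.

Units throughout: micrometres (µm), seconds (s), piconewtons (pN).
Thermal energy is then kT ≈ 0.0042 pN·µm at ~30 °C.

## 1. Model

### 1.1 Geometry and degrees of freedom

The cell body is a disk of radius `R` (default 10 µm). Three kinds of
agents live in it:

* **Melanosomes** — rigid disks of radius `a` (0.25 µm) with position
  `x_i`. Each carries motor anchor points and nucleates actin filaments
  from its surface.
* **Actin filaments** — discretised bead-spring chains of vertices with
  rest segment length `s0` (0.5 µm). Vertex 0 is the pointed (−) end;
  the last vertex is the barbed (+) end, which grows. In **attached**
  mode the pointed end is tethered by a spring to a fixed anchor point
  on the surface of the nucleating organelle; in **detached** mode the
  filament is released at birth. This single flag is the simulated
  experiment.
* **Myosin-Va motors** — point linkages anchored at fixed surface
  points of their host organelle. A bound motor holds a Hookean spring
  between its anchor and a material point on a filament (arc coordinate
  `s` from the pointed end) and steps toward the barbed end.

### 1.2 Dynamics

All mobile degrees of freedom follow overdamped (Brownian) dynamics,
integrated with Euler–Maruyama:

    x(t+dt) = x(t) + F/γ · dt + sqrt(2 kT dt / γ) · ξ,   ξ ~ N(0, I)

* Organelle drag `γ_org = 6πηa` with η = 0.3 Pa·s (cytoplasm), ≈ 1.41
  pN·s/µm.
* Filament vertices use a drag per unit length (`gamma_per_length`,
  0.6 pN·s/µm²) times `s0` per vertex.
* Forces: segment stretching `k_seg (l − l_rest)`, discrete worm-like
  bending energy `(κ/s0) Σ (1 − cos θ)` with κ = Lp·kT (Lp ≈ 10 µm),
  pointed-end tether spring `k_link`, motor spring `k_motor`,
  organelle–organelle steric repulsion `k_rep` on disk overlap, and a
  soft confining wall `k_wall` acting on protrusion beyond `R`,
  followed by a radial projection so no organelle centre ends a step
  beyond `R − a`. Bending and stretching forces are the exact analytic
  gradients of the energy (validated against central differences).
* Stability: `dt` must satisfy `dt ≤ 0.1 γ_min / k_max` (checked at
  config validation). Default `dt` = 1 ms.

### 1.3 Stochastic kinetics

Each step executes, in fixed order: filament turnover → nucleation →
barbed-end growth → motor unbinding → motor binding → motor stepping →
mechanics. Every Poisson process with rate `r` is realised per step as
a Bernoulli draw with `p = 1 − exp(−r·dt)`, and an exposure counter is
incremented before every draw, so realised event counts are exactly
Binomial(exposure, p) — the property the kinetics tests exploit.

* **Nucleation**: each organelle nucleates at rate `nucleation_rate`
  (0.05 s⁻¹); a new filament of length `initial_length` (0.25 µm)
  appears at a random surface point pointing outward (tethered only in
  attached mode; the mode changes nothing else about nucleation).
* **Growth**: barbed end elongates at `growth_speed` (0.3 µm/s) up to
  `max_length` (3 µm); vertices are appended as the terminal segment
  exceeds 1.5·s0.
* **Turnover**: whole filaments disappear at rate
  1/`filament_lifetime` (lifetime 20 s), releasing any bound motors.
* **Binding**: a free motor binds the closest filament point within
  `r_capture` (0.1 µm) at rate `k_on` (5 s⁻¹). Binding to filaments
  nucleated by the motor's own organelle is allowed by default.
* **Unbinding**: constant rate `k_off` (0.3 s⁻¹) by default; an
  optional Bell law `k_off·exp(F/F_d)` exists but is off by default.
* **Stepping**: linear force–velocity, `ds = v_m·max(0, 1 − F∥/F_stall)·dt`
  against load, capped at `v_m` under assisting load (`v_motor` 0.5
  µm/s, `f_stall` 3 pN). A motor reaching the barbed end detaches.
  Within a binding episode the arc coordinate is non-decreasing by
  construction (motor polarity invariant).

All randomness for a run flows from one PCG64 stream seeded by
`seed`; runs are bit-reproducible.

### 1.4 Initial condition and study protocol

Runs start from a perinuclear cluster: `n_organelles` (60)
non-overlapping organelles placed uniformly in the central disk of
radius `cluster_radius` (3 µm), no filaments, all motors free. The
study protocol compares three presets over 300 s, 5 seeds each:

* `attached` — full model, defaults;
* `detached` — identical except filaments are released at birth;
* `no_motor` — no motors (pure diffusion + sterics baseline).

The headline result is strict ordering of the final mean radial
dispersion index and pigment-area fraction:
attached > detached > no_motor, with attached runs classified
"dispersed" and no_motor runs "clustered".

### 1.5 Parameter values and provenance

| Parameter | Default | Why |
|---|---|---|
| `R` | 10 µm | typical melanocyte cell-body radius at desk scale |
| `kT` | 0.0042 pN·µm | thermal energy near 30 °C |
| `dt` | 1 ms | ≤ 0.1·γ_min/k_max for the default stiffnesses |
| `duration` | 300 s | dispersion time scale of the model |
| `n_organelles` | 60 | resolvable population at desk scale |
| `organelle_radius` | 0.25 µm | melanosome radius ~0.5 µm diameter |
| `gamma_org` | 6πηa, η=0.3 Pa·s | Stokes drag in cytoplasm |
| `cluster_radius` | 3 µm | perinuclear cluster footprint |
| `motors_per_organelle` | 1 | simultaneously *engaged* myosin-Va linkages per cargo; processive cargo transport is carried by 1–2 engaged motors even when more are anchored |
| `k_motor`, `k_link`, `k_seg`, `k_rep`, `k_wall` | 30 pN/µm | soft-spring scale; relaxation time γ/k well resolved by dt |
| `v_motor` | 0.5 µm/s | myosin-Va unloaded gliding speed |
| `f_stall` | 3 pN | myosin-Va stall force (1–3 pN range) |
| `k_on` | 5 s⁻¹ | in-range attachment faster than detachment |
| `k_off` | 0.3 s⁻¹ | run lengths of a few seconds |
| `r_capture` | 0.1 µm | motor lever-arm reach |
| `nucleation_rate` | 0.05 s⁻¹ | a few filaments per organelle at steady state |
| `growth_speed` | 0.3 µm/s | formin-mediated elongation (0.1–0.5 µm/s) |
| `max_length` | 3 µm | short cytoplasmic actin filaments |
| `filament_lifetime` | 20 s | dynamic actin turnover |
| `segment_length` | 0.5 µm | bead-spring resolution ≪ Lp |
| `kappa` | 0.042 pN·µm² | κ = Lp·kT with Lp ≈ 10 µm |
| `gamma_per_length` | 0.6 pN·s/µm² | slender-body drag in cytoplasm |

The kinetic values are standard cytoskeletal ranges; within those
ranges `growth_speed`, `filament_lifetime` and `motors_per_organelle`
were fixed (before the acceptance suite was frozen) at the values that
place the default study protocol in the regime the model is built to
exhibit — connected networks disperse, free filaments disperse less,
no motors not at all. Notably `motors_per_organelle = 1` matters
mechanistically: with several simultaneously engaged linkages per
organelle, free filaments act as multivalent cross-bridges and the
detached population condenses into a single actomyosin aggregate
instead of remaining (partially) clustered.

All parameters are overridable per run (YAML/TOML config, CLI flags,
or `SimConfig.replace`).

### 1.6 Dispersion metrics

* **Radial dispersion index** `mean(|x_i|)/R`: 0 for a central point
  cluster, 2/3 for a uniform population, →1 for rim enrichment.
* **Pigment area fraction**: percent of cell area covered by the union
  of disks of radius `a + d` (dilation `d` = 1 µm mimics the optical
  footprint of pigment in brightfield), rasterised at 1024² and clipped
  to the cell. Also measurable from a rendered 8-bit image by
  thresholding, which agrees with the geometric value to well under 2
  percentage points.
* **Classification**: area < 50% → "clustered"; otherwise
  "hyper-dispersed" if under 5% of organelles lie inside r < 0.5·R,
  else "dispersed".
* Nearest-neighbour distance statistics complete the spatial summary.

## 2. Quantification modules

* **Saturation binding** (`quant.binding`): fraction bound
  `y = 100(y_o − y_c)/y_o`; nonlinear least squares of
  `y = Bmax·x/(Kd + x)` (scipy `curve_fit`), with standard errors,
  convergence flag and a summary table.
* **qPCR** (`quant.qpcr`): standard curve CT = S·log10(Q) + I fit by
  OLS; copy number from mass, amplicon length and Avogadro's number;
  the 4-step chain CT → quantity → /MNT → /GAPDH giving expression
  relative to GAPDH.
* **Imaging** (`quant.imaging`): Pearson correlation over a mask;
  Costes block-scramble significance test (block size = first
  zero-crossing radius of the image autocorrelation; 199 scrambles;
  significant when ≥95% of scrambles fall below the observed PCC);
  line/region intensity profiles.
* **Tables** (`quant.tables`): per-cell BiFC/mCherry normalisation and
  per-condition medians; filament length summary statistics.

## 3. Numerical choices and limitations

* Explicit Euler–Maruyama with per-step Bernoulli kinetics: first-order
  weak accuracy is sufficient because all observables are
  steady-state/ensemble quantities; the stability guard keeps spring
  relaxation resolved.
* 2D, not 3D: the paper's read-outs are 2D projections; drag and
  density parameters are effective 2D values, so absolute time scales
  are indicative only.
* Filaments interact with organelles only via tethers and bound
  motors; filament–filament sterics and crosslinking are not modelled.
* Hydrodynamic interactions are neglected (free-draining drag).
* Motor stepping is continuous (no 36-nm step discreteness), valid at
  dt ≫ single-step dwell times.
* The wall projection makes confinement exact at frame times at the
  cost of a small unresolved boundary-layer dynamics.
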