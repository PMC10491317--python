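# Methods

Models, parameter choices, numerical methods and known limitations for each
module of `actonem`. All defaults below are the package's study conditions:
they are what the examples, the pipeline, and the acceptance script use
unless explicitly overridden.

## 1. Motor-cluster stepping (`actonem.motors`)

### Model

Each myosin head cycles irreversibly through three states:

1. unbound, ATP-loaded → (rate `k12`) → 2. bound, post-powerstroke →
(rate `k23`) → 3. bound, nucleotide-free → (rate `k31_per_atp · [ATP]`) → 1.

Only the 1→2 transition moves the head: a binding head attaches at a
position drawn from `Normal(anchor + s/2, s/2)`, where `s` is the
coarse-grained step length. The cluster anchor is the position of the
rearmost bound head plus `s/2`; a cluster with no bound heads keeps its last
anchor (it diffuses with the background and re-engages where it was). All
heads of a cluster of size `valency` run independent copies of the cycle;
the composite process is simulated exactly with the Gillespie algorithm
(exponential waiting times, rate-proportional event selection).

Single-filament observables: gliding **velocity** = total anchor
displacement per unit attached time, and **run length** = anchor
displacement per continuous attachment episode, *including* the reposition
produced by the episode's first binding event. That convention matters: at
high [ATP], episodes are often a single binding-unbinding pair and the first
reposition dominates the run length.

Two-filament observables, for one cluster shared between two antiparallel
filaments (heads alternate targets): the pair **strain rate** `eps` =
relative sliding speed / filament length (length 1 µm, so numerically the
relative speed), and the **crosslinking probability** `Pcl` = fraction of
time at least one head is bound to *each* filament.

`duty_ratio(atp)` is closed-form: the bound fraction of the cycle,
`(1/k23 + 1/(k31_per_atp·atp)) / (1/k12 + 1/k23 + 1/(k31_per_atp·atp))`.

### Parameters and why

| parameter | default | rationale |
|---|---|---|
| `s` (step length) | 0.40 µm | coarse-grained displacement per binding event of a cluster on a filament, not the ~5–10 nm single-head powerstroke; chosen jointly with the rates to satisfy the benchmarks below |
| `k12` | 6.0 s⁻¹ | attachment rate |
| `k23` | 250 s⁻¹ | powerstroke/ADP-release, fast and ATP-independent |
| `k31_per_atp` | 0.22 s⁻¹µM⁻¹ | ATP-induced detachment, the only [ATP]-dependent rate |
| `valency` | 4 | tetramer, the reference cluster |
| filament length | 1 µm | short-filament nematic regime |

The four rate/step numbers are a calibrated, frozen set: they were selected
(see `calibrate_rates`, which reproduces the procedure) so that a tetramer
matches the single-filament benchmarks
**v ≈ 0.5 µm/s, run ≈ 4 µm at 10 µM ATP** and
**v ≈ 10 µm/s, run ≈ 0.5 µm at 500 µM ATP** (`TETRAMER_TARGETS`).
`scripts/acceptance.py` re-measures these from scratch.

### Numerics

Two engines produce statistically identical results: a numba-compiled core
(default) and a pure-Python reference used to test it. Episodes are capped
(`max_episodes`) to bound runtime; summaries report the episode count so
callers can check statistical weight. Runs at `atp = 0` stall (state 3 is
absorbing) and are flagged rather than averaged silently.

### Limitations

- The cycle is strictly irreversible and unloaded — no force–velocity
  relation, no back-stepping, no strain-dependent detachment.
- With this calibration the tetramer pair strain rate `eps(atp)` rises up to
  ~100 µM and then *declines*: above the detachment-dominated crossover the
  cluster spends too little time doubly bound to shear the pair faster. A
  monotone `eps` over 1–1000 µM and the four single-filament benchmarks
  could not be satisfied simultaneously anywhere in the explored rate space;
  we kept the benchmarks (they are the directly measured quantities) and
  document the non-monotone tail as a model limitation. One acceptance test
  asserts the monotone version and is deliberately left failing.

## 2. Micro-to-hydrodynamics scaling (`actonem.scaling`)

Activity and elasticity are built from the pair micro-curves:

- `alpha(atp) = eps(atp) ** beta` with `beta = 0.1` — a weak power law so
  activity saturates while elasticity still varies.
- `K(atp) = K0 + kappa · (cm · Pcl(atp) + cp)` with `K0 = 0.001`,
  `kappa = 10 K0`, motor concentration `cm = 1`, passive crosslinker
  concentration `cp ≥ 0`. Motor crosslinking contributes elasticity in
  proportion to its duty on filament pairs.

Force balance gives `v = sqrt(K·alpha)/eta` and `ell = sqrt(K/alpha)`;
`predict_curves` also returns peak-normalized versions. At a speed maximum
interior to the grid, `alpha_peak = -K·alpha'/K'` (primes are d/d[ATP]);
`locate_peak` reports the residual of this identity as a self-check.

Peak location: raw 16-point central differences on a log grid carry ~16%
identity error, so `locate_peak(refine=True)` (default) interpolates
`alpha(log atp)` and `K(log atp)` with shape-preserving PCHIP splines,
finds the maximum of `sqrt(K·alpha)` on a 20001-point dense grid, and
evaluates the identity with spline derivatives (residual ~1e-4). PCHIP is
used because it is monotonicity-preserving: it cannot manufacture spurious
extrema from noisy micro-curves. Boundary maxima are reported as
non-interior; flat curves as degenerate.

## 3. Flow-field analysis (`actonem.flow`)

### Optical flow

`optical_flow` implements Horn–Schunck with a 3-level Gaussian pyramid and
3 re-warping passes per level (`scipy.ndimage.map_coordinates`, cubic,
wrapped), smoothness weight 0.5, 100 Jacobi iterations per warp. Pyramid +
warping is needed because nematic textures displace by several pixels per
frame at the default frame interval; single-level HS only captures
sub-pixel motion. Horn–Schunck (global smoothness) was chosen over local
least-squares (Lucas–Kanade) because dense nematic textures have aperture
problems that a global regularizer handles gracefully; the iterative
Lucas–Kanade estimator from scikit-image is used as an independent
cross-check in the tests, not in the pipeline. Velocities are returned in
physical units via `pixel_size` (µm/px) and `dt` (s/frame); defaults 1.0
and 2.0.

### Observables

- `mean_and_rms_speed`: mean and RMS of `|u|` over all pixels/frames.
- `velocity_autocorr_length`: the radially averaged, FFT-based spatial
  autocorrelation of `(ux, uy)` (zero-padded, overlap-count normalized so
  finite-window bias is removed), normalized to 1 at r = 0; `ell_corr` is
  the 1/e crossing with linear interpolation. If the profile never reaches
  1/e inside the window the last radius is returned with
  `ell_corr_is_lower_bound = True` instead of guessing.
- `ell_vort`: the radius of the maximum of the tangential azimuthal average
  of the vorticity–velocity cross-correlation,
  `C(r) = ⟨ω(x) u(x+r)⟩ · t̂(r)` with `t̂` the in-plane tangential unit
  vector, normalized by RMS ω and RMS |u|. The peak is refined with a
  3-point parabola; the SD comes from splitting the movie into 5
  non-overlapping frame subsets.

### Known estimator bias

For a Gaussian-core model vortex `u_θ = v0 (r/a) exp((1 − (r/a)²)/2)` the
cross-correlation response is exactly `∝ r (1 − r²/8a²) exp(−r²/4a²)`,
which peaks at `r = a·sqrt(7 − sqrt(33)) ≈ 1.1205 a`. The estimator is the
standard one but it is **intrinsically ~12% high** relative to the core
radius for this vortex shape; we report the raw peak (it is the defined
quantity) rather than applying a shape-dependent correction. Tests and
validation accept recovery within 15%. Single frame-filling vortices add
further edge inflation; validation fixtures use several well-separated
vortices on grids ≥ 192².

### Finite-window limits

The autocorrelation length of an exponentially correlated field is
recovered within ~10% (averaged over seeds) when the true length is below
roughly 1/25 of the domain size; longer correlation lengths push the 1/e
crossing into the poorly sampled tail and trigger the lower-bound flag.

## 4. Active nematohydrodynamics (`actonem.lb`)

### Model

Hybrid solver on a periodic 2-D lattice:

- **Fluid**: D2Q9 lattice Boltzmann, single-relaxation-time (BGK) collision
  with Guo forcing; kinematic viscosity `eta = (tau − 1/2)/3`; the physical
  velocity includes the half-force correction `u = (Σ f_i c_i + F/2)/rho`.
- **Order tensor**: the traceless symmetric 2-D `Q` is carried as
  `(qxx, qxy)` — tracelessness is exact by construction — and evolved with
  an explicit finite-difference Beris–Edwards equation: advection,
  flow-alignment/corotation with parameter `xi`, and relaxation
  `Γ H` toward the minimum of the Landau–de Gennes bulk potential plus
  elastic term `K ∇²Q`.
- **Coupling back**: body force `F = ∇·(σ_active + σ_elastic)` with
  extensile active stress `σ_active = −alpha Q` and the Ericksen elastic
  stress `−K (∂_i Q : ∂_j Q − δ_ij |∇Q|²/2)`.

The bulk potential, written in the scalar order `q = sqrt(2 tr Q²)`, is
`f(q) = A0 [ (1 − U/3)/3 · q² − (2U/27) q³ + (U/9) q⁴ ]`, the uniaxial
reduction of the standard three-dimensional Landau–de Gennes form. Its
ordered minimum has the closed form
`q_eq = 1/4 + (3/4) sqrt(1 − 8/(3U))`; `equilibrium_order` finds the
minimum numerically (bounded search above the unstable root) and the tests
cross-check it against the closed form. At the defaults `A0 = 0.1`,
`U = 3.5`: `q_eq = 0.6160 ≈ 0.62`. For `U ≤ 8/3` the ordered minimum
disappears (`(0, False)` is returned).

### Parameters and why

`tau = 1.5` (viscosity 1/3, comfortably stable), `xi = 0.7` (flow-aligning),
`Gamma = 0.13`, `A0 = 0.1`, `U = 3.5`, `K = 0.04`, `alpha = 0.005`,
128 × 128 lattice, 3000 warm-up + 3000 sampling steps, sampling every 50.
These are standard active-turbulence lattice units; the lattice is scaled
down from production sizes so a full run takes ~40 s of wall time on one
core while still developing many vortices. Initial condition: uniform order
at `q_eq` with 1% angular noise to seed the bend instability.

### Diagnostics and validation

`run_turbulence` returns an `EnergyTrace` (kinetic energy
`⟨ρ|u|²⟩/2` with the force-corrected velocity, and mean order) plus the
final state; non-finite fields raise `BlowUpError` rather than returning
garbage. The solver is validated by: exact mass and momentum conservation;
a uniform ordered state being stationary; a decaying shear wave reproducing
`eta = (tau − 1/2)/3` within 5%; passive relaxation of perturbed order; and
— the physically meaningful passive-decay check — an imposed sinusoidal
shear flow at zero activity decaying to ≤ 1e-10 of its initial kinetic
energy, confirming that without active stress the model is purely
dissipative. (A fully unforced passive run never reaches machine zero: the
relaxing Q field exerts a tiny elastic force that itself decays at the slow
rate `~Γ K k²` per step, so the imposed-flow version is the meaningful
formulation of "passive flows decay".) In the turbulent regime, mean
kinetic energy increases with `alpha` and — at fixed high activity — with
`K`, and `ell_vort` of the steady velocity field decreases with `alpha`.

### Limitations

BGK with explicit Q-update is first-order accurate in the coupling;
parameters are reported in lattice units only (no physical unit map is
asserted); the 2-D `Q` has no biaxiality by construction; defect-level
observables (±1/2 tracking) are out of scope.

## 5. Synthetic data (`actonem.synthetic`)

All generators are deterministic given `seed` and return ground truth
alongside the data.

- `make_vortex_field` / `make_vortex_movie`: sums of Gaussian-core vortices
  `u_θ = v0 (r/a) exp((1 − (r/a)²)/2)` (peak tangential speed `v0` exactly
  at `r = a`) placed by rejection sampling with `min_separation = 3a` by
  default, on a periodic domain. Ground truth for `ell_vort` validation is
  the core radius `a`.
- `make_correlated_field`: spectral synthesis with power spectrum
  `S(k) ∝ (1 + (kL)²)^{-3/2}`, whose 2-D transform gives an exactly
  exponential velocity autocorrelation `C(r) = exp(−r/L)`; normalized to a
  target RMS speed. Ground truth for `ell_corr` is `L`.
- `make_nematic_movie`: renders a polarized-fluorescence-style texture
  `I = base + contrast · cos²(θ − θ_pol)` from a smooth random director
  field, advects it with a supplied (or default single-vortex) velocity
  field by semi-Lagrangian backtracking (cubic, wrapped), and adds Gaussian
  noise (`noise_sd = 5`). Defaults: 8 frames, 128², `base = 200`,
  `contrast = 600`.
- `make_toy_micro_curves`: smooth Michaelis–Menten-style
  `eps = eps_max · atp/(atp + 50)` and logistic `Pcl = 1/(1 + atp/50)` for
  fast scaling-layer demos without running the motor simulation.

### Realism limits

The movies are advected static textures: no photobleaching, no defect
creation/annihilation, no intensity fluctuation from order-parameter
dynamics, shot noise approximated as additive Gaussian. Cubic interpolation
overshoots the `cos²` intensity bounds by a few percent on advected frames.
The vortex fields are not divergence-free superpositions on the torus
(individual vortices are, their periodic images are truncated); with the
default separation the residual divergence is negligible. These fixtures
validate the measurement chain, not the microscopy.

## 6. Pipeline (`actonem.pipeline`, `actonem.cli`)

`SweepConfig` is a frozen dataclass with YAML round-trip and a manifest
(config SHA-256, seeds, package version) for provenance. Defaults — the
study conditions: 16-point log-spaced [ATP] grid on [1, 1000] µM, cluster
valencies (3, 4, 8), seeds (0..4), 1000 s of simulated time per condition,
`kappa = 10 K0`, `cp ∈ {0, 0.25, 1.0}` for the crosslinker sweep.

Micro-curves are computed once per (valency, seed) and reused across all
scaling parameters, so e.g. the `cp` sweep is bit-identical at the
micro-level by construction. Peaks are located on seed-mean curves; per-seed
tables are retained for error estimation. `write_sweep_result` emits CSV
tables plus the JSON manifest.

The CLI (`actonem`) is a thin veneer: every subcommand
(`simulate-motors`, `sweep`, `predict`, `analyze-flow`, `simulate-lb`,
`make-fixtures`) calls the same public API an interactive user would.
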