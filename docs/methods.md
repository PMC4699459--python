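# Methods

## Model

A ParB-coated bead of radius `R` sits on a surface carrying DNA-bound
ParA-ATP.  Two Gaussian-range interactions, both centered on the bead,
drive everything:

- **Removal**: ParB stimulates ParA hydrolysis and release within range
  `σ_r`, depleting the surface concentration at rate
  `exp(−(x−x_p)²/2σ_r²)·a`.
- **Attraction**: each surface ParA pulls the bead with a force of range
  `σ_f` directed along the surface component of the separation vector.

The bead is overdamped (Stokes drag `β = 6πηR`), so its velocity is the
force integral divided by `β`.  Rescaling lengths by `R`, time by `1/γ₀`
and concentration by `a₀` leaves two parameters: the force scale
`A₀ = F₀a₀/(βR)` and the range ratio `c = σ_r/σ_f`.  In these units the
force kernel is `exp(−u²/2)·u/(1+u²)` with `u = x − x_p` (the `1/(1+u²)`
factor is the geometric projection onto the surface for a bead of unit
radius), and the removal kernel is `exp(−u²/2c²)`.

Measured numbers motivate `c ≈ 0.2–0.4`: a bead carrying ~4800 engaged ParB
at the ~5:1 ParB:ParA ratio needed for motion must reach ~1000 ParA, which
at 400 ParA/µm² covers ~2.5 µm²; reading `σ_f` as the radius of that disc
gives ~0.9 µm, against a measured removal radius of ~0.23 µm.  The
disc-radius reading is our choice; it reproduces the reported ~0.9 µm
force range from the coverage area.

The only randomness is iid uniform noise (half-width `δa`, default
`0.05·mean`) on the initial ParA field.  A perfectly flat field is an
unstable symmetric fixed point; any noise seeds a net force, the bead
drifts, deepens the asymmetry, and settles into ballistic motion behind a
self-generated wavefront.

### Rebinding

The substrate carries a binding-site concentration `d(x)` (mean `D₀`,
uniform noise `δd`, default 0.05).  Free buffer ParA `a_b(τ)` (well mixed —
buffer diffusion is fast) rebinds at rate `a_b·(d−a)·(k_r + k_c·a)`; the
`k_c` term favours sites that already hold ParA (cooperativity).  Removed
ParA returns to the buffer uniformly, divided by the domain length `L`
(area `L²` in 2D), so `∫a dx + L·a_b` is conserved — our discrete update
uses the same Simpson weights for the field and buffer budget, making the
conservation exact to rounding.  Before the bead is introduced the surface
is equilibrated against the buffer (rebinding-only dynamics, adaptive Euler,
terminated when the fastest pointwise binding rate falls below 1e-8).  With
`k_c = 0` this relaxes to uniform fractional occupancy `a = min(φ,1)·d`, so
the initial spatial noise of a rebinding run is `φ·δd`.

The saturation ratio `φ = A_s/D₀` controls the phenomenology: undersaturated
surfaces (`φ < 1`) let the wavefront grow without bound (persistent
acceleration, never a stall); saturated surfaces (`φ > 1`) cap the
wavefront (constant speed) and, for fast enough recovery, refill the wake
and prevent motion entirely above a boundary `φ_stop(k_r, k_c)`.

### Surface diffusion

With no buffer, bound ParA can instead spread along the surface, limited by
the local binding capacity: the flux term is `κ·[d·∂²a/∂x² − a·∂²d/∂x²]`,
which vanishes identically when `a ∝ d` and therefore preserves the
capacity bound and the noise structure of `d(x)` that seeds motion.
Diffusion-mode runs start at uniform fractional occupancy `a = φ·d` (our
reading of "all sites carrying ParA equal to the binding distribution"
while still honouring a total ParA of `φ·D₀` per unit length; recorded as a
package choice).  Second derivatives are central differences with zero-flux
(mirrored-node) boundaries, which conserves surface ParA in the uniform-`d`
limit; `d''` is taken from the stored noisy `d(x)` without smoothing.

### Traveling-wave analytics

Assuming constant speed `v`, the removal equation integrates in the
co-moving coordinate `ξ = x − vτ` to

    a(ξ) = exp(−(c/v)·√(π/2)·erfc(ξ/(c√2))),

a wavefront rising to 1 ahead of the bead with wake floor
`exp(−c√(2π)/v)` behind it (for `c = 0.5`, `v = 1` the floor is ≈ 0.286,
not 0 — the wake is only partially depleted).  Balancing the force of this
profile against drag gives a scalar equation `v = A₀·F(v; c)` solved by
bracketing and Brent's method on `v ∈ [10⁻³, 10]`; if the force cannot beat
drag even at the lower bracket the stalled branch `v* = 0` is reported
(`v = 0` is always a trivial solution; only a positive root counts as
motion).  In 2D the bead is taken to move along `x`, each point's removal
history carries the lateral Gaussian factor `exp(−y²/2c²)`, and the vector
force uses the Euclidean distance kernel; the lateral force component
vanishes by symmetry.  The speed curves cross near `c ≈ 0.3`: below it the
2D wake is thinner than the force range, leaving attractive ParA beside and
behind the bead, so 1D is faster; above it 2D wins.

## Numerics

- **Grid**: node-centered, both endpoints included, `round(L/dx)+1` nodes
  with the interval count forced even so composite Simpson's rule covers
  the whole domain (spacing adjusted minutely when needed).  Defaults
  `L = 70`, `dx = 0.02` (1D) and `L = 20`, `dx = 0.05` (2D, desk-scale);
  validation requires `dx ≤ c/5` to resolve the removal kernel.
- **Time stepping**: explicit Euler, `dτ = 0.01` (≤ 0.1 enforced).  The
  velocity is evaluated on the pre-update field, then field and bead
  advance simultaneously; this Jacobi-style ordering makes the symmetric
  state an exact fixed point.  Negative concentrations are clamped to zero
  with a warning (with the default step the removal factor is 0.01, so
  clamping never fires in practice).  The rebinding update refuses steps
  large enough to push `a` above `d`; the diffusion update enforces the
  explicit-scheme stability bound `κ·max(d)·dτ/dx² ≤ ½` (which is why
  diffusion studies default to `dx = 0.1`: the reference spacing
  `dx = 0.02` would cap `κ` at 0.02, far below the stall regime).
- **Exact symmetry preservation**: node offsets from the bead are computed
  relative to the nearest grid node (`u = dx·(i − i_near) − δ`), and force
  reductions sum mirror-image node pairs first.  Offsets of an on-node bead
  are then exactly antisymmetric in floating point and symmetric fields
  give a velocity of exactly 0.0 — a noiseless centered run stays pinned
  for every step, not just to rounding error.  The grid is materialized as
  `dx·arange(n)`, so its right endpoint may differ from `L` by one ulp;
  that is the price of the exact antisymmetry.
- **Force quadrature**: composite Simpson over the entire domain — no
  kernel truncation; the Gaussian makes far contributions negligible
  anyway.  The discontinuity of test fields (half-plane oracle) is placed
  on an even node so Simpson panels are not smeared.
- **Boundaries**: the bead position is clamped to `[0, L]`; in the base 1D
  model a bead reaching an edge waits there (ParA never recovers), with
  rebinding it eventually returns, and in 2D it turns without halting.
- **Analytics quadrature**: 1D force functionals use adaptive quadrature on
  `ξ ∈ [−10, 10]` (the kernel's support) at tolerance 1e-8; 2D uses a
  cached tensor-product Simpson grid with spacing `min(0.04, c/8)` so the
  profile's `c`-scale structure stays resolved.  Roots in `v` are found by
  Brent to 1e-10, the 1D/2D crossover in `c` by Brent to 1e-3, optima by
  bounded scalar minimization on `c ∈ (0.05, 1)`.

## Trajectory analysis

Speeds are measured as an experimentalist would: fit a line to displacement
versus time, ignoring the lag.  The lag is the first time the instantaneous
speed exceeds 10% of the mean speed over the trailing half of the run (both
thresholds configurable); the slope is fit over that trailing window.  A
bead that never travels one bead radius within `tau_max` counts as stalled
(`tau_max = 500` for stall determinations; the displacement criterion is
our concrete reading of "did not commence motion").  `φ_stop` is located by
bisection on `φ ∈ (1, 2]` to 0.01, using `L = 20` — the scale at which the
released-ParA budget couples strongly enough to `k_r` for stalls to occur at
moderate `φ`.  Sweeps run replicated simulations with per-replicate seeds
derived from `(seed, replicate)` and report mean ± standard error; the
default replicate count is 20, enough to resolve the (small) seed-to-seed
scatter at desk scale.

Undersaturated acceleration is summarized by the single-parameter law
`v(τ) = v₀·L/(L − v₀·τ)` fit to the speed series with the clock re-zeroed
at motion onset.  Two honest caveats from our own runs (`φ = 0.2`,
`k_r = 1`, `c = 0.5`, `L = 20`, `A₀ = 1`): the simulated series actually
tracks the displacement form of the same law — `v·(L − x(τ))` is constant
to ~3% over the accelerating phase — while the time-linearized form above
(which replaces `x` by `v₀τ`) fits with r² ≈ 0.8–0.9 depending on the
onset convention, because the swept distance outruns `v₀τ` once the speed
has grown appreciably; and close to
the domain edge (within ~2 bead radii) the bead decelerates instead, a
finite-size effect outside the law's regime.  The stall boundary follows
`φ_stop(k_r) = 1/(k_r·Δτ) + 1` (fit in closed form; our defaults give
Δτ ≈ 4.7 — the constant depends on `A₀`, which is why we treat these laws
as form checks, not number checks).

## What the synthetic fields do and do not capture

The generator reproduces the modelling assumptions exactly: iid uniform
noise, uniform grids, a single bead starting at the domain center.  Real
assays have correlated DNA-carpet heterogeneity, bead-to-bead variation in
ParB load (which the model folds into `A₀`), thermal bead diffusion, and
stochastic molecule-level kinetics — none are modelled, so passing tests
validate the deterministic continuum theory, not those effects.  Known
limitations: single bead only; no ParB diffusion; explicit (non-adaptive)
integration; 2D rebinding equilibration assumes the same well-mixed buffer
as 1D.

## Problem sizes used in the tests

Simulation-backed checks run the reference 1D grid (`L = 70`, `dx = 0.02`)
for speed comparisons, `L = 20` for stall and acceleration studies, 20
replicates for noise ensembles and 5 for trend fits, and 2D lattices up to
201² nodes — sizes chosen so the whole suite completes on a laptop while
leaving every qualitative regime (lag, ballistic, accelerating, stalled)
clearly resolved.
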