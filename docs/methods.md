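# Methods

## Scope and state variables

The package simulates the fate of one buoyant polyethylene particle
released at the ocean surface, as three coupled mass pools: a surface
size spectrum (mg per size bin), exported parcels in vertical transit,
and an absorbing sediment pool.  Only mass is tracked; particle numbers
are never formed, so every operation is an expectation dynamics and mass
conservation is exact by construction (asserted to 1e-9 relative in the
tests, achieved at machine precision).

## Fragmentation cascade

Each monthly step erodes a fixed fraction `degradation_rate` (default
0.0045 month⁻¹, an empirically motivated surface-weathering rate for
polyethylene) from every non-terminal bin and redistributes it over the
strictly smaller bins with negative-binomial weights
Γ(k+f)/(Γ(k+1)Γ(f)) pᵏ(1−p)ᶠ, renormalised per source column.  The two
smallest bins (nominal 25 and 75 µm) are terminal: mass arriving there is
moved to a cumulative export account at the end of the month and is
excluded from further fragmentation, because those sizes fit within a
fresh 1 mm marine snow aggregate (threshold rule below) and leave the
surface on a time scale (~days) far below the monthly cascade resolution.

**k-indexing convention.**  The PMF argument k must be mapped onto
destination bins, and the direction of that mapping is a genuine design
choice with first-order consequences:

* `from_smallest` (default): k = 1 is the smallest bin.  Small p then
  concentrates eroded mass in the smallest, exportable sizes — lowering p
  accelerates surface mass loss, raising p (or f) shifts eroded mass into
  mid-size bins that stay buoyant longer.
* `steps_down`: k = 1 is the adjacent smaller bin, so the cascade moves
  mass one size class at a time and the sensitivity to p reverses.

We default to `from_smallest` because the resulting parameter responses
(faster surface clearance at low p, greater retention at high p or f,
small f favouring the production of the smallest fragments) match the
reported behaviour of the modelling framework this package
re-implements; both conventions are first-class and selectable via
`k_convention`.

**Known limitation.**  A constant erosion fraction makes the largest-bin
mass decay exactly exponentially (502.65 mg → 292.56 mg after 120
months at defaults).  Weathering histories in which the specific erosion
rate slows over time — e.g. because an oxidised crust shields the core —
cannot be represented without a state-dependent rate, which is out of
scope; comparisons against decelerating reference decay curves should
expect the difference.

## Water column

The environment is a static 1-D column (default 5100 m, 10 m grid) with
linear interpolation between nodes.  The synthetic generator emulates a
subtropical gyre: SST 24 °C relaxing exponentially (300 m scale) to
1.5 °C at depth; seawater density rising monotonically 1023.5 → 1027.8
kg m⁻³ (400 m scale); total particulate matter 25 µg L⁻¹ at the surface
decaying (400 m scale) to a 10 µg L⁻¹ deep floor; shear 0.2 s⁻¹ through a
100 m mixed layer, decaying below (200 m scale, 10⁻³ s⁻¹ floor);
dynamic viscosity constant at 1.08e-3 kg m⁻¹ s⁻¹ (overridable per depth).
These are field-typical magnitudes chosen once, not fits.  What the
generator does **not** emulate: seasonality, mixed-layer dynamics,
salinity-resolved density, mesoscale variability, and any covariance
between shear, stratification and particle load.  Tests passing on this
column therefore demonstrate internal consistency and realistic orders of
magnitude, not site-specific transit times: those depend strongly on the
particulate-matter profile (which sets recapture waiting times) and on
the thermal profile (which sets aggregate attenuation).

## Settling cycles

MP capture by marine snow is an inhomogeneous encounter process with
hazard λ(z) = [β_shear + β_settling + β_Brownian](z) · N_MSA(z), with
N_MSA = TPM / 2.5 µg.  In the default deterministic mode a waiting episode
ends when ∫λ dt reaches 1 (equal to the expected waiting time 1/(βN)
under uniform conditions); `stochastic_exponential` mode draws the target
from a seeded unit-exponential instead.  While incorporated, the particle
moves at the aggregate's Stokes velocity computed from the fixed
effective density excess (1.2 kg m⁻³); the aggregate diameter attenuates
as d′ = −L·d only below the euphotic depth (100 m).  Detachment fires
when aggregate mass loss strictly exceeds 40 % (1 − (d/d₀)³ > 0.4, i.e.
d < 843.4 µm) or when the incorporation threshold y(d) falls below the MP
diameter; with default parameters the mass-loss rule always fires first
for 25 and 75 µm MPs, at 161 µm threshold margin.  Recapture uses a fresh
ambient 1 mm aggregate.  An MP reaching the surface waits there; it is
not returned to the fragmentation pool (it is already terminal-size, and
re-entry would double-count its mass).

**Integrators.**  The reference integrator is a fixed 1-minute step
(configurable).  The `event` integrator takes adaptive steps (≤ 0.25 d,
≤ 5 m of settling, ≤ 0.25 % diameter shrink, trapezoidal hazard with the
step cut at the capture crossing, exact landing on the euphotic boundary
and on the detachment threshold) and reproduces fixed-step transit times
within 0.3 % on test columns — against an analytic solution on a uniform
column both agree to 5 significant digits — at ~300× fewer steps.  The
strictness of the detachment inequality matters at the threshold itself:
the event integrator deliberately lands just *past* the threshold so both
integrators see the same cycle boundaries.

## Coupling

Because the column is static, all parcels of one terminal size class
share a single trajectory; the driver integrates one template per class
and convolves monthly exports with the template transit time (a parcel
exported at month m is column mass until m + τ, sediment after).  This is
exactly equivalent to per-parcel integration (asserted to 1e-6 relative
on a 2-yr run) and reduces ~10⁹ minute-steps per century to ~10⁶.
Months are 365.25/12 = 30.4375 d.  A template that hits the integration
time cap (default 3650 d) leaves its parcels in the column permanently —
with default parameters both size classes reach the bottom in well under
two years, but extreme parameter choices (e.g. very light aggregates with
fast attenuation) can stall the 75 µm class legitimately.

Snapshots default to 10/30/75/100 yr over a 100 yr horizon; the
sensitivity sweep varies degradation rate (0.00045/0.0045/0.045
month⁻¹), p (0.1/0.3/0.5) and f (0.1/0.3/0.5) one at a time and reports
the surface-bin masses after 100 yr, using fragmentation-only runs since
terminal export makes the surface state independent of every
sedimentation parameter (also asserted in the tests).

## Numerical and I/O choices

* Negative-binomial weights are computed in log space (`gammaln`) for
  stability at large k or small f.
* All tabular output is CSV with `%.17g` floats and `# key: value`
  provenance headers; reads use round-trip float parsing, so a written
  profile reloads bit-identically.
* Degenerate inputs: zero degradation rate is the identity map; a
  zero-mass spectrum is a fixed point; `months=0` returns the initial
  state; non-incorporable MP sizes (above the 162 µm threshold of a
  fresh aggregate) are rejected before integration.
* All randomness flows from the single configured seed; the default
  expected-time mode uses none.

## Limitations

Single polymer and single release pulse; no biofouling pathway, no
aggregate production/coagulation dynamics, no MP load feedback on
aggregate density or settling, no seabed resuspension, and no horizontal
transport.  Transit times on the synthetic column are
order-of-magnitude results (hundreds of days), not site predictions.
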