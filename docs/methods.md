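# Methods

## Kinetic model

The droplet is a well-mixed compartment. Unbound Y-motifs (count N_u)
disappear through two channels:

* **Diffusive escape.** The dextran/PEG interface acts as a semi-permeable
  layer of thickness w; the concentration gradient across it is
  N_u/(V·w), giving a first-order loss rate a = D·A/(V·w) with the
  Stokes–Einstein coefficient D = kT/(6πηr). For a cylindrical well whose
  droplet fills it with a flat interface at the mouth, A/V = 1/h exactly,
  so a = D/(h·w) and a is independent of well diameter.
* **Coagulation.** Motif–motif collisions are irreversible and every dimer
  is assumed to join a single growing aggregate, which cannot escape. The
  monodisperse Brownian kernel α = 8kT/(3η) gives the pairwise rate
  b = α/(2V).

The pair dN_u/dt = −aN_u − bN_u², dN_g/dt = bN_u² has the Riccati solution

    N_u(t) = a N0 e^{−at} / (a + b N0 (1 − e^{−at}))

(the coagulation hyperbola N0/(1 + bN0t) when a = 0), and integrating
b·N_u² to infinity gives the steady-state gelled count

    N_g(∞) = N0 − (a/b) ln(1 + b N0 / a).

Both closed forms are verified in the test suite independently of the
solver — the first by substituting a central-difference derivative into the
ODE, the second against numerical quadrature of b·N_u² over the analytic
trajectory — and only then used as oracles for the numeric integrator.

A third state, N_lost, accumulates a·N_u so that N_u + N_g + N_lost = N0 is
a checkable conservation law on every trajectory.

### Solver

`scipy.integrate.solve_ivp` with LSODA (stiffness-switching), analytic
Jacobian, rtol 1e-9 and atol 1e-3 counts by default. Tiny negative
undershoots are clipped to zero. Steady state is reached by integrating to
40/a (diffusion-dominated tail) or 1e8/(b·N0) when a = 0; at the default
tolerances the endpoint agrees with the closed form to better than 1e-4
relative, and at rtol 1e-12 the whole trajectory agrees to 1e-6.

### Annealing

A round boundary moves all gelled motifs back to the unbound pool
(N_u ← N_u + N_g, N_g ← 0); escaped motifs never return. Each round is by
default integrated to quasi-steady state, because gelation completes in
seconds (≲10 s at default parameters) while the experimental cooling takes
minutes; a fixed `round_duration` mode exists. The model is isothermal —
the temperature dependence of η and D during cooling is neglected. The
exponential cooling profile T(t) = T_amb + (T_hot − T_amb)·e^{−t/τ}
(defaults 75 °C → 25 °C, τ = 30 s; τ is not experimentally constrained and
is config-exposed) is provided for synthetic schedules only and never feeds
back into the rate constants.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| T | 298 | K | room temperature |
| η | 1e-2 | Pa·s | dextran-phase viscosity |
| r | 5e-9 | m | motif arm length scale (~20 bp); the source prints "r = 5" without units and 5 nm is the physically consistent reading |
| w | 4e-8 | m | interfacial-region thickness of polymer ATPSs |
| ρ_g | 14e-6 | mol/L | measured motif concentration inside DNA gels |
| λ | 5 | — | simulated polymer compaction under crowding + spermine |
| well depth h | 100e-6 | m | device microwell depth |

Interface area: the default `disc_at_mouth` takes the droplet to fill the
well with a flat interface (A = π(d/2)²). Because A/V is then 1/h for every
diameter, a and b·c are diameter-independent under this choice and the
concentration dependence of r_g differs between well sizes only through V.
A `spherical_cap` alternative (droplet bulging to meet the mouth at a
contact angle) is provided because 100-µm wells hold droplets smaller than
the well; no claim is made about which geometry the original analysis used.

Counts vs moles: model state is absolute motif count; molar quantities
convert through a single pair of functions in `gelwell.units`
(Avogadro × 1000 L/m³), unit-tested both ways.

## Wetting classifier

A particle stays at the interface iff |γ_p,PEG − γ_p,dex| < γ_dex,PEG
(strict). The two complementary branches are the standard wetting
completion: when PEG contact is costlier by at least γ_dex,PEG the particle
is engulfed in dextran, and vice versa; exact equality is classified as
engulfed. No contact-angle or partial-engulfment geometry is modelled.

## Synthetic scenes

The generator emulates a confocal field of a microwell array: a 1.8 mm ×
1.8 mm field at 3.5 µm/pixel. 1.8 mm / 3.5 µm = 514.3, so the grid is fixed
at 514 × 514 — within half a pixel of the stated field. Coordinates are
0-based, row-major, pixel-center convention (physical = (index + 0.5) ·
pixel size).

Wells sit on a square lattice (pitch defaults to twice the well diameter;
the real pitch is not documented). Per well: one droplet disc with a
truncated-normal radius, and a categorical number of particles (default
P(0) = 0.02, P(1) = 0.93, P(2) = 0.05, emulating the observed near-one
particles-per-well means with small excess). Particles are placed on the
droplet rim circle — where they accumulate experimentally — or at the
center (the high-spermine, convection-driven single-aggregate case).
Same-well rim particles keep a guard band of two particle radii plus three
pixels of chord so their rendered discs remain separable under
8-connectivity labelling.

Rendering draws projected discs (a 2D confocal slice, matching how areas
were measured, not 3D spheres) with anti-aliased edges: per-pixel coverage
clip(r + ½ − d, 0, 1) in pixel units, which reproduces the true disc area
to sub-pixel accuracy (checked against 10× supersampled rasterization).
Dextran channel = background + droplet discs; DNA channel = background +
dim droplet-wide level (unbound motifs) + bright particle discs,
contributions additive. Noise is seeded Gaussian read noise plus optional
Poisson shot noise, clipped at zero. One root seed feeds independent
substreams for droplet radii, occupancies, particle radii, rim angles and
noise, and is recorded in the emitted spec JSON; outputs (two TIFFs, truth
CSV, spec JSON) are byte-stable for identical inputs.

What the scenes do **not** emulate: optical PSF / confocal sectioning,
photobleaching, cross-channel bleed-through, uneven illumination,
convection dynamics, or background structure in the PEG phase. Passing the
recovery tests therefore shows the quantification logic is correct on
idealized imagery, not that it is robust to every real-microscopy artifact.

## Quantification pipeline

Global threshold per channel (pixel == threshold counts as foreground;
default is Otsu's value since only "a uniform threshold" is documented,
with an explicit override for bit-exact runs), connected-component
labelling (8-connectivity, the ImageJ Analyze Particles convention; 4 is
available), physical-units area filter at 1 µm² to suppress noise — at
3.5 µm/px one pixel is 12.25 µm², so the filter only bites on finer pixel
grids, where the tests exercise it — and equivalent-radius conversion
r = √(A/π). The projected-circle formula applies to both channels: a
microwell-shaped (cylindrical) droplet seen from above and a spherical
particle both project to discs. Holes inside components are not filled.
Channel-specific thresholds are used and recorded in the summary output.
Particles-per-well is count(DNA objects) / count(dextran objects);
summaries report mean and sample (n−1) standard deviation of radii, with
NaN markers when undefined (n = 0 or 1).

`match_to_truth` greedily pairs detections to ground-truth objects
closest-first within a distance cap (ties broken by index), yielding
precision, recall and per-object radius errors independent of record order.
Under heavy noise the matched-detections mean radius is the right recovery
statistic: at 3.5 µm/px single-pixel speckle survives the 1 µm² filter, and
matching excludes such spurious components without touching thresholds.

## Numerical and design notes

* Degenerate inputs: zero initial count short-circuits to an all-zero
  trajectory; a = b = 0 yields constant N_u; zero detected droplets raises
  rather than returning an infinite ratio.
* The large-a·t branch of the closed form is written with e^{−at} so it
  underflows to 0 instead of overflowing.
* Sweep tables are deterministic row-per-(concentration, geometry) frames;
  the comparison report joins them with measured summaries on exact
  condition keys and flags the sign of the model's concentration trend per
  well size.
* Problem sizes in the test suite: 20 synthetic scenes at 514² for recovery
  checks, 22–25 random parameter triples spanning six orders of magnitude
  for the oracle equivalence — sizes chosen to exercise the contracts while
  keeping the default run in seconds.

## Limitations

* Monodisperse Smoluchowski kernel and a single aggregate: no size
  spectrum, no nucleation statistics, so the model predicts one radius per
  condition, not a distribution.
* The well-mixed assumption drops spatial gradients and the convective
  flows that in reality help merge aggregates.
* Escaped motifs are irreversibly lost; re-entry from the PEG phase in
  later rounds is assumed impossible.
* No temperature-dependent hybridization thermodynamics; gelation is
  treated as instantaneous, irreversible binding at the isothermal ambient.
* The interface-area choice for underfilled wells is genuinely
  unconstrained by the available description; both options are exposed.
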