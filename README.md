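# gelwell

Kinetics and image quantification of DNA hydrogel particle formation in
microwell-confined dextran/PEG droplets.

## The problem

Branched DNA motifs (three-armed "Y-motifs" with sticky ends) gel into
hydrogel particles when annealed. Confining the gelation inside uniform
dextran-rich droplets — one per microwell, isolated by an immiscible
PEG-rich phase — produces a single, uniformly sized particle per droplet.
Two questions drive the analysis this package implements:

1. **How large should the particle be?** Unbound motifs either leak out of
   the droplet across the dextran/PEG interface or coalesce irreversibly
   into the growing aggregate. The competition fixes the final gelled
   fraction, hence the particle radius.
2. **How is the size distribution measured?** Two-channel confocal images
   of the well array (rhodamine-dextran marks droplets, Oligreen marks
   DNA) are thresholded, labelled, filtered and converted to equivalent
   radii — the classic ImageJ *Analyze Particles* workflow.

`gelwell` implements both, plus a seeded synthetic-scene generator with
machine-readable ground truth so the quantification pipeline is testable
without microscopy data, a wetting classifier for where the particle sits
(interface vs engulfed), and a CLI tying them together.

## The model

For a droplet of volume *V* with interface area *A* and interfacial
thickness *w*, holding *N<sub>u</sub>* unbound motifs of hydrodynamic
radius *r*:

```
dN_u/dt = -a N_u - b N_u²          dN_g/dt = +b N_u²
a = D·A/(V·w),  D = kT/(6πηr)      b = α/(2V),  α = 8kT/(3η)
```

*a* is the Fickian escape rate through the interface, *b* the Smoluchowski
Brownian-coagulation rate. The system has a closed-form (Riccati) solution,
used as the test oracle for the adaptive ODE integration; the steady-state
gelled count is `N_g(∞) = N0 − (a/b)·ln(1 + b·N0/a)`. The aggregate radius
follows from the motif concentration inside the gel, ρ_g, and a compaction
factor λ:

```
r_g = (1/λ) · (3 N_g / (4π ρ_g))^(1/3)
```

An annealing round fully re-dissociates the aggregate (N_u ← N_u + N_g)
while motifs already lost to the PEG phase stay lost, so extra rounds can
only shrink the particle. A particle sits at the dextran/PEG interface when
`|γ_p,PEG − γ_p,dex| < γ_dex,PEG`.

## Worked example

```python
from gelwell import (PhysicalParams, MotifSpec, GelParams, make_well_geometry,
                     rate_constants, solve_to_steady_state, gel_radius)
from gelwell.units import motif_count

geom = make_well_geometry(diameter=50e-6, depth=100e-6)   # 50-um well
rates = rate_constants(PhysicalParams(), MotifSpec(), geom)
n0 = motif_count(8e-6, geom.volume)                       # 8 uM of motifs
traj = solve_to_steady_state(rates, n0)
print(f"a = {rates.loss_rate_a:.4f} 1/s, b = {rates.coalescence_rate_b:.3e} 1/(s count)")
print(f"gelled fraction = {traj.final_gelled / n0:.4f}")
print(f"particle radius = {gel_radius(traj.final_gelled, GelParams()) * 1e6:.2f} um")
```

prints

```
a = 1.0914 1/s, b = 2.794e-06 1/(s count)
gelled fraction = 0.9968
particle radius = 5.98 um
```

At 8 µM in a 50-µm well the coalescence term dominates (b·N0 ≈ 2600 ≫ a ≈
1.1 s⁻¹), so 99.7 % of motifs gel and the predicted radius of 5.98 µm falls
inside the experimentally observed 4.8–6.0 µm band for that condition.

The same from the shell, plus a synthetic scene round trip:

```
gelwell simulate --out sweep.csv
gelwell generate --preset microwell_50 --seed 3 --out scene
gelwell analyze --dex scene_dex.tif --dna scene_dna.tif --threshold 115 --out scene
gelwell wetting --gpp 1.0 --gpd 1.0 --gdp 0.5     # -> interface
```

`scene_summary.json` then reports the detected droplet/particle counts,
their mean ± sd radii and the particles-per-well ratio, which on a
noiseless scene match the generated ground truth in `scene_truth.csv`
exactly.

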