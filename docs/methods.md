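# Methods

## Coarse-grained representation

Amphiphilic dendrimers are mapped at MARTINI resolution, roughly four
heavy atoms per bead, all beads 72 amu:

* **Alkyl tail** — one C1 bead per four methylenes: 3 beads for a 13C
  tail, 4 for 15C, 5 for 18C, bonded linearly (r₀ = 0.47 nm,
  k = 1250 kJ mol⁻¹ nm⁻²; 180° angles at 25 kJ mol⁻¹ rad⁻²).
* **Ring** — a single hydrophobic C1 bead joining tail and dendron.
* **Dendron head** — one neutral Nda node bead per branch point of the
  binary dendritic tree, plus one charged Qd bead (+1) per terminal
  amine.  A generation-g dendron carries 2^(g+1) terminals, so net
  charges are +2, +4, +8 for G0/G1/G2; all terminal amines are treated
  as protonated (physiological pH).  The exact head connectivity of the
  published PAMAM-dendron mapping is not reprinted anywhere usable, so
  the tree rule above (node per branch point, bonds along the tree) is
  adopted as this package's convention; bonded constants come from the
  standard MARTINI polymer values.

The siRNA duplex (20 bp, 3′ dTdT overhangs) maps each nucleotide to one
Qa phosphate (−1), one P1 ribose bead, and base beads A→(Na,Na,Nda),
G→(Nda,Nda,Na), C→(Na,Nd), U→(Na,Na).  dT overhangs use the uridine
complement (the extra methyl is below CG resolution) and their
phosphates are excluded from the N/P denominator, which counts the 40
core phosphates.  5′ termini carry a phosphate bead so the core holds
exactly 2 × 20 = 40.  Duplex shape is maintained by an elastic network:
every bead pair within 0.7 nm that is not covalently bonded receives a
harmonic restraint at the observed distance with
k = 1500 kJ mol⁻¹ nm⁻²; beyond the cutoff pairs interact only
non-bondedly.  When no structure is supplied, an idealized A-form
geometry is generated (rise 0.28 nm/bp, twist 32.7°/bp, backbone radius
0.9 nm at CG resolution, 165° inter-strand offset); any helically
plausible geometry satisfying the elastic-network cutoff statistics is
equivalent for this purpose.  Atomistic coordinates, when given, are
reduced by mass-weighted centre-of-mass mapping of fixed heavy-atom
groups per bead — standard MARTINI practice; the mapping figure being
reduced does not state the reduction operator, so COM is chosen.

## Synthetic configurations

The generators produce the end states the analysis assumes, not
dynamics: no forces, no thermostat, no kinetics.  What passing tests
show is therefore that the *estimators* are correct on configurations
with known ground truth — they say nothing about whether real AD systems
reach those states.

* **Spherical micelles.** Each AD is assigned a radial axis (Fibonacci
  sphere).  Hydrophobic beads sit on that axis at distances
  R·(j/n)^(1/3) from the centre — the cube-root law that reproduces a
  uniform solid sphere's density, so the √(5/3)·Rg estimator recovers
  the target core radius to within ~6% before noise.  The terminal tail
  bead's *signed* radius is R·(1 − I_d) for a tunable interdigitation
  target I_d (default 1.4, the long-tail regime): a terminal past the
  centre emulates interpenetrating tails, giving ring-to-terminal
  distances l₀ = I_d·R without disturbing the radial density profile.
  The construction preserves the Rg recovery for I_d ≈ 0.5–1.5.  Head
  beads stack outward in 0.25 nm shells with tangential fans, which
  reproduces overall micelle radii of ~2.1–2.2 nm for a 1.1 nm core —
  the magnitude the per-micelle tables report.
* **Rods.** Anchors form staggered rings of 8 ADs spaced 0.4 nm along
  the axis (tails converge on the axis, keeping successive rings
  single-linkage connected); hydrophobic magnitudes follow the
  square-root (uniform disc) law.  Long rods need many ADs: with ~2.9 nm
  of head extent, shape anisotropy κ² > 0.2 requires roughly ≥150
  small-head (G0) ADs.
* **Complexes.** The duplex sits at the box centre, axis along z;
  micelles are placed at the requested COM distances, spread in azimuth
  and modestly along the axis (beads-on-string), with the perpendicular
  offset kept large enough that dendron heads reach the backbone without
  bead overlap (< 0.3 nm ⇒ rejection).
* **Solvent and ions.** Water beads (4:1 mapping) occupy a jittered
  cubic lattice at 8.35 beads nm⁻³ outside a 0.45 nm solute exclusion;
  NaCl pairs are drawn at the requested molarity
  (0.150 M ⇒ 0.0903 pairs nm⁻³) plus counterions so total charge is
  exactly zero.  Ion/water counts, not molarities, are the generator
  inputs (the source text's own count-to-molarity conversion does not
  close).
* **Fusion trajectories.** Micelle B approaches micelle A along x
  following a scripted schedule — 9 nm start, plateau at 6 nm, approach,
  plateau at 2 nm, merge to 0.8 nm — with isotropic Gaussian noise
  (σ = 0.05 nm per bead per frame: small enough to preserve cluster
  identity, large enough to exercise estimators).  A handful of
  designated chloride beads track the inter-micelle midpoint so the
  shared-counterion signal precedes hydrophobic tail contacts
  deterministically, emulating the counterion-bridged fusion sequence.
  This is a scripted fixture for the fusion-profile estimators, not a
  simulation of fusion.

## Analysis conventions

* **Aggregates** are single-linkage connected components of AD
  molecules: two ADs link when any pair of their hydrophobic (tail +
  ring) beads is within the clustering cutoff under the minimum-image
  convention.  The underlying simulations never state their criterion;
  0.6 nm (first MARTINI neighbour shell) is the default and a config
  knob.  Unwrapping makes each molecule whole around its first bead,
  then places molecules breadth-first along the linkage graph at
  minimum-image offsets; aggregates spanning more than half the box in
  every dimension are flagged ambiguous.  Group COMs under periodic
  boundaries use the circular-mean construction, which is invariant to
  wrapping.
* **Geometry.** Micelle radius = √(5/3)·Rg over all aggregate beads
  (uniform-sphere convention; the factor is configurable), core radius
  likewise over hydrophobic beads — the primary estimator; R = 3v₀/a is
  kept as a consistency identity rather than an estimator.  l₀ is the
  mean ring-to-terminal-tail distance per molecule.  The ring bead
  counts as core in all hydrophobic metrics.  Shape: P ≤ 0.33 sphere
  (closed threshold: P = 0.33 is spherical, 0.34 cylindrical),
  ≤ 0.50 cylinder, else bilayer; aggregates with relative shape
  anisotropy κ² > 0.2 are additionally reported with min/max cylinder
  cross-section radii from thirds along the principal axis and are never
  classified spherical.  Trajectory reports average per lineage over the
  final quarter of frames.
* **Cutoffs** follow one convention package-wide: 0.65 nm for solvation
  shells (shared water/ions, shell composition), 0.75 nm for bead–bead
  contacts (amine–siRNA, tail–siRNA, micelle–micelle).
* **SASA** is Shrake–Rupley point sampling: per-bead spheres of radius
  (bead + probe) sampled at quasi-uniform points (default 960), points
  inside any other context bead's extended sphere discarded.  Bead radius
  0.26 nm (half the MARTINI Lennard-Jones σ of 0.47 nm, rounded up) and
  probe 0.26 nm (half a water-bead diameter); both configurable, since
  no radii are stated in the source.  Exactly coincident spheres resolve
  toward the lower bead index so a degenerate overlapping pair counts
  one sphere's area.
* **Contacts** are counted as cross-selection pairs by default; the
  amine-binding statistics instead count *distinct* amine beads in
  contact with siRNA (the per-micelle table semantics, bounded by the
  amine count).  Both semantics are exposed because the time-series
  figures' convention is not stated.
* **Bound micelles** are those whose window-mean COM distance to siRNA
  is ≤ 5 nm.  The N/P ratio of a complex divides the summed aggregation
  numbers of bound micelles by the 40 core phosphates — the printed
  convention (82/40 = 2:1 for bound sizes 13+19+24+26), even though an
  amine-based count (N = protonatable nitrogens) would be 8-fold larger
  for G2.  Standard errors of per-frame counts optionally sub-sample
  every k-th frame as a crude decorrelation control; the source's ±
  definition is not stated.
* **RDF maps** normalize per-base-pair shell counts by shell volume and
  the species' bulk density (N/V), averaged over the window; a uniform
  species converges to g(r) = 1 outside the excluded core.
* **Plateau detection** for COM series uses a sliding-window slope test
  (|slope| < 0.01 nm ns⁻¹ over ≥ 10 frames by default) — an operational
  definition chosen here, since plateaus are described only narratively.

## Problem sizes

The published simulation campaigns (175 ADs, 5 μs, ~450 k beads with
solvent) are emulated at reduced scale: micelles of 13–26 ADs
(~270–550 beads), fusion trajectories of ~40 frames and ~9 k beads with
solvent, analysis windows of a few frames.  These sizes were chosen so
the full property suite and the pipeline run in seconds while every
estimator still faces periodic boundaries, solvent occlusion and noise.

## Known limitations and published-number caveats

* Generated configurations have idealized radial architecture; estimator
  accuracy on them does not bound accuracy on thermally disordered
  micelles (e.g. the √(5/3) factor is exact only for uniform spheres).
* The published mean interdigitation for the longest-tail system (~1.5)
  is not reproducible from the printed per-micelle radii (l₀/R ≈
  1.3–1.4); the formula l₀/R is implemented as defined and the
  discrepancy left standing.
* The published surface-charge-density worked values (2.6, 2.1, 3.4,
  3.1 e nm⁻²) do not follow from σ_m = e·N_agg/S_m with the printed
  areas; the formula is implemented as printed and those numbers are not
  used as references.
* A few printed per-micelle rows are internally inconsistent (packing
  parameter vs R/(3 l₀) beyond rounding; one total-amine count that does
  not match N × e); the regression suite covers the self-consistent
  rows.
* No energetics: binding-enthalpy claims are represented only by contact
  proxies; no free energies, no critical micelle concentration, no
  force-field fitting from atomistic histograms, no MD engine input
  generation.
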