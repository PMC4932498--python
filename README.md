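# dendrimicelle

Coarse-grained modelling and self-assembly analysis of amphiphilic PAMAM
dendrimers (ADs) and their siRNA complexes.

Amphiphilic dendrimers are lipid/dendrimer hybrids — a low-generation
hydrophilic PAMAM dendron head (G0/G1/G2, with 2, 4 or 8 protonated
terminal amines) bonded to a hydrophobic alkyl tail (13, 15 or 18
carbons).  They self-assemble into micelles whose size and shape govern
how well they condense and protect siRNA, which in turn decides whether a
variant works as a gene-delivery vector.  This package provides, for
computational chemists and formulation scientists working on such
carriers:

* **Topology builders** — MARTINI-style coarse-grained topologies for all
  AD variants (one bead per four methylenes, one hydrophobic ring bead,
  one charged Qd bead per protonated terminal amine) and for a 20-bp
  siRNA duplex (Qa phosphate, P1 sugar, 2–3 small polar beads per base)
  held in shape by an elastic network (harmonic restraints of
  1500 kJ mol⁻¹ nm⁻² between all bead pairs within 0.7 nm).  Export/import
  as GRO/PDB coordinates and ITP-style topology text.
* **Synthetic configuration generators** — seeded, deterministic micelles
  (spherical or rod), siRNA–micelle complexes, 150 mM NaCl ion beads and
  4:1-mapped water, and scripted two-micelle fusion trajectories.  These
  stand in for molecular-dynamics output so every analysis stage is
  testable at desk scale.
* **Self-assembly analysis** — single-linkage aggregate detection under
  periodic boundaries, aggregate tracking and merge events, micelle
  geometry (radii from radii of gyration, core volume/area, packing
  parameter and shape class, interdigitation, surface charge density,
  area per amine), hydrophobic SASA fractions.
* **Interaction analysis** — Shrake–Rupley SASA, contact counts at
  0.75 nm, solvation-shell composition at 0.65 nm, per-base-pair radial
  distribution maps, COM-distance series with plateau detection, and
  per-micelle amine-binding statistics with the N/P ratio of a complex.

## The model

The shape of an aggregate of `N` amphiphiles is predicted by the
Israelachvili packing parameter

```
P = v0 / (a · l0)
```

where `v0` is the hydrophobic-chain volume per molecule, `a` the core
surface area per molecule and `l0` the critical tail length.  For a
spherical core of radius `R`,

```
V = (4/3) π R³ ,   A = 4 π R² ,   R = 3V/A = 3 v0 / a ,
```

so `P` reduces to `R / (3 l0)`.  `P ≤ 0.33` predicts a spherical micelle,
`0.33 < P ≤ 0.50` a cylinder ("rod"), and `P ≈ 0.50` a bilayer.  Radii
are estimated from radii of gyration with the uniform-sphere factor
`√(5/3)`; the core uses only hydrophobic (tail + ring) beads.  Derived
descriptors: interdigitation `I_d = l0 / R` (tails interpenetrate the
core when `I_d > 1`), surface charge density `σ_m = e·N_agg / S_m`, area
per amine `S_m / (N_agg · e)`, and the N/P ratio of a dendriplex, counted
as bound ADs over core phosphates.

## Worked example

```python
import dendrimicelle as dm

spec = dm.ADSpec(generation=2, tail_carbons=18)          # G2-18C
micelle = dm.generate_micelle(spec, n_ads=19, core_radius_target=1.1, seed=7)
aggregate = dm.detect_aggregates(micelle)[0]
geo = dm.micelle_geometry(micelle, aggregate, spec)
print(f"N_agg = {geo.n_agg}")
print(f"micelle radius R_m = {geo.micelle_radius:.2f} nm")
print(f"core radius R      = {geo.core_radius:.2f} nm")
print(f"tail length l0     = {geo.tail_length:.2f} nm")
print(f"packing parameter  = {geo.packing_parameter:.2f} ({geo.shape_class})")
print(f"interdigitation    = {geo.interdigitation:.2f}")
print(f"area per amine     = {geo.area_per_amine:.2f} nm^2")
```

prints

```
N_agg = 19
micelle radius R_m = 2.22 nm
core radius R      = 1.15 nm
tail length l0     = 1.54 nm
packing parameter  = 0.25 (sphere)
interdigitation    = 1.35
area per amine     = 0.41 nm^2
```

The generator was asked for a 19-AD sphere with a 1.1 nm core; the
analysis recovers the aggregation number exactly and the core radius
within a few percent, classifies the aggregate spherical (`P ≤ 0.33`),
and reports tails interdigitated (`I_d > 1`) — the packing regime of the
long-tail G2 systems.

A one-command pipeline (build → synthesize → analyze → report) is
available from the shell:

```bash
dendrimicelle all --seed 7 --outdir pipeline_out
dendrimicelle build ad --generation 2 --tail 18
dendrimicelle build sirna            # elastic-network duplex
dendrimicelle synth --n-ads 19 --out micelle.gro
dendrimicelle analyze --coordinates micelle.gro
```

The pipeline writes per-micelle geometry and amine-binding CSV reports,
interaction summaries (including the N/P ratio), topology/coordinate
files and a JSON manifest echoing every tunable and seed; reruns with
the same seed are byte-identical.

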