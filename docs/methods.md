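# Methods

This note records the models, conventions and numerical choices behind
cgnano, and what its synthetic test-bed does and does not establish.

## Units, boxes and periodic conventions

All lengths are nm, masses amu, times ns; thresholds quoted in Å in the
literature are stored as nm (15 Å → 1.5, 3 Å → 0.3, 10 Å → 1.0). Boxes
are orthorhombic only; triclinic input is rejected explicitly.
Coordinates are stored wrapped into [0, L) and every analysis applies the
minimum-image convention per operation — nothing is unwrapped globally,
which avoids trajectory-length-dependent drift. The minimum-image map
sends each displacement component to [−L/2, +L/2), with the tie at
exactly +L/2 folding to −L/2. Analysis radii (clustering cutoff, RDF
r_max, aggregate extents) must stay below half the shortest box edge;
violations raise rather than silently alias.

The periodic center of mass uses the circular (angle-mapping) estimate —
each axis is mapped to an angle θ = 2πx/L and the mass-weighted mean of
(cos θ, sin θ) is back-mapped — only to seed a second pass that averages
minimum-image displacements from that seed. The two-pass form is exact
(to floating point) for any subset of extent < L/2, which the test suite
checks against a brute-force unwrap oracle at 1e−9 nm. A breadth-first
`unwrap_cluster` alternative (adjacency-graph unwrap) is provided for
aggregates too elongated for the circular seed; the default is the
circular method because it is parameter-free.

Constants are pinned for bit-stable tables: 1 amu = 1.66053906660e−27 kg,
N_A = 6.02214076e23 /mol. Report values round half-to-even at two
decimals, applied to the shortest round-trip decimal representation of
the float so that printed midpoints like 9.575 round the way the decimal
string does (→ 9.58), not the way the binary approximation does.

## Aggregate detection and size observables

Chains are clustered by bead-level single linkage: molecules are adjacent
when *any* inter-molecule bead pair lies within r_C (default 1.5 nm),
and aggregates are connected components of that graph. Bead-level
contact (rather than COM–COM distance) is what makes 1.5 nm a *contact*
criterion for ~0.5 nm beads; both the contact graph and the O(N²)
union-find oracle used to verify it are exact, so the implementation
(periodic k-d tree pair query + sparse connected components) is an
engineering choice, not an approximation.

Two size estimators are reported because "particle size" is ambiguous
for a fuzzy polymer blob: the default sphere-equivalent diameter
D = 2√(5/3)·R_g (exact for a uniform ball, verified against Monte-Carlo
sampling), and a geometric extent (largest minimum-image bead-pair
distance plus two bead radii, computed on the convex hull of the
COM-unwrapped blob). The particle radius r_PEG used by the classifier is
the largest chain-COM distance from the aggregate COM (`max_com`), with a
percentile variant for outlier-robust work.

## Drug classification and encapsulation efficiency

Each drug is assigned to the aggregate with the nearest COM, then judged
against three radial bands derived from that aggregate's r_PEG with
margins inner = 0.3 nm and outer = 1.0 nm: inside below
r_PEG − inner, outside beyond r_PEG + outer, surface between. Two
further rules matter in edge cases:

* **Contact requirement.** "Belongs to the aggregate" requires an actual
  contact — some drug bead within the attach cutoff (default = r_C) of
  some aggregate bead. A drug radially close to the COM but physically
  detached (e.g. above a flat disc of chains) is outside, and inside
  status always implies contact.
* **Ties resolve to surface**, the catch-all band, so boundary
  equalities never flip between inside and outside.

EE(%) = N_inside / N_total × 100. Surface drugs never count toward EE.
With zero drugs EE is flagged undefined rather than reported as 0. A
degenerate single-chain aggregate has r_PEG = 0, so no drug can be
inside for any positive inner margin — asserted in tests.

## RDF, SASA, time series

The RDF histograms minimum-image pair distances (self-pairs excluded for
identical selections), normalises each bin by the 4πr²Δr shell and by the
local bulk density of B estimated within r_max-spheres around the A
particles (r_max ≤ L/2). That local normalisation makes g(r) → 1 for
homogeneous systems of any finite size, which the suite checks on a
5,000-bead ideal gas at per-bin counting-statistics tolerance.
Selections are bead-index arrays (bead–bead distances) or molecule-type
strings (COM–COM distances); both modes are exposed because typed
analyses of polymer–drug structure are usually COM-based while bead-typed
analyses are not.

SASA is Shrake–Rupley: each bead's sphere is expanded by the probe
radius (default 0.14 nm, water-sized), sampled with a deterministic
Fibonacci lattice (default 960 points — bit-reproducible, no seed), and a
test point is accessible when outside every other expanded occluder
sphere under minimum image. Occluders default to every bead in the
frame so a selection's area accounts for burial by the rest of the
system; pass an explicit occluder set to ignore explicit solvent. The
lone-sphere case is exact at any point count; overlapping geometries
converge to a 10⁶-point refinement within 0.5 % at the default 960. CG
bead radii are not defined by the bead chemistry here; when a molecule
map omits them the default is 0.264 nm, a configuration default
documented as arbitrary, not derived.

`metric_timeseries` evaluates SASA / R_g / density / EE per frame;
per-frame clustering is recomputed for EE so the series reflects the
instantaneous aggregate structure.

## Bonded-distribution validation

Bond lengths use minimum-image distances; bend angles are the included
angle at the middle bead in [0°, 180°]; torsions use the standard atan2
construction with the IUPAC sign convention (cis = 0°, right-handed
positive, range [−180°, 180°)) — stated because the sign is convention,
and cross-checked against both an independent projection-based oracle and
mdtraj. Colinear inner triples are skipped and counted. Histograms are
unit-area; default bin widths 0.005 nm (bonds) and 1° (angles/torsions)
resolve peak spacings of 0.01 nm / 1°, with a 5-bin moving-average
smoothing (edge-replicated, so flat densities stay peak-free) before
prominence-based peak detection. Deviation tables match each reference
peak to its *nearest* model peak, allowing many-to-one reuse: a coarse
model frequently merges two reference conformers into one peak, and both
deviations are meaningful.

## Synthetic test-bed

`generate_placement` is the module the recovery guarantees rest on. Each
aggregate is grown as confined random-walk chains (bond step 0.33 nm)
inside a core sphere, every chain seeded within the contact cutoff of an
earlier chain so the aggregate is one cluster *by construction*. The
geometry is then re-centred on its realized COM, and all drug bands are
measured against the realized r_PEG — not the nominal core radius —
using the same estimators the classifier applies, with a 0.05 nm guard
band at every boundary. Inside and surface drugs are anchored to an
actual chain bead within contact reach; outside drugs are placed beyond
both the outer margin and the contact reach of the outermost bead.
Aggregate centers are separated by the larger of the realized occupied
radii plus contact slack and the clustering floor 2·(max core) + 3 nm,
so multi-aggregate systems can neither merge under clustering nor
misassign drugs by nearest-COM. Infeasible prescriptions (e.g. inside
drugs around a single-chain aggregate) raise with the violated
constraint. Because every placement respects a guard band, the pipeline
recovers the intended labels with zero errors for any feasible spec —
verified over randomized prescriptions each run.

What this shows — and does not. Passing recovery proves the
clustering/classification logic implements its own definitions exactly.
It does not validate the definitions against real assemblies: generated
aggregates are isotropic blobs without entanglement, solvent, or drug
excluded volume, and drug counts per band are inputs, not emergent
thermodynamics. Equally, the fractions the acceptance script reports
are arithmetic consequences of the prescribed band counts.

`run_toy_aggregation` integrates overdamped Langevin dynamics
x ← x + (F/γ)dt + √(2kT dt/γ)·N(0,1) in reduced units (kT = γ = 1) with
harmonic bonds (k = 100 kT/nm², b₀ = 0.4 nm) and, between non-bonded
beads, a bounded DPD-style soft repulsion A(1 − r/σ)² (A = 50 kT,
σ = 0.6 nm) plus an attraction −ε(1 − (r/r_c)²)² of depth ε and range
r_c = 1.0 nm. Bounded forces keep the integrator stable from random
initial overlaps at dt = 0.001 without force capping; any single-step
displacement beyond r_c/2 aborts with a diagnostic instead of silently
corrupting the neighbour bookkeeping. It is explicitly not a chemical
force field: one bead type, implicit solvent, no electrostatics. Its
role is phenomenological, and the regimes the tests assert are
qualitative: ε = 0 leaves ≥ 80 % of 50 chains unclustered in a 16 nm
box; ε = 4 kT with 30 chains crowded into a 4.5 nm box coalesces to a
single cluster in ≥ 8/10 seeds within 8,000 steps; and at ε = 3 kT in an
8 nm box the mean final cluster count decreases from 25 to 400 chains at
a fixed 4,000-step budget (Spearman ρ < 0 over 10 seeds per count).
Those problem sizes keep each regime within the diffusive time the
budget affords while the contrast between regimes stays unambiguous.

## Pipeline determinism

`run_pipeline` validates its config up front (unknown keys rejected),
runs clustering/classification on the final frame of the requested range
(final-frame reporting is the default; per-frame series cover the
time-averaged view), and writes CSVs whose first line embeds the SHA-256
of the effective config. Identical config + inputs give byte-identical
CSVs; only the run log carries a timestamp. All stochastic generators
take a single seed and draw from one `default_rng` in documented order,
so fixtures are bit-reproducible.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Single-frame clustering: no merge/split genealogy across frames.
* The RDF local-density normalisation assumes selections sample the box
  reasonably; for a single small cluster it measures structure relative
  to the cluster's own mean density, not a bulk reservoir.
* SASA cost grows with point count × neighbours; the default 960 points
  targets ~0.5 % accuracy, not crystallographic-grade areas.
* The toy simulator's kinetics are overdamped and unentangled; it orders
  regimes correctly but its absolute rates mean nothing.
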