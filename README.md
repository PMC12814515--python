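# cgnano

Analysis toolkit for coarse-grained (CG) simulations of self-assembling
polymer nanocarriers that encapsulate a hydrophobic drug — the
PEG-in-water, bead-per-few-atoms setting where a polymer solution
aggregates into nanoparticles and drug molecules partition between the
particle core, its surface, and free solution.

It is written for people who have bead trajectories (their own MD, or the
built-in toy simulator) and want the standard quantitative readout of
such systems:

* **Aggregate detection** — single-linkage clustering of polymer chains:
  two chains belong to the same aggregate when any inter-chain bead pair
  is closer than the contact cutoff *r*<sub>C</sub> (default 15 Å), under
  the minimum-image convention. Reports per-particle chain counts,
  sphere-equivalent diameters *D* = 2√(5/3) *R*<sub>g</sub>, size medians
  and molar concentrations.
* **Encapsulation classification** — each drug molecule is assigned to
  the aggregate with the nearest center of mass; with
  *r*<sub>drug</sub> the drug-COM-to-aggregate-COM distance and
  *r*<sub>PEG</sub> the particle radius (largest chain-COM distance from
  the aggregate COM), the label is

      inside    if  r_drug < r_PEG − 3 Å   and the drug touches the cluster
      outside   if  r_drug > r_PEG + 10 Å  or it touches no cluster bead
      surface   otherwise

  and the encapsulation efficiency is
  EE(%) = *N*<sub>inside</sub>/*N*<sub>total</sub> × 100.
* **Structural observables** — system density ρ = *M*/*V*; pair
  correlation *g*<sub>AB</sub>(*r*) = ⟨ρ<sub>B</sub>(*r*)⟩/⟨ρ<sub>B</sub>⟩<sub>local</sub>
  with the local bulk density estimated inside half-box spheres so finite
  systems normalise to 1; Shrake–Rupley solvent-accessible surface area
  with a 1.4 Å probe and a deterministic Fibonacci point lattice; the
  mass-weighted radius of gyration, all periodic-boundary aware.
* **Model validation** — bond / angle / torsion distributions of two
  trajectories of the same molecule (e.g. all-atom reference vs CG
  model), peak detection, and nearest-peak absolute-deviation tables.
* **Synthetic data** — seeded generators for ideal-gas reference frames,
  aggregate/drug placements with exact ground-truth labels, and a toy
  overdamped-Langevin bead-spring simulator reproducing the qualitative
  nucleation–growth–coalescence phenomenology of concentrated polymer
  solutions.

File formats: GRO frames (nm, fixed width), multi-frame XYZ trajectories
(Å), and a molecule-map sidecar CSV
(`bead_index,molecule_id,molecule_type,mass_amu,radius_nm`) that carries
molecule identity, masses and radii. Internal units are nm / amu / ns.

## Worked example

```python
import cgnano as cg

spec = cg.PlacementSpec(
    box=cg.Box([30.0, 30.0, 30.0]),
    aggregates=(cg.AggregateSpec(n_chains=200, beads_per_chain=45,
                                 core_radius=3.0),),
    drugs=(cg.DrugCounts(n_inside=151, n_surface=45, n_outside=4),),
    seed=7,
)
frame, mmap, truth = cg.generate_placement(spec)
report = cg.cluster_molecules(frame, mmap, "PEG", r_c=1.5, box=spec.box)
result = cg.classify_drugs(frame, mmap, report, spec.margins, box=spec.box)
print(report.n_particles, result.counts, result.ee)
```

prints

```
1 (151, 45, 4) 75.5
```

one detected aggregate of 200 chains, the 151/45/4 inside/surface/outside
placements recovered exactly, and an encapsulation efficiency of 75.50 %
(the inside fraction — surface-adsorbed drugs are associated with the
carrier but not encapsulated). The scripts in `examples/` walk through
each capability the same way: aggregation reports, RDF + SASA, bonded
validation, and the toy aggregation simulator.

A thin CLI wraps the same functions
(`cgnano generate | simulate | cluster | classify | rdf | sasa |
validate-dist | report`); `cgnano report --config run.yaml` runs the
whole pipeline from a declarative config and writes a deterministic CSV
bundle (aggregation table, classification table, RDF, SASA and R_g time
series) whose files embed the config hash.

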