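"""Concentration-dependent aggregation report (particle counts and sizes).

Builds systems with three intended aggregates of different chain counts
and prints the report row the clustering module produces: particle
count, per-particle sphere-equivalent diameters, their median, and the
molar polymer concentration in the box.
"""

import cgnano as cg

spec = cg.PlacementSpec(
    box=cg.Box([30.0, 30.0, 30.0]),
    aggregates=(
        cg.AggregateSpec(n_chains=34, beads_per_chain=45, core_radius=2.6),
        cg.AggregateSpec(n_chains=10, beads_per_chain=45, core_radius=1.8),
        cg.AggregateSpec(n_chains=6, beads_per_chain=45, core_radius=1.5),
    ),
    drugs=(cg.DrugCounts(), cg.DrugCounts(), cg.DrugCounts()),
    seed=3,
)
frame, mmap, _ = cg.generate_placement(spec)
report = cg.cluster_molecules(frame, mmap, "PEG", r_c=1.5, box=spec.box)

from cgnano.clustering import cluster_report_row

row = cluster_report_row(report, spec.box)
for key, value in row.items():
    print(f"{key:>16}: {value}")
# particle_sizes are gyration-based sphere-equivalent diameters (nm),
# descending; chain_counts shows how the 50 chains split across particles;
# concentration_mM is n / (N_A * V) for the 30 nm box.
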