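"""Watch bead-spring polymers self-assemble in the toy Brownian simulator.

Runs the overdamped Langevin toy model at moderate attraction and prints
the cluster count and largest-aggregate size over time: the
nucleation -> growth -> coalescence sequence that concentrated polymer
solutions exhibit, in miniature.
"""

import cgnano as cg

sim = cg.ToySimSpec(
    box=cg.Box([8.0, 8.0, 8.0]),
    n_chains=60,
    beads_per_chain=4,
    attraction_eps=3.0,  # kT
    n_steps=4000,
    save_every=500,
    seed=5,
)
traj = cg.run_toy_aggregation(sim)

print(" time   clusters   largest   rg_largest")
for frame, box in zip(traj.frames, traj.boxes):
    report = cg.cluster_molecules(frame, traj.mmap, "PEG", sim.cutoff, box=box)
    largest = report.aggregates[0] if report.aggregates else None
    print(f"{frame.time:5.2f}   {report.n_particles:8d}   "
          f"{largest.n_chains if largest else 0:7d}   "
          f"{largest.rg if largest else 0.0:7.2f} nm")
# cluster count falls and the largest aggregate grows as chains nucleate,
# absorb monomers and finally coalesce; time is in reduced units
# (kT = friction = 1).
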