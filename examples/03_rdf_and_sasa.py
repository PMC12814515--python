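"""Structural observables: pair correlation and solvent-accessible area.

Computes the polymer-drug RDF (center-of-mass mode) on a drug-loaded
aggregate and the Shrake-Rupley SASA of the drug selection, the two
observables that track encapsulation: drugs bound to the carrier show a
strong short-range RDF peak and a reduced solvent exposure.
"""

import numpy as np

import cgnano as cg

spec = cg.PlacementSpec(
    box=cg.Box([20.0, 20.0, 20.0]),
    aggregates=(cg.AggregateSpec(n_chains=60, beads_per_chain=30,
                                 core_radius=2.5),),
    drugs=(cg.DrugCounts(n_inside=30, n_surface=10, n_outside=5),),
    seed=11,
)
frame, mmap, _ = cg.generate_placement(spec)

profile = cg.rdf(frame, "PEG", "HINA", bin_width=0.1, box=spec.box, mmap=mmap)
peak_bin = int(np.argmax(profile.g))
print(f"RDF bins:              {len(profile.bin_centers)}")
print(f"peak g(r):             {profile.g[peak_bin]:.1f} "
      f"at r = {profile.bin_centers[peak_bin]:.2f} nm")
print("the short-range enhancement (g >> 1) is the polymer-drug binding;")
print("g decays at large r because everything sits in one aggregate")

# For a homogeneous system the same estimator is flat at 1:
gas = cg.generate_ideal_gas(3000, spec.box, seed=0)
flat = cg.rdf(gas, np.arange(3000), np.arange(3000), bin_width=0.25,
              box=spec.box)
print(f"ideal-gas g(r) mean:   {flat.g[flat.bin_centers > 1].mean():.3f} "
      "(normalization check)")

drug_beads = mmap.beads_of_type("HINA")
exposed = cg.sasa(frame, drug_beads, probe_radius=0.14, n_points=960,
                  box=spec.box)
lone = 4 * np.pi * (frame.radii[drug_beads] + 0.14) ** 2
print(f"drug SASA:             {exposed.total:.1f} nm^2")
print(f"fully-exposed bound:   {lone.sum():.1f} nm^2")
print("the gap is the surface buried by encapsulation")
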