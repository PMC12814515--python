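"""Validate a coarse model against a reference by bonded distributions.

Emulates the model-validation workflow: two trajectories of the same
4-bead molecule — a 'reference' with two torsional conformers and a
'model' that merges them into one — are histogrammed, peaks detected,
and each reference peak matched to its nearest model peak to produce an
absolute-deviation table.
"""

import numpy as np

import cgnano as cg


def torsion_frames(phi_values_deg, n_frames, noise_deg, seed):
    """4-bead geometries with a prescribed noisy torsion angle."""
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        phi = np.radians(rng.choice(phi_values_deg) + rng.normal(0, noise_deg))
        p0 = np.array([1.0, 0.0, 0.0])  # torsion = phi by construction
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 1.0])  # central bond along z
        p3 = p2 + np.array([np.cos(phi), np.sin(phi), 0.0])
        coords = np.vstack([p0, p1, p2, p3]) + 5.0
        frames.append(cg.Frame(coords=coords, masses=np.ones(4),
                               radii=np.zeros(4), time=float(t)))
    return cg.Trajectory(frames=frames, boxes=[cg.Box([10] * 3)] * n_frames)


term = cg.BondedTermSpec("dihedral", ((0, 1, 2, 3),))
reference = cg.bonded_histogram(torsion_frames([-60, 60], 4000, 5, 1), term, 1.0)
model = cg.bonded_histogram(torsion_frames([10], 4000, 8, 2), term, 1.0)
cg.find_peaks(reference, smoothing_window=5)
cg.find_peaks(model, smoothing_window=5)

print("reference peaks (deg):", np.round(reference.peaks, 1))
print("model peaks (deg):    ", np.round(model.peaks, 1))
for row in cg.deviation_table(reference, model):
    print(f"  ref {row['ref_peak']:8.2f} -> model {row['model_peak']:8.2f}"
          f"   |deviation| {row['deviation']:.2f} deg")
# Both reference conformers map onto the single model peak: nearest-peak
# matching reuses model peaks, which is how a coarse model that merges
# conformational substates is scored.
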