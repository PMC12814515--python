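import numpy as np
import pytest

from cgnano import (
    AggregateSpec,
    Box,
    DrugCounts,
    Frame,
    Margins,
    MoleculeMap,
    PlacementSpec,
)


@pytest.fixture
def box10():
    return Box([10.0, 10.0, 10.0])


@pytest.fixture
def box30():
    return Box([30.0, 30.0, 30.0])


def make_chain_frame(chain_positions, box, beads_per_chain=None, masses=None):
    """Frame + map from explicit per-chain bead coordinate arrays."""
    coords = np.concatenate([np.atleast_2d(c) for c in chain_positions])
    n = len(coords)
    bead_mol = np.concatenate(
        [np.full(len(np.atleast_2d(c)), i) for i, c in enumerate(chain_positions)]
    )
    frame = Frame(
        coords=coords,
        masses=np.ones(n) if masses is None else masses,
        radii=np.full(n, 0.25),
    )
    mmap = MoleculeMap(
        bead_mol, np.array(["PEG"] * len(chain_positions), dtype=object)
    )
    return frame, mmap


def loading_spec(counts, n_aggregates=1, n_chains=200, seed=11, box_len=30.0):
    """Placement spec for one drug-loading composition (one or two aggregates)."""
    per = []
    n_in, n_surf, n_out = counts
    for a in range(n_aggregates):
        share = lambda total: total // n_aggregates + (
            1 if a < total % n_aggregates else 0
        )
        per.append(DrugCounts(share(n_in), share(n_surf), share(n_out)))
    chains_each = n_chains // n_aggregates
    return PlacementSpec(
        box=Box([box_len] * 3),
        aggregates=tuple(
            AggregateSpec(n_chains=chains_each, beads_per_chain=45, core_radius=3.0)
            for _ in range(n_aggregates)
        ),
        drugs=tuple(per),
        margins=Margins(),
        seed=seed,
    )
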