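"""Aggregate detection by single-linkage distance clustering.

Polymer chains are grouped into aggregates: two molecules are adjacent
when any inter-molecule bead pair lies within the contact cutoff r_C
(minimum image; default 1.5 nm), and aggregates are the connected
components of that contact graph.  Per-aggregate observables (center of
mass, radius of gyration, sphere-equivalent diameter, particle radius
from chain centers of mass) feed the concentration-dependent aggregation
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Box, Frame, MoleculeMap, PBCPolicy, POLYMER_TYPE
from .geometry import (
    center_of_mass,
    minimum_image,
    radius_of_gyration,
    round_half_even,
)

#: Contact cutoff r_C below which two molecules are linked (nm).
DEFAULT_RC = 1.5

_DEFAULT_POLICY = PBCPolicy()


@dataclass
class Aggregate:
    """One detected cluster of polymer chains and its size observables."""

    member_molecule_ids: np.ndarray  # sorted ascending
    bead_indices: np.ndarray
    com: np.ndarray  # nm
    rg: float  # nm
    diameter: float  # nm, default estimator
    diameter_extent: float  # nm, alternative estimator
    r_particle: float  # nm

    @property
    def n_chains(self) -> int:
        return len(self.member_molecule_ids)


@dataclass
class ClusterReport:
    """Aggregates of one frame, sorted by chain count descending."""

    aggregates: list[Aggregate]
    r_c: float
    molecule_type: str

    @property
    def n_particles(self) -> int:
        return len(self.aggregates)

    @property
    def sizes(self) -> list[float]:
        """Aggregate diameters, sorted descending (report order)."""
        return sorted((a.diameter for a in self.aggregates), reverse=True)

    @property
    def chain_counts(self) -> list[int]:
        return [a.n_chains for a in self.aggregates]

    @property
    def size_median(self) -> float:
        return median_particle_size(self.sizes)


def _molecule_adjacency(
    coords: np.ndarray,
    bead_mol: np.ndarray,
    n_mol: int,
    box: Box,
    r_c: float,
) -> np.ndarray:
    """Connected-component labels of the molecule contact graph."""
    tree = cKDTree(box.wrap(coords), boxsize=box.lengths)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    if len(pairs):
        mi, mj = bead_mol[pairs[:, 0]], bead_mol[pairs[:, 1]]
        keep = mi != mj
        mi, mj = mi[keep], mj[keep]
    else:
        mi = mj = np.empty(0, dtype=np.intp)
    graph = coo_matrix(
        (np.ones(len(mi)), (mi, mj)), shape=(n_mol, n_mol)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def cluster_molecules(
    frame: Frame,
    mmap: MoleculeMap,
    molecule_type: str = POLYMER_TYPE,
    r_c: float = DEFAULT_RC,
    box: Box | None = None,
    diameter_method: str = "gyration",
    radius_method: str = "max_com",
    radius_q: float = 95.0,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> ClusterReport:
    """Single-linkage clustering of all molecules of one type.

    Two molecules are merged when any inter-molecule bead pair is within
    ``r_c`` (minimum image).  Returns aggregates sorted by chain count
    descending, ties broken by lowest member molecule id, so labels are
    deterministic under permutation of the input.
    """
    if box is None:
        raise ValueError("cluster_molecules requires the periodic box")
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    box.check_radius(r_c, "clustering cutoff r_C")

    mol_ids = mmap.molecules_of_type(molecule_type)
    if mol_ids.size == 0:
        return ClusterReport(aggregates=[], r_c=r_c, molecule_type=molecule_type)

    bead_idx = mmap.beads_of_type(molecule_type)
    # Compact molecule numbering restricted to the selected type.
    compact = np.full(mmap.n_molecules, -1, dtype=np.intp)
    compact[mol_ids] = np.arange(mol_ids.size)
    labels = _molecule_adjacency(
        frame.coords[bead_idx],
        compact[mmap.bead_molecule[bead_idx]],
        mol_ids.size,
        box,
        r_c,
    )

    aggregates = []
    for lab in np.unique(labels):
        members = mol_ids[labels == lab]
        beads = np.concatenate([mmap.beads_of(m) for m in members])
        agg = _build_aggregate(
            members, beads, frame, mmap, box, diameter_method, radius_method,
            radius_q, policy,
        )
        aggregates.append(agg)
    aggregates.sort(key=lambda a: (-a.n_chains, int(a.member_molecule_ids[0])))
    return ClusterReport(aggregates=aggregates, r_c=r_c, molecule_type=molecule_type)


def _build_aggregate(
    members: np.ndarray,
    beads: np.ndarray,
    frame: Frame,
    mmap: MoleculeMap,
    box: Box,
    diameter_method: str,
    radius_method: str,
    radius_q: float,
    policy: PBCPolicy,
) -> Aggregate:
    com = center_of_mass(frame, beads, box, policy)
    rg = radius_of_gyration(frame, beads, box, policy)
    agg = Aggregate(
        member_molecule_ids=np.sort(members),
        bead_indices=beads,
        com=com,
        rg=rg,
        diameter=0.0,
        diameter_extent=0.0,
        r_particle=0.0,
    )
    agg.diameter_extent = aggregate_diameter(agg, frame, box, method="extent")
    gyration = aggregate_diameter(agg, frame, box, method="gyration")
    agg.diameter = gyration if diameter_method == "gyration" else agg.diameter_extent
    agg.r_particle = particle_radius(
        agg, frame, mmap, box, method=radius_method, q=radius_q, policy=policy
    )
    return agg


def aggregate_diameter(
    aggregate: Aggregate, frame: Frame, box: Box, method: str = "gyration"
) -> float:
    """Aggregate size estimate in nm.

    ``gyration``: sphere-equivalent diameter D = 2*sqrt(5/3)*R_g (exact for
    a uniform solid sphere).  ``extent``: largest minimum-image bead-pair
    distance plus twice the largest bead radius.
    """
    beads = aggregate.bead_indices
    if method == "gyration":
        return 2.0 * np.sqrt(5.0 / 3.0) * aggregate.rg
    if method == "extent":
        coords = frame.coords[beads]
        if len(coords) == 1:
            return 2.0 * float(frame.radii[beads[0]])
        # Unwrap about the aggregate COM (aggregates span < L/2), then the
        # largest pair distance is attained on the convex hull.
        pts = aggregate.com + minimum_image(coords - aggregate.com, box)
        if len(pts) > 8:
            try:
                from scipy.spatial import ConvexHull

                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # degenerate (coplanar/colinear) blobs
                pass
        delta = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        return float(dist.max()) + 2.0 * float(frame.radii[beads].max())
    raise ValueError(f"unknown diameter method {method!r}")


def particle_radius(
    aggregate: Aggregate,
    frame: Frame,
    mmap: MoleculeMap,
    box: Box,
    method: str = "max_com",
    q: float = 95.0,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> float:
    """Particle radius from member-chain center-of-mass positions.

    ``max_com`` (default): the largest minimum-image distance between a
    member chain's COM and the aggregate COM.  ``percentile_com``: the
    q-th percentile of those distances.
    """
    chain_coms = np.array(
        [center_of_mass(frame, mmap.beads_of(m), box, policy)
         for m in aggregate.member_molecule_ids]
    )
    delta = minimum_image(chain_coms - aggregate.com, box)
    dist = np.sqrt(np.einsum("ij,ij->i", delta, delta))
    if method == "max_com":
        return float(dist.max())
    if method == "percentile_com":
        return float(np.percentile(dist, q))
    raise ValueError(f"unknown radius method {method!r}")


def median_particle_size(sizes: list[float]) -> float:
    """Standard median of per-particle sizes; even counts average the middle two."""
    if len(sizes) == 0:
        raise ValueError("median of an empty size list")
    return float(np.median(np.asarray(sizes, dtype=float)))


def cluster_report_row(
    report: ClusterReport, box: Box, n_molecules: int | None = None
) -> dict:
    """One aggregation-report row: counts, concentration, sizes, median."""
    from .geometry import concentration_mM

    if n_molecules is None:
        n_molecules = int(sum(report.chain_counts))
    sizes = [round_half_even(s) for s in report.sizes]
    return {
        "n_molecules": n_molecules,
        "concentration_mM": round_half_even(concentration_mM(n_molecules, box)),
        "n_particles": report.n_particles,
        "particle_sizes": ";".join(f"{s:.2f}" for s in sizes),
        "size_median": round_half_even(median_particle_size(sizes))
        if sizes
        else float("nan"),
        "chain_counts": ";".join(
            str(c) for c in sorted(report.chain_counts, reverse=True)
        ),
    }
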