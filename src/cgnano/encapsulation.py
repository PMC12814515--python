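"""Inside / surface / outside drug classification and encapsulation efficiency.

Each drug molecule is assigned to the aggregate whose center of mass is
nearest (minimum image); with r_drug the distance between the drug COM and
that aggregate COM and r_particle the aggregate's particle radius, the label

    inside   if  r_drug < r_particle - inner  and the drug is in contact
                 with the aggregate (any drug bead within the contact
                 cutoff of any aggregate bead),
    outside  if  r_drug > r_particle + outer  or there is no contact,
    surface  otherwise,

with default margins inner = 0.3 nm and outer = 1.0 nm.  Encapsulation
efficiency is EE(%) = N_inside / N_total * 100: surface-adsorbed drugs do
not count as encapsulated.  Boundary ties resolve to surface, the
catch-all band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .clustering import ClusterReport, cluster_molecules
from .core import Box, Frame, MoleculeMap, PBCPolicy, DRUG_TYPE, POLYMER_TYPE
from .geometry import center_of_mass, minimum_image, round_half_even

_DEFAULT_POLICY = PBCPolicy()


@dataclass(frozen=True)
class Margins:
    """Classification bands in nm: inner and outer shell margins, and the
    contact cutoff used for the cluster-attachment condition (defaults to
    the clustering cutoff r_C)."""

    inner: float = 0.3
    outer: float = 1.0
    cluster_attach: float = 1.5

    def __post_init__(self) -> None:
        if self.inner < 0 or self.outer < 0 or self.cluster_attach <= 0:
            raise ValueError("margins must be non-negative, contact cutoff positive")


@dataclass
class DrugRecord:
    molecule_id: int
    aggregate_index: int | None  # index into ClusterReport.aggregates
    r_drug: float  # nm, COM-to-aggregate-COM distance
    linked: bool
    label: str  # inside | surface | outside


@dataclass
class ClassificationResult:
    records: list[DrugRecord]
    margins: Margins

    @property
    def n_total(self) -> int:
        return len(self.records)

    def _count(self, label: str) -> int:
        return sum(1 for r in self.records if r.label == label)

    @property
    def n_inside(self) -> int:
        return self._count("inside")

    @property
    def n_surface(self) -> int:
        return self._count("surface")

    @property
    def n_outside(self) -> int:
        return self._count("outside")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_inside, self.n_surface, self.n_outside)

    @property
    def ee_defined(self) -> bool:
        return self.n_total > 0

    def fraction(self, label: str) -> float:
        """Percentage of drugs with the given label (raw, unrounded)."""
        if self.n_total == 0:
            raise ValueError("fractions undefined: no drug molecules")
        return self._count(label) / self.n_total * 100.0

    @property
    def ee(self) -> float:
        """Encapsulation efficiency EE(%) = N_inside / N_total * 100."""
        return encapsulation_efficiency(self)


def encapsulation_efficiency(result: ClassificationResult) -> float:
    if result.n_total == 0:
        raise ValueError("encapsulation efficiency undefined for zero drugs")
    return result.n_inside / result.n_total * 100.0


def classify_drugs(
    frame: Frame,
    mmap: MoleculeMap,
    cluster_report: ClusterReport,
    margins: Margins = Margins(),
    box: Box | None = None,
    drug_type: str = DRUG_TYPE,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> ClassificationResult:
    """Label every drug molecule inside / surface / outside.

    Assignment is to the nearest aggregate COM; the contact condition is
    evaluated against that aggregate's beads only ("belonged to the same
    cluster" requires contact, not just proximity of centers).  With no
    aggregates every drug is outside.
    """
    if box is None:
        raise ValueError("classify_drugs requires the periodic box")
    drug_ids = mmap.molecules_of_type(drug_type)
    if drug_ids.size == 0:
        return ClassificationResult(records=[], margins=margins)

    aggregates = cluster_report.aggregates
    if aggregates:
        agg_coms = np.array([a.com for a in aggregates])
        agg_radii = np.array([a.r_particle for a in aggregates])
        # Bead -> aggregate lookup for the contact condition.
        all_agg_beads = np.concatenate([a.bead_indices for a in aggregates])
        bead_agg = np.concatenate(
            [np.full(len(a.bead_indices), k) for k, a in enumerate(aggregates)]
        )
        tree = cKDTree(box.wrap(frame.coords[all_agg_beads]), boxsize=box.lengths)

    records = []
    for mid in drug_ids:
        beads = mmap.beads_of(mid)
        com = center_of_mass(frame, beads, box, policy)
        if not aggregates:
            records.append(DrugRecord(int(mid), None, float("inf"), False, "outside"))
            continue
        delta = minimum_image(agg_coms - com, box)
        dist = np.sqrt(np.einsum("ij,ij->i", delta, delta))
        k = int(np.argmin(dist))
        r_drug = float(dist[k])
        neighbour_lists = tree.query_ball_point(
            box.wrap(frame.coords[beads]), margins.cluster_attach
        )
        linked = any(
            bead_agg[j] == k for hits in neighbour_lists for j in hits
        )
        r_particle = float(agg_radii[k])
        if linked and r_drug < r_particle - margins.inner:
            label = "inside"
        elif (not linked) or r_drug > r_particle + margins.outer:
            label = "outside"
        else:
            label = "surface"
        records.append(DrugRecord(int(mid), k, r_drug, linked, label))
    return ClassificationResult(records=records, margins=margins)


def classification_timeseries(
    trajectory,
    mmap: MoleculeMap | None = None,
    r_c: float = 1.5,
    margins: Margins = Margins(),
    molecule_type: str = POLYMER_TYPE,
    drug_type: str = DRUG_TYPE,
) -> tuple[np.ndarray, list[ClassificationResult]]:
    """Per-frame classification on freshly clustered aggregates.

    Returns the frame times (ns) and one ClassificationResult per frame.
    """
    mmap = mmap if mmap is not None else trajectory.mmap
    if mmap is None:
        raise ValueError("a molecule map is required")
    results = []
    for frame, fbox in zip(trajectory.frames, trajectory.boxes):
        report = cluster_molecules(frame, mmap, molecule_type, r_c, box=fbox)
        results.append(
            classify_drugs(frame, mmap, report, margins, box=fbox, drug_type=drug_type)
        )
    return trajectory.times, results


def classification_row(result: ClassificationResult, report: ClusterReport) -> dict:
    """One classification-report row: counts, fractions, particle sizes."""
    sizes = [round_half_even(s) for s in report.sizes]
    row = {
        "n_total": result.n_total,
        "n_inside": result.n_inside,
        "n_surface": result.n_surface,
        "n_outside": result.n_outside,
    }
    if result.n_total:
        row.update(
            frac_inside=round_half_even(result.fraction("inside")),
            frac_surface=round_half_even(result.fraction("surface")),
            frac_outside=round_half_even(result.fraction("outside")),
        )
    else:
        row.update(frac_inside=float("nan"), frac_surface=float("nan"),
                   frac_outside=float("nan"))
    from .clustering import median_particle_size

    row.update(
        particle_sizes=";".join(f"{s:.2f}" for s in sizes),
        size_median=round_half_even(median_particle_size(sizes)) if sizes else float("nan"),
        n_particles=report.n_particles,
    )
    return row
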