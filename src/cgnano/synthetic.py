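"""Synthetic configurations with known ground truth, and a toy aggregation
simulator.

Three generators drive the test-bed for the analysis pipeline:

* :func:`generate_placement` builds aggregates of confined random-walk
  polymer chains and places rigid drug molecules in prescribed radial
  bands (inside / surface / outside) around each aggregate, with guard
  margins chosen so the clustering + classification pipeline provably
  recovers the intended labels.
* :func:`generate_ideal_gas` samples homogeneous (Poisson) bead
  configurations, the null model for RDF normalization.
* :func:`run_toy_aggregation` integrates an overdamped Langevin
  bead-spring polymer fluid with a bounded short-range attraction,
  reproducing the qualitative nucleation-growth-coalescence phenomenology
  of self-assembling polymer solutions.  It is a test harness for
  time-resolved analyses, not a physical force field: one bead type,
  implicit solvent, reduced units with kT = 1.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call, so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Box,
    DRUG_TYPE,
    Frame,
    MoleculeMap,
    POLYMER_TYPE,
    Trajectory,
)
from .encapsulation import Margins

#: Guard band (nm) separating placements from classification boundaries.
GUARD_EPS = 0.05


class PlacementError(ValueError):
    """The placement spec is geometrically infeasible; message names the
    violated constraint."""


@dataclass(frozen=True)
class AggregateSpec:
    """One intended aggregate: chain count, chain length, confinement radius."""

    n_chains: int
    beads_per_chain: int = 45
    core_radius: float = 3.0  # nm

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.beads_per_chain < 1:
            raise ValueError("n_chains and beads_per_chain must be >= 1")
        if self.core_radius < 0.5:
            raise ValueError("core_radius must be >= 0.5 nm")


@dataclass(frozen=True)
class DrugCounts:
    n_inside: int = 0
    n_surface: int = 0
    n_outside: int = 0

    def __post_init__(self) -> None:
        if min(self.n_inside, self.n_surface, self.n_outside) < 0:
            raise ValueError("drug counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_inside + self.n_surface + self.n_outside


@dataclass(frozen=True)
class PlacementSpec:
    """Prescription for a synthetic aggregate/drug configuration."""

    box: Box
    aggregates: tuple[AggregateSpec, ...]
    drugs: tuple[DrugCounts, ...]  # one entry per aggregate
    margins: Margins = Margins()
    seed: int = 0
    chain_bond_length: float = 0.33  # nm
    chain_bead_mass: float = 45.0  # amu
    chain_bead_radius: float = 0.264  # nm
    drug_n_beads: int = 4
    drug_bead_offset: float = 0.12  # nm, rigid-body radius
    drug_bead_mass: float = 90.0  # amu
    drug_bead_radius: float = 0.23  # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "aggregates", tuple(self.aggregates))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        if len(self.aggregates) < 1:
            raise ValueError("at least one aggregate required")
        if len(self.drugs) != len(self.aggregates):
            raise ValueError("one DrugCounts entry per aggregate required")
        for agg in self.aggregates:
            if agg.core_radius >= self.box.min_length / 2:
                raise PlacementError(
                    "core radius must be below half the shortest box edge"
                )


@dataclass
class GroundTruth:
    """Intended labels: aggregate id per chain, band label per drug."""

    chain_aggregate: np.ndarray  # (n_chains,) intended aggregate index
    drug_label: np.ndarray  # (n_drugs,) inside | surface | outside
    drug_aggregate: np.ndarray  # (n_drugs,) intended aggregate index
    chain_molecule_ids: np.ndarray
    drug_molecule_ids: np.ndarray


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_centers(
    spec: PlacementSpec, rng: np.random.Generator, sep: float
) -> np.ndarray:
    """Aggregate centers with pairwise minimum-image separation >= `sep`."""
    lengths = spec.box.lengths
    if len(spec.aggregates) > 1 and sep >= lengths.min():
        raise PlacementError(
            f"required aggregate separation {sep:.2f} nm exceeds the box"
        )
    centers: list[np.ndarray] = []
    for _ in range(len(spec.aggregates)):
        for _attempt in range(2000):
            cand = rng.uniform(0, 1, 3) * lengths
            ok = True
            for c in centers:
                delta = cand - c
                delta -= lengths * np.floor(delta / lengths + 0.5)
                if np.linalg.norm(delta) < sep:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                break
        else:
            raise PlacementError("could not place aggregate centers at the "
                                 f"required separation {sep:.2f} nm")
    return np.array(centers)


def _grow_chains(
    agg: AggregateSpec, center: np.ndarray, spec: PlacementSpec,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Confined random-walk chains, each seeded within the contact cutoff of
    an earlier chain so the aggregate is one connected cluster by
    construction."""
    attach = spec.margins.cluster_attach
    step = spec.chain_bond_length
    chains: list[np.ndarray] = []
    all_beads: list[np.ndarray] = []

    def confined_step(prev: np.ndarray, length: float) -> np.ndarray:
        for _ in range(50):
            cand = prev + length * _random_unit(rng)[0]
            if np.linalg.norm(cand - center) <= agg.core_radius:
                return cand
        to_center = center - prev
        dist = np.linalg.norm(to_center)
        if dist < 1e-9:
            return prev
        return prev + min(length, dist) * to_center / dist

    for c in range(agg.n_chains):
        if c == 0:
            start = center.copy()
        else:
            anchor = all_beads[rng.integers(len(all_beads))]
            start = confined_step(anchor, rng.uniform(0.3, max(0.31, attach - 0.15)))
        chain = [start]
        for _ in range(agg.beads_per_chain - 1):
            chain.append(confined_step(chain[-1], step))
        chain_arr = np.array(chain)
        chains.append(chain_arr)
        all_beads.extend(chain_arr)
    return chains


_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def _drug_beads(com: np.ndarray, spec: PlacementSpec, rng: np.random.Generator) -> np.ndarray:
    """Rigid drug bead positions with centroid exactly at `com`."""
    n = spec.drug_n_beads
    if n == 1:
        return com[None, :]
    verts = _TETRAHEDRON[:n] if n <= 4 else _random_unit(rng, n)
    verts = verts - verts.mean(axis=0)
    scale = spec.drug_bead_offset / max(np.linalg.norm(verts, axis=1).max(), 1e-12)
    return com + verts * scale


def generate_placement(
    spec: PlacementSpec,
) -> tuple[Frame, MoleculeMap, GroundTruth]:
    """Build a frame whose clustering + classification recovers the spec.

    Chains are confined random walks inside each aggregate's core sphere;
    drug centers of mass are placed in the radial band corresponding to
    their intended label, with a guard band of ``GUARD_EPS`` on every
    classification boundary, an explicit contact anchor for inside/surface
    drugs, and a no-contact guarantee for outside drugs.
    """
    rng = np.random.default_rng(spec.seed)
    margins = spec.margins
    attach = margins.cluster_attach
    reach = attach - spec.drug_bead_offset - 2.0 * GUARD_EPS
    if reach <= 0:
        raise PlacementError("contact cutoff too small for the drug geometry")

    # Phase 1: build each aggregate in local coordinates centred on its own
    # realized center of mass, so all radial bands are exact by construction.
    local_chains: list[list[np.ndarray]] = []
    local_drugs: list[list[tuple[np.ndarray, str]]] = []
    occupied_radius: list[float] = []  # outermost material incl. drug beads

    for a, (agg, counts) in enumerate(zip(spec.aggregates, spec.drugs)):
        chains = _grow_chains(agg, np.zeros(3), spec, rng)
        beads = np.concatenate(chains)
        com = beads.mean(axis=0)
        chains = [c - com for c in chains]
        beads = beads - com
        chain_coms = np.array([c.mean(axis=0) for c in chains])
        r_part = float(np.linalg.norm(chain_coms, axis=1).max())
        r_b = np.linalg.norm(beads, axis=1)
        r_bead = float(r_b.max())
        drugs: list[tuple[np.ndarray, str]] = []

        # --- inside band: r < r_part - inner, anchored to a deep bead ---
        hi_in = r_part - margins.inner - GUARD_EPS
        if counts.n_inside:
            candidates = np.flatnonzero(r_b <= hi_in)
            if hi_in <= 0 or candidates.size == 0:
                raise PlacementError(
                    f"aggregate {a}: inside band empty (r_particle "
                    f"{r_part:.2f} nm <= inner margin); more/longer chains "
                    "or a larger core radius needed"
                )
            for _ in range(counts.n_inside):
                anchor = beads[candidates[rng.integers(candidates.size)]]
                pos = anchor
                for _try in range(200):
                    cand = anchor + rng.uniform(0, min(reach, 0.8)) * _random_unit(rng)[0]
                    if np.linalg.norm(cand) <= hi_in:
                        pos = cand
                        break
                drugs.append((pos, "inside"))

        # --- surface band: r_part - inner < r < r_part + outer, anchored ---
        lo_s = r_part - margins.inner + GUARD_EPS
        hi_s = r_part + margins.outer - GUARD_EPS
        if counts.n_surface:
            if hi_s <= max(lo_s, 0):
                raise PlacementError(f"aggregate {a}: surface band empty")
            reach_r = 0.8 * reach
            cand_idx = np.flatnonzero(
                (r_b >= lo_s - reach_r) & (r_b <= hi_s + reach_r)
            )
            if cand_idx.size == 0:
                raise PlacementError(
                    f"aggregate {a}: no chain bead within contact reach of "
                    "the surface band"
                )
            for _ in range(counts.n_surface):
                b = cand_idx[rng.integers(cand_idx.size)]
                rb = r_b[b]
                u = beads[b] / rb if rb > 1e-9 else _random_unit(rng)[0]
                t_lo = max(lo_s, rb - reach_r, 0.0)
                t_hi = min(hi_s, rb + reach_r)
                t = rng.uniform(t_lo, t_hi) if t_hi > t_lo else t_lo
                axial = abs(t - rb)
                w_max = min(
                    np.sqrt(max(reach**2 - axial**2, 0.0)),
                    np.sqrt(max(hi_s**2 - t**2, 0.0)),
                )
                w = rng.uniform(0, 0.9 * w_max) if w_max > 0 else 0.0
                v = _random_unit(rng)[0]
                v -= (v @ u) * u
                norm_v = np.linalg.norm(v)
                v = v / norm_v if norm_v > 1e-9 else np.zeros(3)
                drugs.append((t * u + w * v, "surface"))

        # --- outside: beyond the outer margin and out of contact reach ---
        if counts.n_outside:
            t_min = (
                max(r_part + margins.outer,
                    r_bead + attach + spec.drug_bead_offset)
                + GUARD_EPS
            )
            t_hi = t_min + 0.5
            if t_hi >= 0.45 * spec.box.min_length:
                raise PlacementError(
                    f"aggregate {a}: no room for outside drugs (need radius "
                    f"{t_hi:.2f} nm inside half the box)"
                )
            for _ in range(counts.n_outside):
                t = rng.uniform(t_min, t_hi)
                drugs.append((t * _random_unit(rng)[0], "outside"))

        local_chains.append(chains)
        local_drugs.append(drugs)
        extent = r_bead
        if drugs:
            extent = max(extent, max(np.linalg.norm(p) for p, _ in drugs))
        occupied_radius.append(extent + spec.drug_bead_offset)

    # Phase 2: place realized centers of mass far enough apart that every
    # drug is nearest to (and only in contact with) its own aggregate, with
    # the clustering-separation floor of 2*max(core) + 3 nm.
    if len(spec.aggregates) > 1:
        r_sorted = sorted(occupied_radius, reverse=True)
        sep = max(
            r_sorted[0] + r_sorted[1] + attach + 0.5,
            2.0 * r_sorted[0] + 0.6,
            2.0 * max(a.core_radius for a in spec.aggregates) + 3.0,
        )
    else:
        sep = 0.0
    for a, r_occ in enumerate(occupied_radius):
        if 2.0 * r_occ + attach + 0.5 >= spec.box.min_length:
            raise PlacementError(
                f"aggregate {a}: occupied radius {r_occ:.2f} nm does not fit "
                "the periodic box"
            )
    centers = _place_centers(spec, rng, sep)

    chain_coords: list[np.ndarray] = []
    chain_agg: list[int] = []
    drug_coms: list[np.ndarray] = []
    drug_label: list[str] = []
    drug_agg: list[int] = []
    for a in range(len(spec.aggregates)):
        for c in local_chains[a]:
            chain_coords.append(c + centers[a])
            chain_agg.append(a)
        for pos, label in local_drugs[a]:
            drug_coms.append(pos + centers[a])
            drug_label.append(label)
            drug_agg.append(a)

    # --- assemble the frame ---
    n_chains = len(chain_coords)
    n_drugs = len(drug_coms)
    coords = [np.concatenate(chain_coords)] if n_chains else []
    bead_mol: list[np.ndarray] = [
        np.repeat(np.arange(n_chains),
                  [len(c) for c in chain_coords])
    ]
    for d, com in enumerate(drug_coms):
        beads = _drug_beads(com, spec, rng)
        coords.append(beads)
        bead_mol.append(np.full(len(beads), n_chains + d))
    all_coords = np.concatenate(coords)
    bead_mol_arr = np.concatenate(bead_mol)
    n_chain_beads = sum(len(c) for c in chain_coords)
    masses = np.concatenate(
        [np.full(n_chain_beads, spec.chain_bead_mass),
         np.full(len(all_coords) - n_chain_beads, spec.drug_bead_mass)]
    )
    radii = np.concatenate(
        [np.full(n_chain_beads, spec.chain_bead_radius),
         np.full(len(all_coords) - n_chain_beads, spec.drug_bead_radius)]
    )
    mol_types = np.array(
        [POLYMER_TYPE] * n_chains + [DRUG_TYPE] * n_drugs, dtype=object
    )
    frame = Frame(coords=spec.box.wrap(all_coords), masses=masses, radii=radii)
    mmap = MoleculeMap(bead_mol_arr, mol_types)
    truth = GroundTruth(
        chain_aggregate=np.array(chain_agg, dtype=np.intp),
        drug_label=np.array(drug_label, dtype=object),
        drug_aggregate=np.array(drug_agg, dtype=np.intp),
        chain_molecule_ids=np.arange(n_chains),
        drug_molecule_ids=n_chains + np.arange(n_drugs),
    )
    return frame, mmap, truth


def generate_ideal_gas(
    n: int, box: Box, seed: int = 0, mass: float = 72.0, radius: float = 0.264
) -> Frame:
    """Uniform i.i.d. bead positions: the homogeneous (Poisson) null model."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1, size=(n, 3)) * box.lengths
    return Frame(
        coords=coords, masses=np.full(n, mass), radii=np.full(n, radius)
    )


@dataclass(frozen=True)
class ToySimSpec:
    """Parameters of the overdamped bead-spring aggregation simulator.

    Reduced units: kT = 1, friction gamma = 1, so the free-bead diffusion
    constant is D = temperature.  ``attraction_eps`` (in kT) scales a
    bounded polynomial well between beads of different chains; at 0 the
    fluid is purely repulsive and stays dispersed.
    """

    box: Box
    n_chains: int = 50
    beads_per_chain: int = 4
    bond_length: float = 0.4  # nm
    bond_k: float = 100.0  # kT / nm^2
    attraction_eps: float = 0.0  # kT
    cutoff: float = 1.0  # nm, attraction range
    repulsion_a: float = 50.0  # kT, soft-core amplitude
    repulsion_sigma: float = 0.6  # nm, soft-core range
    friction: float = 1.0
    temperature: float = 1.0  # kT
    dt: float = 0.001  # reduced time
    n_steps: int = 4000
    save_every: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.attraction_eps < 0:
            raise ValueError("attraction_eps must be >= 0")
        if self.cutoff >= self.box.min_length / 2:
            raise ValueError("cutoff must be below half the shortest box edge")
        if self.n_steps < 1 or self.save_every < 1:
            raise ValueError("n_steps and save_every must be >= 1")


def _toy_forces(coords: np.ndarray, sim: ToySimSpec, bead_chain: np.ndarray) -> np.ndarray:
    box = sim.box
    n = len(coords)
    forces = np.zeros((n, 3))

    # Non-bonded: soft repulsion + eps-scaled attraction, bounded everywhere.
    tree = cKDTree(coords, boxsize=box.lengths)
    rmax = max(sim.cutoff, sim.repulsion_sigma)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        bonded = (bead_chain[i] == bead_chain[j]) & (np.abs(i - j) == 1)
        i, j = i[~bonded], j[~bonded]
        delta = coords[i] - coords[j]
        delta -= box.lengths * np.floor(delta / box.lengths + 0.5)
        r = np.linalg.norm(delta, axis=1)
        r_safe = np.where(r > 1e-9, r, 1e-9)
        mag = np.zeros_like(r)
        in_rep = r < sim.repulsion_sigma
        mag[in_rep] += (2.0 * sim.repulsion_a / sim.repulsion_sigma) * (
            1.0 - r[in_rep] / sim.repulsion_sigma
        )
        if sim.attraction_eps > 0:
            in_att = r < sim.cutoff
            x = r[in_att] / sim.cutoff
            mag[in_att] -= 4.0 * sim.attraction_eps * x * (1.0 - x * x) / sim.cutoff
        fvec = (mag / r_safe)[:, None] * delta
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)

    # Harmonic bonds along each chain.
    heads = np.flatnonzero(np.diff(bead_chain) == 0)  # bond i -- i+1
    bi, bj = heads, heads + 1
    delta = coords[bi] - coords[bj]
    delta -= box.lengths * np.floor(delta / box.lengths + 0.5)
    r = np.linalg.norm(delta, axis=1)
    r_safe = np.where(r > 1e-9, r, 1e-9)
    fvec = (-sim.bond_k * (r - sim.bond_length) / r_safe)[:, None] * delta
    np.add.at(forces, bi, fvec)
    np.add.at(forces, bj, -fvec)
    return forces


def run_toy_aggregation(sim: ToySimSpec) -> Trajectory:
    """Integrate the toy polymer fluid and return the saved trajectory.

    Overdamped Langevin update
        x <- x + (F / gamma) dt + sqrt(2 kT dt / gamma) * N(0, 1),
    minimum-image forces, coordinates wrapped each step.  Aborts with a
    diagnostic if any single-step displacement exceeds half the attraction
    cutoff (the neighbour bookkeeping would no longer be trustworthy).
    """
    rng = np.random.default_rng(sim.seed)
    box = sim.box
    n_beads = sim.n_chains * sim.beads_per_chain
    bead_chain = np.repeat(np.arange(sim.n_chains), sim.beads_per_chain)

    # Initial condition: random-walk chains at random positions.
    coords = np.empty((n_beads, 3))
    k = 0
    for _c in range(sim.n_chains):
        pos = rng.uniform(0, 1, 3) * box.lengths
        for b in range(sim.beads_per_chain):
            if b:
                pos = pos + sim.bond_length * _random_unit(rng)[0]
            coords[k] = pos
            k += 1
    coords = box.wrap(coords)

    masses = np.full(n_beads, 72.0)
    radii = np.full(n_beads, 0.264)
    noise_amp = np.sqrt(2.0 * sim.temperature * sim.dt / sim.friction)
    max_step = 0.5 * sim.cutoff

    frames = [Frame(coords=coords.copy(), masses=masses, radii=radii, time=0.0)]
    for step in range(1, sim.n_steps + 1):
        forces = _toy_forces(coords, sim, bead_chain)
        disp = forces * (sim.dt / sim.friction) + noise_amp * rng.normal(
            size=(n_beads, 3)
        )
        worst = float(np.abs(disp).max())
        if not np.isfinite(worst) or worst > max_step:
            raise RuntimeError(
                f"step {step}: displacement {worst:.3f} nm exceeds half the "
                f"cutoff ({max_step:.3f} nm); reduce dt or the interaction "
                "strength"
            )
        coords = box.wrap(coords + disp)
        if step % sim.save_every == 0 or step == sim.n_steps:
            frames.append(
                Frame(coords=coords.copy(), masses=masses, radii=radii,
                      time=step * sim.dt)
            )
    mmap = MoleculeMap(
        bead_chain, np.array([POLYMER_TYPE] * sim.n_chains, dtype=object)
    )
    return Trajectory(frames=frames, boxes=[box] * len(frames), mmap=mmap)
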