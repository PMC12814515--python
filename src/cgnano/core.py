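"""Domain containers for coarse-grained bead configurations.

All quantities use internal units of nm (length), amu (mass) and ns (time).
Coordinates are stored wrapped into the primary cell [0, L); analyses apply
the minimum-image convention per operation rather than unwrapping globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Molecule types with special meaning in the pipeline.
POLYMER_TYPE = "PEG"
DRUG_TYPE = "HINA"
WATER_TYPE = "W"

#: Default CG bead radius (nm) when a molecule map omits radii.  Arbitrary
#: but fixed: half a typical regular CG bead contact distance.
DEFAULT_BEAD_RADIUS = 0.264

#: Default CG bead mass (amu) when a molecule map omits masses.
DEFAULT_BEAD_MASS = 72.0


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValueError(f"box lengths must be positive and finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def min_length(self) -> float:
        return float(self.lengths.min())

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into the primary cell [0, L) per axis."""
        wrapped = np.mod(np.asarray(coords, dtype=float), self.lengths)
        # mod can return L itself for tiny negative inputs; fold it back.
        return np.where(wrapped >= self.lengths, wrapped - self.lengths, wrapped)

    def check_radius(self, r: float, what: str = "radius") -> None:
        """Reject analysis radii for which the minimum image is ambiguous."""
        if r >= self.min_length / 2:
            raise ValueError(
                f"{what} {r} nm must be < half the shortest box edge "
                f"({self.min_length / 2} nm)"
            )


@dataclass
class Frame:
    """A single configuration: N beads with coordinates, masses and radii."""

    coords: np.ndarray  # (N, 3) nm
    masses: np.ndarray  # (N,) amu
    radii: np.ndarray  # (N,) nm
    bead_types: np.ndarray | None = None  # (N,) labels
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        self.masses = np.asarray(self.masses, dtype=float).reshape(n)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if n and (np.any(self.masses <= 0) or not np.all(np.isfinite(self.masses))):
            raise ValueError("masses must be positive and finite")
        if n and (np.any(self.radii < 0) or not np.all(np.isfinite(self.radii))):
            raise ValueError("radii must be non-negative and finite")
        if self.bead_types is not None:
            self.bead_types = np.asarray(self.bead_types).reshape(n)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class MoleculeMap:
    """Bead-to-molecule assignment plus a per-molecule type label.

    Molecule ids form a contiguous 0-based range; every bead belongs to
    exactly one molecule.  Types are free-form labels, with ``PEG``,
    ``HINA`` and ``W`` recognised by the pipeline.
    """

    bead_molecule: np.ndarray  # (N,) int molecule id per bead
    molecule_types: np.ndarray  # (M,) str type label per molecule
    _beads_by_molecule: list[np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.bead_molecule = np.asarray(self.bead_molecule, dtype=np.intp).ravel()
        self.molecule_types = np.asarray(self.molecule_types, dtype=object).ravel()
        m = len(self.molecule_types)
        if self.bead_molecule.size:
            lo, hi = self.bead_molecule.min(), self.bead_molecule.max()
            if lo < 0 or hi >= m:
                raise ValueError(
                    f"bead molecule ids must lie in [0, {m}), got [{lo}, {hi}]"
                )
            present = np.unique(self.bead_molecule)
            if present.size != m:
                raise ValueError("molecule ids must form a contiguous 0-based range")
        elif m:
            raise ValueError("molecule types given but no beads are mapped")

    @property
    def n_beads(self) -> int:
        return self.bead_molecule.size

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_types)

    def beads_of(self, molecule_id: int) -> np.ndarray:
        """Bead indices of one molecule (cached, sorted ascending)."""
        if self._beads_by_molecule is None:
            order = np.argsort(self.bead_molecule, kind="stable")
            bounds = np.searchsorted(
                self.bead_molecule[order], np.arange(self.n_molecules + 1)
            )
            self._beads_by_molecule = [
                order[bounds[i] : bounds[i + 1]] for i in range(self.n_molecules)
            ]
        return self._beads_by_molecule[molecule_id]

    def molecules_of_type(self, molecule_type: str) -> np.ndarray:
        return np.flatnonzero(self.molecule_types == molecule_type)

    def beads_of_type(self, molecule_type: str) -> np.ndarray:
        """All bead indices whose molecule has the given type."""
        wanted = self.molecule_types == molecule_type
        return np.flatnonzero(wanted[self.bead_molecule])


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing times and a shared map.

    The box may vary frame to frame (constant-pressure runs); the bead
    count may not.
    """

    frames: list[Frame]
    boxes: list[Box]
    mmap: MoleculeMap | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        if len(self.boxes) == 1 and len(self.frames) > 1:
            self.boxes = list(self.boxes) * len(self.frames)
        if len(self.boxes) != len(self.frames):
            raise ValueError("one box per frame required")
        n = self.frames[0].n_beads
        if any(f.n_beads != n for f in self.frames):
            raise ValueError("bead count must be constant across frames")
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.mmap is not None and self.mmap.n_beads != n:
            raise ValueError("molecule map bead count does not match frames")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box(self) -> Box:
        """The shared box, if it is constant across frames."""
        first = self.boxes[0]
        if any(not np.allclose(b.lengths, first.lengths) for b in self.boxes[1:]):
            raise ValueError("box varies across frames; use per-frame boxes")
        return first


@dataclass(frozen=True)
class PBCPolicy:
    """How periodic boundaries are handled by geometric reductions.

    ``mode='minimum_image'`` applies the nearest-copy convention;
    ``mode='none'`` treats coordinates as already whole (valid only when
    no pair in the subset spans more than half a box edge).  ``com_method``
    selects how the periodic center of mass is seeded: the parameter-free
    circular (angle-mapping) estimate, or a breadth-first unwrap along a
    bead adjacency graph for elongated aggregates.
    """

    mode: str = "minimum_image"
    com_method: str = "circular"
    unwrap_cutoff: float = 0.6  # nm adjacency cutoff for unwrap_cluster

    def __post_init__(self) -> None:
        if self.mode not in ("minimum_image", "none"):
            raise ValueError(f"unknown PBC mode {self.mode!r}")
        if self.com_method not in ("circular", "unwrap_cluster"):
            raise ValueError(f"unknown COM method {self.com_method!r}")
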