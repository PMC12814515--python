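"""Structural observables: radial distribution function, SASA, time series.

The RDF follows the pair-correlation definition

    g_AB(r) = <rho_B(r)> / <rho_B>_local ,

where the local bulk density of B is estimated within spheres of radius
r_max (at most half the box edge) centred on the A particles, so profiles
tend to unity at large r even in finite systems.  SASA uses the
Shrake-Rupley construction with a deterministic Fibonacci lattice of test
points on each probe-expanded sphere; a point is accessible when it lies
outside every other expanded sphere (minimum-image distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Box, Frame, MoleculeMap, PBCPolicy, Trajectory
from .geometry import center_of_mass, radius_of_gyration, system_density

#: Water-sized probe radius, nm.
DEFAULT_PROBE_RADIUS = 0.14
#: Default number of Shrake-Rupley test points per sphere.
DEFAULT_N_POINTS = 960

_DEFAULT_POLICY = PBCPolicy()


@dataclass
class RDFProfile:
    bin_centers: np.ndarray  # nm
    g: np.ndarray  # unitless
    n_a: int
    n_b: int
    bin_width: float  # nm

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


@dataclass
class SASAResult:
    per_bead_area: np.ndarray  # nm^2, aligned with the bead subset
    bead_subset: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_bead_area.sum())


@dataclass
class TimeSeries:
    times: np.ndarray  # ns
    values: np.ndarray
    unit: str
    label: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _selection_points(
    frame: Frame,
    selection,
    box: Box,
    mmap: MoleculeMap | None,
    policy: PBCPolicy,
) -> np.ndarray:
    """Coordinates for an RDF selection.

    A string selects all molecules of that type and uses their centers of
    mass; an index array selects beads directly.
    """
    if isinstance(selection, str):
        if mmap is None:
            raise ValueError("molecule-typed selections need a molecule map")
        mol_ids = mmap.molecules_of_type(selection)
        if mol_ids.size == 0:
            raise ValueError(f"no molecules of type {selection!r}")
        return np.array(
            [center_of_mass(frame, mmap.beads_of(m), box, policy) for m in mol_ids]
        )
    idx = np.asarray(selection, dtype=np.intp).ravel()
    if idx.size == 0:
        raise ValueError("empty bead selection")
    return frame.coords[idx]


def rdf(
    frames: Trajectory | Frame | list[Frame],
    selection_a,
    selection_b,
    bin_width: float = 0.02,
    r_max: float | None = None,
    box: Box | None = None,
    mmap: MoleculeMap | None = None,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> RDFProfile:
    """Radial distribution function g_AB(r), averaged over frames.

    Selections may be bead-index arrays (bead-to-bead distances) or
    molecule-type strings (COM-to-COM distances).  Self-pairs are excluded
    when the selections coincide.  ``r_max`` defaults to half the shortest
    box edge.
    """
    if isinstance(frames, Trajectory):
        mmap = mmap if mmap is not None else frames.mmap
        frame_list = frames.frames
        boxes = frames.boxes
    else:
        frame_list = [frames] if isinstance(frames, Frame) else list(frames)
        if box is None:
            raise ValueError("rdf requires the periodic box")
        boxes = [box] * len(frame_list)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max is None:
        r_max = min(b.min_length for b in boxes) / 2.0 * (1 - 1e-9)
    for b in boxes:
        b.check_radius(r_max * (1 - 1e-12), "RDF r_max")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    rho_local_sum = 0.0
    n_a = n_b = 0

    for frame, fbox in zip(frame_list, boxes):
        pts_a = fbox.wrap(_selection_points(frame, selection_a, fbox, mmap, policy))
        pts_b = fbox.wrap(_selection_points(frame, selection_b, fbox, mmap, policy))
        n_a, n_b = len(pts_a), len(pts_b)
        same = n_a == n_b and np.array_equal(pts_a, pts_b)
        tree_a = cKDTree(pts_a, boxsize=fbox.lengths)
        tree_b = cKDTree(pts_b, boxsize=fbox.lengths)
        cum = tree_a.count_neighbors(tree_b, edges).astype(float)
        if same:
            cum -= n_a  # remove zero-distance self pairs
        frame_counts = np.diff(cum)
        counts += frame_counts
        n_within = cum[-1]
        rho_local_sum += n_within / (n_a * 4.0 / 3.0 * np.pi * r_max**3)

    n_frames = len(frame_list)
    rho_local = rho_local_sum / n_frames
    shell = 4.0 * np.pi * centers**2 * np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (n_frames * n_a * shell * rho_local)
    g = np.nan_to_num(g, nan=0.0, posinf=0.0)
    return RDFProfile(
        bin_centers=centers, g=g, n_a=n_a, n_b=n_b, bin_width=bin_width
    )


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere points (Fibonacci lattice)."""
    if n_points < 1:
        raise ValueError("need at least one point")
    k = np.arange(n_points)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    frame: Frame,
    bead_subset: np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    box: Box | None = None,
    occluders: np.ndarray | None = None,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area of a bead subset (nm^2).

    Each subset bead's van der Waals sphere is expanded by the probe radius
    and sampled with a Fibonacci lattice; the accessible fraction of its
    test points, times 4*pi*(r_i + probe)^2, is the bead's contribution.
    ``occluders`` (default: every bead of the frame) is the set whose
    expanded spheres block test points — pass e.g. the non-solvent beads to
    ignore explicit solvent.
    """
    if box is None:
        raise ValueError("sasa requires the periodic box")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if bead_subset is None:
        bead_subset = np.arange(frame.n_beads)
    bead_subset = np.asarray(bead_subset, dtype=np.intp).ravel()
    if bead_subset.size == 0:
        raise ValueError("sasa: empty bead subset")
    if occluders is None:
        occluders = np.arange(frame.n_beads)
    occluders = np.asarray(occluders, dtype=np.intp).ravel()
    radii = frame.radii[bead_subset] + probe_radius
    if np.any(radii <= 0):
        raise ValueError("zero bead radius with zero probe: degenerate surface")
    coords = box.wrap(frame.coords[bead_subset])
    occ_coords = box.wrap(frame.coords[occluders])
    occ_radii = frame.radii[occluders] + probe_radius
    unit = fibonacci_sphere(n_points)

    tree = cKDTree(occ_coords, boxsize=box.lengths)
    max_r = float(occ_radii.max())
    areas = np.empty(len(bead_subset))
    for i in range(len(bead_subset)):
        neighbours = [
            j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
            if occluders[j] != bead_subset[i]
        ]
        pts = box.wrap(coords[i] + radii[i] * unit)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            delta = pts - occ_coords[j]
            delta -= box.lengths * np.floor(delta / box.lengths + 0.5)
            accessible &= np.einsum("ij,ij->i", delta, delta) >= occ_radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return SASAResult(
        per_bead_area=areas,
        bead_subset=bead_subset,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


def metric_timeseries(
    trajectory: Trajectory,
    metric: str,
    selection: np.ndarray | str | None = None,
    mmap: MoleculeMap | None = None,
    r_c: float = 1.5,
    margins=None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> TimeSeries:
    """Per-frame evaluation of a scalar observable along a trajectory.

    ``metric`` is one of ``sasa`` (nm^2), ``rg`` (nm), ``density``
    (kg/m^3) or ``ee`` (%).  ``selection`` is a bead-index array or a
    molecule-type string (resolved through the molecule map).
    """
    mmap = mmap if mmap is not None else trajectory.mmap

    def resolve(frame: Frame) -> np.ndarray:
        if selection is None:
            return np.arange(frame.n_beads)
        if isinstance(selection, str):
            if mmap is None:
                raise ValueError("type selections need a molecule map")
            return mmap.beads_of_type(selection)
        return np.asarray(selection, dtype=np.intp)

    values = []
    if metric == "ee":
        from .encapsulation import Margins, classification_timeseries

        _, results = classification_timeseries(
            trajectory, mmap, r_c, margins or Margins()
        )
        values = [r.ee for r in results]
        unit = "%"
    elif metric in ("sasa", "rg", "density"):
        for frame, fbox in zip(trajectory.frames, trajectory.boxes):
            if metric == "sasa":
                values.append(
                    sasa(frame, resolve(frame), probe_radius, n_points, box=fbox).total
                )
            elif metric == "rg":
                values.append(radius_of_gyration(frame, resolve(frame), fbox, policy))
            else:
                values.append(system_density(frame, fbox))
        unit = {"sasa": "nm^2", "rg": "nm", "density": "kg/m^3"}[metric]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return TimeSeries(
        times=trajectory.times, values=np.array(values), unit=unit, label=metric
    )
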