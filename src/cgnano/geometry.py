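"""Periodic-boundary primitives and scalar structural observables.

Implements the minimum-image convention, the periodic center of mass,
the mass-weighted radius of gyration

    R_g = sqrt( sum_i m_i |r_i - r_cm|^2 / sum_i m_i ),

the instantaneous system density rho = M / V, and the molar concentration
of a molecular species in the box.  Internal units: nm, amu, ns.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy.spatial import cKDTree

from .core import Box, Frame, PBCPolicy

#: Unified atomic mass unit in kg (CODATA 2018).
AMU_KG = 1.66053906660e-27
#: Avogadro constant, 1/mol (exact, SI 2019).
N_AVOGADRO = 6.02214076e23

_DEFAULT_POLICY = PBCPolicy()


def round_half_even(x: float, decimals: int = 2) -> float:
    """Round to `decimals` places, ties to even, on the printed decimal value.

    Uses the shortest round-trip decimal representation of the float so that
    e.g. the midpoint 9.575 (stored as 9.5749999...) rounds to 9.58 the way
    its printed form does.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def minimum_image(delta: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement(s) to the nearest periodic image, per component.

    Each component of the result lies in [-L/2, +L/2); the convention at
    exactly +L/2 folds to -L/2.  Idempotent.
    """
    delta = np.asarray(delta, dtype=float)
    lengths = box.lengths
    return delta - lengths * np.floor(delta / lengths + 0.5)


def _unwrap_cluster(coords: np.ndarray, box: Box, cutoff: float) -> np.ndarray:
    """Unwrap a connected blob by breadth-first traversal of its contact graph.

    Beads within `cutoff` (minimum image) are adjacent; each bead's position
    is re-expressed as its parent's position plus the minimum-image step.
    Disconnected components are unwrapped independently (their first bead is
    the anchor), which still yields a usable seed for the COM.
    """
    n = len(coords)
    wrapped = box.wrap(coords)
    tree = cKDTree(wrapped, boxsize=box.lengths)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    out = wrapped.copy()
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start]:
            continue
        seen[start] = True
        queue = [start]
        while queue:
            i = queue.pop()
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    out[j] = out[i] + minimum_image(wrapped[j] - out[i], box)
                    queue.append(j)
    return out


def center_of_mass(
    frame: Frame,
    bead_subset: np.ndarray,
    box: Box,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> np.ndarray:
    """Mass-weighted center of a bead subset under periodic boundaries.

    The circular method maps each axis onto an angle theta = 2*pi*x/L, takes
    the mass-weighted mean of (cos theta, sin theta) and back-maps it; that
    provisional center then anchors a minimum-image refinement, so any subset
    of extent < L/2 recovers the naive mass-weighted mean exactly (up to
    floating point).  The result is wrapped into [0, L).
    """
    bead_subset = np.asarray(bead_subset, dtype=np.intp).ravel()
    if bead_subset.size == 0:
        raise ValueError("center_of_mass: empty bead subset")
    coords = frame.coords[bead_subset]
    masses = frame.masses[bead_subset]
    total = masses.sum()

    if policy.mode == "none":
        return masses @ coords / total

    if policy.com_method == "unwrap_cluster":
        unwrapped = _unwrap_cluster(coords, box, policy.unwrap_cutoff)
        return box.wrap(masses @ unwrapped / total)

    theta = 2.0 * np.pi * box.wrap(coords) / box.lengths
    mean_cos = masses @ np.cos(theta) / total
    mean_sin = masses @ np.sin(theta) / total
    seed = box.wrap(np.arctan2(mean_sin, mean_cos) / (2.0 * np.pi) * box.lengths)
    # Refine: arithmetic mean of minimum-image displacements from the seed.
    delta = minimum_image(coords - seed, box)
    return box.wrap(seed + masses @ delta / total)


def radius_of_gyration(
    frame: Frame,
    bead_subset: np.ndarray,
    box: Box,
    policy: PBCPolicy = _DEFAULT_POLICY,
) -> float:
    """Mass-weighted RMS distance of the subset's beads from their COM (nm)."""
    bead_subset = np.asarray(bead_subset, dtype=np.intp).ravel()
    if bead_subset.size == 0:
        raise ValueError("radius_of_gyration: empty bead subset")
    com = center_of_mass(frame, bead_subset, box, policy)
    delta = frame.coords[bead_subset] - com
    if policy.mode == "minimum_image":
        delta = minimum_image(delta, box)
    masses = frame.masses[bead_subset]
    return float(np.sqrt(masses @ np.einsum("ij,ij->i", delta, delta) / masses.sum()))


def system_density(frame: Frame, box: Box) -> float:
    """Instantaneous mass density rho = M / V in kg/m^3."""
    if frame.n_beads == 0:
        raise ValueError("system_density: empty frame")
    mass_kg = frame.masses.sum() * AMU_KG
    volume_m3 = box.volume_nm3 * 1e-27
    return mass_kg / volume_m3


def mean_and_se(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error over an explicit window of per-frame values.

    The averaging window is the caller's choice (e.g. an equilibrated tail
    of the trajectory); a single value has undefined SE, reported as 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("mean_and_se: no values")
    mean = float(values.mean())
    if values.size == 1:
        return mean, 0.0
    return mean, float(values.std(ddof=1) / np.sqrt(values.size))


def concentration_mM(n_molecules: int, box: Box) -> float:
    """Molar concentration of n molecules in the box, in mmol/L."""
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    volume_litres = box.volume_nm3 * 1e-24
    return n_molecules / (N_AVOGADRO * volume_litres) * 1e3
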