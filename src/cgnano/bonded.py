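"""Bonded-term distributions and reference-vs-model peak deviation tables.

Validates a coarse-grained model against an all-atom reference of the same
molecule: per-frame bond lengths, bend angles and torsions are pooled into
normalized histograms, peaks are detected on a smoothed density, and each
reference peak is matched to its nearest model peak to form an
absolute-deviation table.  Nearest-peak matching allows many-to-one reuse:
a coarse model often merges two reference conformers into one peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks as _scipy_find_peaks

from .core import Box, Trajectory
from .geometry import minimum_image

#: Default histogram bin widths: nm for bonds, degrees for angles/torsions.
DEFAULT_BIN_WIDTHS = {"bond": 0.005, "angle": 1.0, "dihedral": 1.0}


@dataclass(frozen=True)
class BondedTermSpec:
    """A family of like terms: 2 (bond), 3 (angle) or 4 (dihedral) indices each."""

    kind: str
    terms: tuple[tuple[int, ...], ...]
    label: str = ""

    def __post_init__(self) -> None:
        arity = {"bond": 2, "angle": 3, "dihedral": 4}
        if self.kind not in arity:
            raise ValueError(f"unknown bonded term kind {self.kind!r}")
        terms = tuple(tuple(int(i) for i in t) for t in self.terms)
        if not terms:
            raise ValueError("at least one term required")
        if any(len(t) != arity[self.kind] for t in terms):
            raise ValueError(f"{self.kind} terms need {arity[self.kind]} indices")
        object.__setattr__(self, "terms", terms)


@dataclass
class DistributionSummary:
    bin_centers: np.ndarray
    density: np.ndarray  # normalized to unit area
    bin_width: float
    kind: str
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_skipped: int = 0  # degenerate (colinear) terms dropped


def _bond_values(coords: np.ndarray, terms: np.ndarray, box: Box) -> np.ndarray:
    delta = minimum_image(coords[terms[:, 1]] - coords[terms[:, 0]], box)
    return np.sqrt(np.einsum("ij,ij->i", delta, delta))


def _angle_values(coords: np.ndarray, terms: np.ndarray, box: Box) -> np.ndarray:
    """Included angle at the middle bead, degrees in [0, 180]."""
    u = minimum_image(coords[terms[:, 0]] - coords[terms[:, 1]], box)
    v = minimum_image(coords[terms[:, 2]] - coords[terms[:, 1]], box)
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_values(
    coords: np.ndarray, terms: np.ndarray, box: Box
) -> tuple[np.ndarray, int]:
    """Signed torsions by the atan2 construction, degrees in [-180, 180).

    Convention: cis (eclipsed) = 0 degrees, right-handed rotation positive.
    Terms with a colinear inner triple are skipped; their count is returned.
    """
    b1 = minimum_image(coords[terms[:, 1]] - coords[terms[:, 0]], box)
    b2 = minimum_image(coords[terms[:, 2]] - coords[terms[:, 1]], box)
    b3 = minimum_image(coords[terms[:, 3]] - coords[terms[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2, axis=1)
    ok = (np.linalg.norm(n1, axis=1) > 1e-12) & (np.linalg.norm(n2, axis=1) > 1e-12)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(norm_b2 > 0, norm_b2, 1)
    phi = np.degrees(np.arctan2(y, x))
    phi = np.where(phi >= 180.0, phi - 360.0, phi)
    return phi[ok], int((~ok).sum())


def bonded_histogram(
    trajectory: Trajectory,
    spec: BondedTermSpec,
    bin_width: float | None = None,
) -> DistributionSummary:
    """Pooled, unit-area histogram of one bonded term family over all frames."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS[spec.kind]
    terms = np.asarray(spec.terms, dtype=np.intp)
    n = trajectory.frames[0].n_beads
    if terms.min() < 0 or terms.max() >= n:
        raise ValueError(f"term indices must lie in [0, {n})")
    values = []
    n_skipped = 0
    for frame, box in zip(trajectory.frames, trajectory.boxes):
        if spec.kind == "bond":
            values.append(_bond_values(frame.coords, terms, box))
        elif spec.kind == "angle":
            values.append(_angle_values(frame.coords, terms, box))
        else:
            phi, skipped = dihedral_values(frame.coords, terms, box)
            values.append(phi)
            n_skipped += skipped
    pooled = np.concatenate(values)
    if pooled.size == 0:
        raise ValueError("no valid term values (all terms degenerate)")
    if spec.kind == "bond":
        lo = np.floor(pooled.min() / bin_width) * bin_width
        hi = np.ceil(pooled.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
    elif spec.kind == "angle":
        edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    else:
        edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    density, edges = np.histogram(pooled, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DistributionSummary(
        bin_centers=centers,
        density=density,
        bin_width=bin_width,
        kind=spec.kind,
        n_skipped=n_skipped,
    )


def find_peaks(
    summary: DistributionSummary,
    smoothing_window: int = 5,
    min_prominence: float | None = None,
) -> np.ndarray:
    """Peak positions (bin centers) of the smoothed density, ascending.

    The density is smoothed with a centred moving average before local
    maxima with at least ``min_prominence`` (default: 5% of the smoothed
    maximum) are taken.  The result is also stored on the summary.
    """
    if summary.density.size == 0:
        raise ValueError("empty distribution")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    smooth = uniform_filter1d(
        summary.density, size=smoothing_window, mode="nearest"
    )
    if min_prominence is None:
        min_prominence = 0.05 * smooth.max() if smooth.max() > 0 else np.inf
    idx, _ = _scipy_find_peaks(smooth, prominence=min_prominence)
    peaks = np.sort(summary.bin_centers[idx])
    summary.peaks = peaks
    return peaks


def deviation_table(
    summary_ref: DistributionSummary | np.ndarray,
    summary_model: DistributionSummary | np.ndarray,
) -> list[dict]:
    """Match each reference peak to its nearest model peak.

    Inputs are summaries (with peaks already detected) or raw peak-position
    arrays.  Model peaks may be reused by several reference peaks.  Rows:
    ``{'ref_peak', 'model_peak', 'deviation'}`` with deviation =
    |ref - model|, in the peaks' own units.
    """

    def peaks_of(obj, side: str) -> np.ndarray:
        arr = obj.peaks if isinstance(obj, DistributionSummary) else np.asarray(obj, float)
        arr = np.sort(np.asarray(arr, dtype=float).ravel())
        if arr.size == 0:
            raise ValueError(f"no peaks on the {side} side")
        return arr

    ref = peaks_of(summary_ref, "reference")
    model = peaks_of(summary_model, "model")
    rows = []
    for p in ref:
        nearest = model[np.argmin(np.abs(model - p))]
        rows.append(
            {"ref_peak": float(p), "model_peak": float(nearest),
             "deviation": float(abs(p - nearest))}
        )
    return rows
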