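"""Readers and writers: GRO frames, multi-frame XYZ trajectories, molecule maps.

GRO files are fixed-width with coordinates in nm and the box on the last
line; residue numbers seed molecule ids and residue names seed molecule
types.  XYZ trajectories carry coordinates in Angstrom (converted to nm on
read) and the frame time on the comment line.  Molecule identity, masses
and radii authoritative for analysis live in a sidecar CSV with header
``bead_index,molecule_id,molecule_type,mass_amu,radius_nm`` (0-based
indices), because CG bead naming is force-field specific.
"""

from __future__ import annotations

import csv
import re
import warnings
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_BEAD_MASS,
    DEFAULT_BEAD_RADIUS,
    Box,
    Frame,
    MoleculeMap,
    ParseError,
    Trajectory,
)

_TIME_RE = re.compile(r"t\s*=\s*([0-9eE+.\-]+)")


def _contiguous_molecule_ids(raw_ids: np.ndarray) -> np.ndarray:
    """Renumber arbitrary molecule ids to 0..M-1 in order of first appearance."""
    _, first_pos, inverse = np.unique(raw_ids, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    return order[inverse]


def read_gro(path: str | Path) -> tuple[Frame, Box, MoleculeMap]:
    """Read a GRO coordinate file (nm, fixed width).

    Residue numbers become molecule ids (renumbered to a contiguous 0-based
    range, order of first appearance) and residue names become molecule
    types.  Masses and radii are not stored in GRO and default to
    ``DEFAULT_BEAD_MASS`` / ``DEFAULT_BEAD_RADIUS``; load a molecule-map
    sidecar to override them.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: need title, count and box lines, got {len(lines)}")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}:2: malformed atom count {lines[1]!r}") from exc
    if len(lines) < 2 + n_atoms + 1:
        raise ParseError(
            f"{path}: expected {n_atoms} atom lines plus a box line, "
            f"file has only {len(lines)} lines"
        )

    coords = np.empty((n_atoms, 3))
    resids = np.empty(n_atoms, dtype=np.intp)
    resnames: list[str] = []
    for k in range(n_atoms):
        lineno = 3 + k
        line = lines[2 + k]
        if len(line) < 44:
            raise ParseError(f"{path}:{lineno}: atom line too short ({len(line)} chars)")
        try:
            resids[k] = int(line[0:5])
            resnames.append(line[5:10].strip())
            coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed fixed-width fields") from exc

    box_lineno = 2 + n_atoms + 1
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ParseError(f"{path}:{box_lineno}: truncated box line {lines[2 + n_atoms]!r}")
    if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
        raise ParseError(f"{path}:{box_lineno}: triclinic boxes are not supported")
    try:
        box = Box(np.array([float(v) for v in box_fields[:3]]))
    except ValueError as exc:
        raise ParseError(f"{path}:{box_lineno}: bad box line") from exc

    mol_ids = _contiguous_molecule_ids(resids)
    n_mol = mol_ids.max() + 1 if n_atoms else 0
    mol_types = np.empty(n_mol, dtype=object)
    for bead, mid in enumerate(mol_ids):
        mol_types[mid] = resnames[bead]
    frame = Frame(
        coords=box.wrap(coords),
        masses=np.full(n_atoms, DEFAULT_BEAD_MASS),
        radii=np.full(n_atoms, DEFAULT_BEAD_RADIUS),
    )
    return frame, box, MoleculeMap(mol_ids, mol_types)


def write_gro(
    frame: Frame,
    box: Box,
    mmap: MoleculeMap,
    path: str | Path,
    title: str = "cgnano frame",
) -> None:
    """Write a GRO file; coordinates wrapped into the box at 3 decimals.

    Raises on coordinates that overflow the fixed 8.3f field rather than
    silently truncating them.
    """
    path = Path(path)
    coords = box.wrap(frame.coords)
    if coords.size and (coords.max() >= 9999.9995 or coords.min() <= -999.9995):
        raise ValueError("coordinate overflows the fixed-width GRO field")
    with path.open("w") as fh:
        fh.write(f"{title}\n{frame.n_beads}\n")
        for i in range(frame.n_beads):
            mid = int(mmap.bead_molecule[i])
            resname = str(mmap.molecule_types[mid])[:5]
            x, y, z = coords[i]
            fh.write(
                f"{(mid + 1) % 100000:5d}{resname:<5s}{'BB':>5s}"
                f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{box.lengths[0]:10.5f}{box.lengths[1]:10.5f}{box.lengths[2]:10.5f}\n")


def read_molecule_map(
    path: str | Path,
) -> tuple[MoleculeMap, np.ndarray, np.ndarray]:
    """Read the sidecar CSV; returns (map, masses, radii) in bead order."""
    path = Path(path)
    expected = ["bead_index", "molecule_id", "molecule_type", "mass_amu", "radius_nm"]
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise ParseError(f"{path}:1: empty molecule map") from exc
        if [h.strip() for h in header] != expected:
            raise ParseError(f"{path}:1: header must be {','.join(expected)}")
        rows = [row for row in reader if row]
    n = len(rows)
    bead_idx = np.empty(n, dtype=np.intp)
    mol_ids = np.empty(n, dtype=np.intp)
    types: list[str] = []
    masses = np.empty(n)
    radii = np.empty(n)
    for k, row in enumerate(rows):
        try:
            bead_idx[k] = int(row[0])
            mol_ids[k] = int(row[1])
            types.append(row[2].strip())
            masses[k] = float(row[3])
            radii[k] = float(row[4])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{k + 2}: malformed row {row!r}") from exc
    order = np.argsort(bead_idx)
    if not np.array_equal(bead_idx[order], np.arange(n)):
        raise ParseError(f"{path}: bead_index must cover 0..{n - 1} exactly once")
    mol_ids = mol_ids[order]
    masses, radii = masses[order], radii[order]
    types = [types[i] for i in order]
    n_mol = mol_ids.max() + 1 if n else 0
    mol_types = np.empty(n_mol, dtype=object)
    for bead in range(n):
        mol_types[mol_ids[bead]] = types[bead]
    return MoleculeMap(mol_ids, mol_types), masses, radii


def write_molecule_map(
    mmap: MoleculeMap, masses: np.ndarray, radii: np.ndarray, path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["bead_index", "molecule_id", "molecule_type", "mass_amu", "radius_nm"]
        )
        for i in range(mmap.n_beads):
            mid = int(mmap.bead_molecule[i])
            writer.writerow(
                [i, mid, mmap.molecule_types[mid], repr(float(masses[i])), repr(float(radii[i]))]
            )


def apply_molecule_map(frame: Frame, masses: np.ndarray, radii: np.ndarray) -> Frame:
    """Return a copy of the frame with sidecar masses and radii applied."""
    return Frame(
        coords=frame.coords.copy(),
        masses=np.asarray(masses, dtype=float),
        radii=np.asarray(radii, dtype=float),
        bead_types=None if frame.bead_types is None else frame.bead_types.copy(),
        time=frame.time,
    )


def read_xyz_trajectory(
    path: str | Path, mmap: MoleculeMap | None, box: Box
) -> Trajectory:
    """Read a multi-frame XYZ trajectory (Angstrom; converted to nm).

    The comment line of each frame is scanned for ``t = <value>`` (ns);
    frames without a parseable time get sequential indices 0, 1, ... with
    a warning.  The bead count must be constant across frames.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    n_atoms = None
    missing_time = False
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{pos + 1}: expected atom count") from exc
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise ParseError(
                f"{path}:{pos + 1}: atom count changed from {n_atoms} to {count}"
            )
        if pos + 1 + count >= len(lines) + (0 if count else 1):
            raise ParseError(f"{path}:{pos + 1}: truncated frame")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        match = _TIME_RE.search(comment)
        if match:
            time = float(match.group(1))
        else:
            missing_time = True
            time = float(frame_no)
        coords = np.empty((count, 3))
        for k in range(count):
            fields = lines[pos + 2 + k].split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{pos + 3 + k}: malformed atom line")
            coords[k] = [float(fields[1]), float(fields[2]), float(fields[3])]
        coords /= 10.0  # Angstrom -> nm
        masses = np.full(count, DEFAULT_BEAD_MASS)
        radii = np.full(count, DEFAULT_BEAD_RADIUS)
        frames.append(Frame(coords=box.wrap(coords), masses=masses, radii=radii, time=time))
        frame_no += 1
        pos += 2 + count
    if not frames:
        raise ParseError(f"{path}: no frames found")
    if missing_time:
        warnings.warn(
            f"{path}: frames without 't = <ns>' comments; using sequential indices",
            stacklevel=2,
        )
    times = np.array([f.time for f in frames])
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: frame times must be strictly increasing")
    return Trajectory(frames=frames, boxes=[box] * len(frames), mmap=mmap)


def write_xyz_trajectory(traj: Trajectory, path: str | Path, element: str = "C") -> None:
    """Write a multi-frame XYZ file in Angstrom with ``t = <ns>`` comments."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_beads}\nt = {frame.time!r} ns\n")
            for x, y, z in frame.coords * 10.0:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")
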