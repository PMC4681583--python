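"""Structure, topology, restraint, index and trajectory I/O.

GRO files are the primary exchange format: fixed-column text, positions in
nm, 1-based numbering that wraps at five digits. Writers are deterministic
(bit-stable for identical inputs). Trajectories may be concatenated
multi-frame GRO or XTC (read through MDAnalysis).

Only orthorhombic boxes are supported; a triclinic box line raises
:class:`UnsupportedGeometryError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .system import ParticleSystem
from .templates import UnsupportedSpeciesError, load_lipid_template

__all__ = [
    "Frame",
    "RestraintSet",
    "GroParseError",
    "UnsupportedGeometryError",
    "read_gro",
    "write_gro",
    "write_pdb",
    "write_top",
    "write_posre_itp",
    "write_ndx",
    "read_trajectory",
    "write_trajectory_gro",
    "write_xtc",
]


class GroParseError(ValueError):
    """Malformed GRO content; message carries the offending line number."""


class UnsupportedGeometryError(ValueError):
    """Raised for triclinic (non-orthorhombic) boxes."""


@dataclass
class Frame:
    """One trajectory frame: time in ps, positions and box in nm."""

    time: float
    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)


@dataclass
class RestraintSet:
    """Isotropic per-particle position restraints (kJ mol^-1 nm^-2)."""

    indices: np.ndarray  # 0-based particle indices
    force_constants: np.ndarray  # one per index

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1)
        fk = np.asarray(self.force_constants, dtype=float)
        if fk.ndim == 0:
            fk = np.full(len(self.indices), float(fk))
        self.force_constants = fk.reshape(-1)
        if len(self.force_constants) != len(self.indices):
            raise ValueError("one force constant per restrained particle required")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("restraint indices must be unique")
        if (self.force_constants < 0).any():
            raise ValueError("force constants must be >= 0")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_box_line(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(v) for v in line.split()]
    except ValueError:
        raise GroParseError(f"line {lineno}: unreadable box line {line!r}") from None
    if len(vals) not in (3, 9):
        raise GroParseError(f"line {lineno}: box line must have 3 or 9 fields")
    if len(vals) == 9 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise UnsupportedGeometryError(
            f"line {lineno}: triclinic box is not supported (off-diagonal terms present)"
        )
    return np.array(vals[:3], dtype=float)


def _parse_gro_block(lines: list[str], start: int):
    """Parse one GRO frame starting at ``lines[start]``.

    Returns (title, natoms, records, box, next_index) where records is a list
    of (resid, resname, atomname, position).
    """
    if start >= len(lines):
        raise GroParseError("unexpected end of file: missing title line")
    title = lines[start].rstrip("\n")
    if start + 1 >= len(lines):
        raise GroParseError(f"line {start + 2}: missing atom-count line")
    try:
        natoms = int(lines[start + 1].strip())
    except ValueError:
        raise GroParseError(
            f"line {start + 2}: atom count is not an integer: {lines[start + 1]!r}"
        ) from None
    body_start = start + 2
    if len(lines) < body_start + natoms + 1:  # atoms plus box line
        raise GroParseError(
            f"line {start + 2}: header declares {natoms} atoms but only "
            f"{max(0, len(lines) - body_start - 1)} atom lines follow"
        )
    records = []
    for k in range(natoms):
        lineno = body_start + k + 1
        line = lines[body_start + k].rstrip("\n")
        if len(line) < 44:
            raise GroParseError(f"line {lineno}: atom line too short ({len(line)} chars)")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            atomname = line[10:15].strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError:
            raise GroParseError(f"line {lineno}: malformed fixed-column fields") from None
        records.append((resid, resname, atomname, (x, y, z)))
    box = _parse_box_line(lines[body_start + natoms], body_start + natoms + 1)
    return title, natoms, records, box, body_start + natoms + 1


def _annotate_from_templates(resnames, atomnames, mol_ids):
    """Fill bead types and charges from species templates where they match."""
    n = len(resnames)
    bead_type = np.array(atomnames, dtype=object)
    charges = np.zeros(n)
    # group bead indices per molecule
    order = np.argsort(mol_ids, kind="stable")
    boundaries = np.flatnonzero(np.diff(mol_ids[order])) + 1
    groups = np.split(order, boundaries)
    for grp in groups:
        sp = resnames[grp[0]]
        try:
            tmpl = load_lipid_template(sp)
        except UnsupportedSpeciesError:
            continue
        names = tuple(atomnames[i] for i in grp)
        if names == tmpl.bead_names:
            for i, idx in enumerate(grp):
                bead_type[idx] = tmpl.bead_types[i]
                charges[idx] = tmpl.charges[i]
    return bead_type, charges


def read_gro(path) -> ParticleSystem:
    """Read a single-frame GRO file into a :class:`ParticleSystem`.

    Residue numbering is used to delimit molecules: a new molecule starts
    whenever the (wrapped) residue number or residue name changes between
    consecutive atom lines, so files beyond the 5-digit wraparound are read
    correctly. Velocities, if present, are ignored. Bead types and charges
    are reconstructed from the species templates when the residue name and
    bead names match a registered template; otherwise the bead type falls
    back to the atom name with zero charge.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise GroParseError("line 1: empty file")
    _, natoms, records, box, _ = _parse_gro_block(lines, 0)
    resids = np.array([r[0] for r in records], dtype=int)
    resnames = np.array([r[1] for r in records], dtype=object)
    atomnames = np.array([r[2] for r in records], dtype=object)
    positions = np.array([r[3] for r in records], dtype=float).reshape(-1, 3)
    # delimit molecules by change in residue number or name
    mol_ids = np.zeros(natoms, dtype=int)
    mid = 0
    for i in range(1, natoms):
        if resids[i] != resids[i - 1] or resnames[i] != resnames[i - 1]:
            mid += 1
        mol_ids[i] = mid
    bead_type, charges = _annotate_from_templates(resnames, atomnames, mol_ids)
    return ParticleSystem(
        positions=positions,
        bead_name=atomnames,
        bead_type=bead_type,
        species=resnames,
        molecule_id=mol_ids,
        residue_id=resids,
        charges=charges,
        box=box,
    )


def _gro_atom_lines(system: ParticleSystem) -> Iterator[str]:
    mids = system.molecule_id
    # renumber residues 1..M in bead order, wrapping at 5 digits
    resnum = np.empty(system.n_atoms, dtype=int)
    seen: dict[int, int] = {}
    for i, mid in enumerate(mids):
        if mid not in seen:
            seen[mid] = len(seen) + 1
        resnum[i] = seen[mid]
    for i in range(system.n_atoms):
        x, y, z = system.positions[i]
        yield (
            f"{resnum[i] % 100000:5d}{str(system.species[i])[:5]:<5s}"
            f"{str(system.bead_name[i])[:5]:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )


def write_gro(system: ParticleSystem, path, title: str = "asymmem system") -> None:
    """Write a system as fixed-column GRO (positions nm, no velocities)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{system.n_atoms:d}\n")
        for line in _gro_atom_lines(system):
            fh.write(line)
        bx, by, bz = system.box
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def write_trajectory_gro(frames: Iterable[Frame], system: ParticleSystem, path) -> None:
    """Write frames as a concatenated multi-frame GRO trajectory."""
    with open(path, "w") as fh:
        for fr in frames:
            snap = system.with_positions(fr.positions)
            snap.box = fr.box
            fh.write(f"asymmem frame t= {fr.time:.3f}\n{snap.n_atoms:d}\n")
            for line in _gro_atom_lines(snap):
                fh.write(line)
            bx, by, bz = snap.box
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (write-only convenience for visualization)
# ---------------------------------------------------------------------------

def write_pdb(system: ParticleSystem, path) -> None:
    """Write a minimal PDB (ATOM records, positions in Angstrom)."""
    with open(path, "w") as fh:
        bx, by, bz = system.box * 10.0
        fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}  90.00  90.00  90.00 P 1           1\n")
        resnum = 0
        last_mid = None
        for i in range(system.n_atoms):
            if system.molecule_id[i] != last_mid:
                resnum += 1
                last_mid = system.molecule_id[i]
            x, y, z = system.positions[i] * 10.0
            name = str(system.bead_name[i])[:4]
            res = str(system.species[i])[:4]
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {name:<4s}{res:<4s} {resnum % 10000:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# TOP / ITP / NDX
# ---------------------------------------------------------------------------

def write_top(system: ParticleSystem, path, name: str = "asymmem system") -> None:
    """Write a GROMACS-style topology skeleton with the molecules section.

    Only the ``[ system ]`` and ``[ molecules ]`` sections are emitted;
    counts follow the species order of first appearance in the system.
    """
    counts = system.species_counts()
    with open(path, "w") as fh:
        fh.write("[ system ]\n")
        fh.write(f"{name}\n\n")
        fh.write("[ molecules ]\n; species  count\n")
        for sp, n in counts.items():
            fh.write(f"{sp:<10s} {n:d}\n")


def write_posre_itp(restraints: RestraintSet, path) -> None:
    """Write position restraints, one isotropic entry per particle.

    Indices are emitted 1-based; the force constant (kJ mol^-1 nm^-2) is
    applied on all three axes.
    """
    with open(path, "w") as fh:
        fh.write("[ position_restraints ]\n;  i funct       fcx        fcy        fcz\n")
        for idx, k in zip(restraints.indices, restraints.force_constants):
            fh.write(f"{int(idx) + 1:6d}    1 {k:10.1f} {k:10.1f} {k:10.1f}\n")


def write_ndx(groups: Mapping[str, Sequence[int]], path) -> None:
    """Write named index groups (input 0-based, file 1-based, 15 per line)."""
    with open(path, "w") as fh:
        for name, indices in groups.items():
            fh.write(f"[ {name} ]\n")
            idx = [int(i) + 1 for i in indices]
            for start in range(0, len(idx), 15):
                fh.write(" ".join(f"{i:d}" for i in idx[start:start + 15]) + "\n")
            if not idx:
                fh.write("\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _read_gro_frames(path) -> list[Frame]:
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[Frame] = []
    pos = 0
    t_prev = -np.inf
    while pos < len(lines):
        if not "".join(lines[pos:]).strip():
            break
        try:
            title, _, records, box, nxt = _parse_gro_block(lines, pos)
        except GroParseError as err:
            warnings.warn(f"dropping truncated final frame of {path}: {err}")
            break
        time = _time_from_title(title, default=t_prev + 1.0 if frames else 0.0)
        t_prev = time
        frames.append(
            Frame(time=time, positions=np.array([r[3] for r in records]), box=box)
        )
        pos = nxt
    if frames:
        n0 = len(frames[0].positions)
        for fr in frames:
            if len(fr.positions) != n0:
                raise GroParseError("particle count varies across trajectory frames")
    return frames


def _time_from_title(title: str, default: float) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            pass
    return default


def _read_xtc_frames(path) -> list[Frame]:
    from MDAnalysis.coordinates.XTC import XTCReader

    frames: list[Frame] = []
    with XTCReader(str(path)) as reader:
        for ts in reader:
            frames.append(
                Frame(
                    time=float(ts.time),
                    positions=ts.positions.astype(float) / 10.0,  # A -> nm
                    box=np.asarray(ts.dimensions[:3], dtype=float) / 10.0,
                )
            )
    return frames


def read_trajectory(paths) -> list[Frame]:
    """Read one or more trajectory files (multi-frame GRO or XTC) in order."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[Frame] = []
    for p in paths:
        suffix = Path(p).suffix.lower()
        if suffix == ".xtc":
            frames.extend(_read_xtc_frames(p))
        else:
            frames.extend(_read_gro_frames(p))
    return frames


def write_xtc(frames: Iterable[Frame], path) -> None:
    """Write frames to XTC via MDAnalysis (positions converted to Angstrom)."""
    from MDAnalysis.coordinates.XTC import XTCWriter

    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty XTC trajectory")
    n = len(frames[0].positions)
    with XTCWriter(str(path), n_atoms=n) as w:
        for fr in frames:
            import MDAnalysis as mda

            u = mda.Universe.empty(n, trajectory=True)
            u.atoms.positions = fr.positions * 10.0
            u.dimensions = [fr.box[0] * 10, fr.box[1] * 10, fr.box[2] * 10, 90, 90, 90]
            u.trajectory.ts.time = fr.time
            w.write(u.atoms)
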