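"""Flat particle-table representation of a coarse-grained system.

A :class:`ParticleSystem` is a bead table: positions in nm plus per-bead
identity (bead name/type, species, molecule id, residue id, charge) and an
orthorhombic box. Builders assemble systems from lipid templates; analyses
consume them directly or together with trajectory frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .templates import LipidTemplate, load_lipid_template

__all__ = ["ParticleSystem", "ChargeLedger", "net_charge", "concat", "from_molecules"]


@dataclass
class ParticleSystem:
    """Flat table of beads with positions (nm) and molecular identity."""

    positions: np.ndarray  # (N, 3) nm
    bead_name: np.ndarray  # (N,) str
    bead_type: np.ndarray  # (N,) str
    species: np.ndarray  # (N,) str
    molecule_id: np.ndarray  # (N,) int
    residue_id: np.ndarray  # (N,) int
    charges: np.ndarray  # (N,) float
    box: np.ndarray  # (3,) nm
    periodic: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.bead_name = np.asarray(self.bead_name, dtype=object)
        self.bead_type = np.asarray(self.bead_type, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        for name in ("bead_name", "bead_type", "species", "molecule_id", "residue_id", "charges"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"per-particle field {name} has wrong length")
        if n and not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if not (self.box > 0).all():
            raise ValueError("box lengths must be strictly positive")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id)) if self.n_atoms else 0

    def _molecule_first_indices(self) -> np.ndarray:
        _, idx = np.unique(self.molecule_id, return_index=True)
        return np.sort(idx)

    def molecule_ids(self) -> np.ndarray:
        """Distinct molecule ids in first-appearance order."""
        return self.molecule_id[self._molecule_first_indices()]

    def molecule_species(self) -> np.ndarray:
        """Species of each molecule, in first-appearance order."""
        return self.species[self._molecule_first_indices()]

    def species_counts(self) -> dict[str, int]:
        """Molecule count per species, in first-appearance order."""
        counts: dict[str, int] = {}
        for sp in self.molecule_species():
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    def molecule_mask(self, mid: int) -> np.ndarray:
        return self.molecule_id == mid

    def select(self, mask: np.ndarray) -> "ParticleSystem":
        """Sub-system of the masked beads (molecule ids kept as-is)."""
        return ParticleSystem(
            positions=self.positions[mask].copy(),
            bead_name=self.bead_name[mask].copy(),
            bead_type=self.bead_type[mask].copy(),
            species=self.species[mask].copy(),
            molecule_id=self.molecule_id[mask].copy(),
            residue_id=self.residue_id[mask].copy(),
            charges=self.charges[mask].copy(),
            box=self.box.copy(),
            periodic=self.periodic,
        )

    def copy(self) -> "ParticleSystem":
        return self.select(np.ones(self.n_atoms, dtype=bool))

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        if len(positions) != self.n_atoms:
            raise ValueError("position array length mismatch")
        return ParticleSystem(
            positions=positions,
            bead_name=self.bead_name.copy(),
            bead_type=self.bead_type.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            residue_id=self.residue_id.copy(),
            charges=self.charges.copy(),
            box=self.box.copy(),
            periodic=self.periodic,
        )

    def renumber(self) -> "ParticleSystem":
        """Relabel molecule ids 0..M-1 and residue ids 1..M in bead order."""
        out = self.copy()
        new = np.empty(self.n_atoms, dtype=int)
        mapping: dict[int, int] = {}
        for i, mid in enumerate(self.molecule_id):
            if mid not in mapping:
                mapping[mid] = len(mapping)
            new[i] = mapping[mid]
        out.molecule_id = new
        out.residue_id = new + 1
        return out

    def validate_against_templates(self) -> None:
        """Check every molecule's bead names match its species template."""
        for mid in self.molecule_ids():
            mask = self.molecule_id == mid
            sp = self.species[mask][0]
            tmpl = load_lipid_template(sp)
            names = tuple(self.bead_name[mask])
            if names != tmpl.bead_names:
                raise ValueError(
                    f"molecule {mid} ({sp}): bead names {names} do not match template"
                )


def empty_system(box: Sequence[float]) -> ParticleSystem:
    z = np.zeros(0)
    e = np.array([], dtype=object)
    return ParticleSystem(
        positions=np.zeros((0, 3)), bead_name=e.copy(), bead_type=e.copy(),
        species=e.copy(), molecule_id=np.zeros(0, dtype=int),
        residue_id=np.zeros(0, dtype=int), charges=z, box=np.asarray(box, float),
    )


def from_molecules(
    placements: Iterable[tuple[LipidTemplate, np.ndarray]],
    box: Sequence[float],
    start_molecule_id: int = 0,
) -> ParticleSystem:
    """Assemble a system from (template, bead-position-array) placements."""
    pos, names, types, specs, mids, rids, chg = [], [], [], [], [], [], []
    mid = start_molecule_id
    for tmpl, coords in placements:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (tmpl.n_beads, 3):
            raise ValueError(f"{tmpl.species}: placement shape {coords.shape}")
        pos.append(coords)
        names.extend(tmpl.bead_names)
        types.extend(tmpl.bead_types)
        specs.extend([tmpl.species] * tmpl.n_beads)
        mids.extend([mid] * tmpl.n_beads)
        rids.extend([mid + 1] * tmpl.n_beads)
        chg.extend(tmpl.charges)
        mid += 1
    if not pos:
        return empty_system(box)
    return ParticleSystem(
        positions=np.concatenate(pos),
        bead_name=np.array(names, dtype=object),
        bead_type=np.array(types, dtype=object),
        species=np.array(specs, dtype=object),
        molecule_id=np.array(mids, dtype=int),
        residue_id=np.array(rids, dtype=int),
        charges=np.array(chg, dtype=float),
        box=np.asarray(box, dtype=float),
    )


def concat(a: ParticleSystem, b: ParticleSystem, box: Sequence[float] | None = None) -> ParticleSystem:
    """Concatenate two systems; b's molecule ids are shifted past a's."""
    shift = (int(a.molecule_id.max()) + 1) if a.n_atoms else 0
    if b.n_atoms:
        bmin = int(b.molecule_id.min())
    return ParticleSystem(
        positions=np.concatenate([a.positions, b.positions]),
        bead_name=np.concatenate([a.bead_name, b.bead_name]),
        bead_type=np.concatenate([a.bead_type, b.bead_type]),
        species=np.concatenate([a.species, b.species]),
        molecule_id=np.concatenate(
            [a.molecule_id, (b.molecule_id - bmin + shift) if b.n_atoms else b.molecule_id]
        ),
        residue_id=np.concatenate(
            [a.residue_id, (b.molecule_id - bmin + shift + 1) if b.n_atoms else b.residue_id]
        ),
        charges=np.concatenate([a.charges, b.charges]),
        box=np.asarray(box if box is not None else a.box, dtype=float),
        periodic=a.periodic,
    )


@dataclass
class ChargeLedger:
    """Per-species charge bookkeeping for neutralization."""

    species_counts: dict[str, int] = field(default_factory=dict)
    species_charge: dict[str, float] = field(default_factory=dict)
    system_charge: float = 0.0

    @property
    def cations_needed(self) -> int:
        """Monovalent cations required to bring the net charge to zero."""
        return max(0, int(round(-self.system_charge)))


def net_charge(system: ParticleSystem) -> ChargeLedger:
    """Total charge accounting of a system, by species and overall."""
    counts = system.species_counts()
    per_species: dict[str, float] = {}
    for sp in counts:
        mask = system.species == sp
        first_mid = system.molecule_id[mask][0]
        q_mol = float(system.charges[(system.molecule_id == first_mid) & mask].sum())
        per_species[sp] = q_mol
    total = float(round(float(system.charges.sum()), 9))
    return ChargeLedger(species_counts=counts, species_charge=per_species,
                        system_charge=total)
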