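"""Planar asymmetric bilayer starting configurations.

Two lipid slabs — one with the cytoplasmic (CP) leaflet mixture, one with
the intravesicular (IV) mixture — are packed independently, then stacked
into a taller box with a configurable vertical overlap (default 0.5 nm;
zero overlap leaves a lipid-poor seam that fills with water and tends to
split the self-assembling membrane in two). The stacked configuration is
then optionally enriched with PIP2, a protein is co-placed across the
seam, and the box is solvated and neutralized with monovalent cations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .packing import CellList, PackingError, random_rotation_matrix, spawn_seed
from .system import ChargeLedger, ParticleSystem, concat, empty_system, from_molecules, net_charge
from .templates import load_lipid_template

__all__ = [
    "SlabSpec",
    "StackSpec",
    "GeometryError",
    "SolvationError",
    "pack_box",
    "stack_boxes",
    "substitute_species",
    "place_protein_planar",
    "solvate",
    "neutralize",
    "build_planar",
    "PlanarBuildResult",
]

DEFAULT_CLASH_CUTOFF = 0.3  # nm, between beads of different molecules
DEFAULT_MAX_RETRIES = 1000


class GeometryError(ValueError):
    """Incompatible box/slab/protein geometry."""


class SolvationError(RuntimeError):
    """Too few water beads for the requested conversion."""


@dataclass
class SlabSpec:
    """A lipid slab to pack: box dims (nm), composition, seed, clash cutoff."""

    dims: tuple[float, float, float]
    composition: Mapping[str, int]
    seed: int = 0
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    max_retries: int = DEFAULT_MAX_RETRIES

    def __post_init__(self) -> None:
        self.dims = tuple(float(d) for d in self.dims)
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError("slab dims must be three positive lengths")
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("composition counts must be >= 0")
        if self.clash_cutoff <= 0:
            raise ValueError("clash cutoff must be positive")


@dataclass
class StackSpec:
    """How two slabs stack: overlap (nm), merged box, which slab is upper."""

    overlap: float
    merged_dims: tuple[float, float, float]
    upper: str = "CP"
    lower: str = "IV"

    def __post_init__(self) -> None:
        self.merged_dims = tuple(float(d) for d in self.merged_dims)
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


def _feasibility_check(spec: SlabSpec, volume: float) -> None:
    """Crude volume heuristic: beads at the clash cutoff must fit."""
    n_beads = sum(
        load_lipid_template(sp).n_beads * n for sp, n in spec.composition.items()
    )
    bead_vol = (4.0 / 3.0) * np.pi * (spec.clash_cutoff / 2.0) ** 3
    if n_beads * bead_vol > 0.64 * volume:  # random close packing bound
        raise PackingError(
            f"composition infeasible: {n_beads} beads at cutoff "
            f"{spec.clash_cutoff} nm cannot fit a volume of {volume:.1f} nm^3"
        )


def _pack_molecules(spec: SlabSpec, sample_and_check, volume: float) -> list:
    """Shared rejection-packing loop over the spec's composition.

    ``sample_and_check(rng, tmpl)`` must return candidate bead coordinates
    inside the allowed region, or None to signal a geometric rejection.
    """
    _feasibility_check(spec, volume)
    rng = np.random.default_rng(spec.seed)
    cells = CellList(spec.clash_cutoff)
    placements = []
    achieved = 0
    for sp in spec.composition:
        tmpl = load_lipid_template(sp)
        for _ in range(int(spec.composition[sp])):
            for _attempt in range(spec.max_retries):
                coords = sample_and_check(rng, tmpl)
                if coords is None:
                    continue
                if cells.any_within_cutoff(coords):
                    continue
                cells.add(coords)
                placements.append((tmpl, coords))
                achieved += 1
                break
            else:
                raise PackingError(
                    f"packing infeasible: placed {achieved} molecules before "
                    f"exhausting {spec.max_retries} retries on a {sp} molecule"
                )
    return placements


def pack_box(spec: SlabSpec) -> ParticleSystem:
    """Randomly pack the spec's molecules into its box.

    Every bead ends strictly inside the box; no two beads of different
    molecules come closer than the clash cutoff; each molecule's
    orientation is uniform over rotations. Deterministic for a fixed seed.
    """
    dims = np.asarray(spec.dims)

    def sample(rng: np.random.Generator, tmpl):
        center = rng.uniform(0.0, dims)
        rot = random_rotation_matrix(rng)
        coords = center + tmpl.internal_coords @ rot.T
        if (coords <= 0).any() or (coords >= dims).any():
            return None
        return coords

    placements = _pack_molecules(spec, sample, float(np.prod(dims)))
    return from_molecules(placements, box=spec.dims)


def stack_boxes(lower: ParticleSystem, upper: ParticleSystem, stack: StackSpec) -> ParticleSystem:
    """Stack the upper slab on the lower one with the requested overlap.

    The upper slab is lifted by (lower slab height - overlap), the merged
    system is centered in the merged box, and molecule counts are conserved.
    Molecules of the lower slab keep the lowest molecule ids, so slab origin
    remains recoverable from id order.
    """
    if not np.allclose(lower.box[:2], upper.box[:2]):
        raise GeometryError(
            f"slab x/y dims differ: {lower.box[:2]} vs {upper.box[:2]}"
        )
    if stack.overlap >= lower.box[2]:
        raise GeometryError("overlap must be smaller than the slab height")
    shift = lower.box[2] - stack.overlap
    lifted = upper.with_positions(upper.positions + np.array([0.0, 0.0, shift]))
    merged = concat(lower, lifted, box=stack.merged_dims)
    if merged.n_atoms:
        lo = merged.positions.min(axis=0)
        hi = merged.positions.max(axis=0)
        center_shift = (np.asarray(stack.merged_dims) - (hi + lo)) / 2.0
        merged = merged.with_positions(merged.positions + center_shift)
    return merged


def substitute_species(
    system: ParticleSystem,
    from_species: str,
    to_species: str,
    n: int,
    seed: int = 0,
) -> ParticleSystem:
    """Replace ``n`` randomly chosen molecules of one species by another.

    The replacement molecule is rebuilt from its template with the head
    bead anchored at the old head-bead position and the template axis
    aligned with the old molecule's head-to-tail axis. Molecule ids and
    ordering are preserved; all other species counts are unchanged.
    """
    if n == 0:
        return system.copy()
    old_tmpl = load_lipid_template(from_species)
    new_tmpl = load_lipid_template(to_species)
    mids = system.molecule_ids()
    mol_species = system.molecule_species()
    candidates = mids[mol_species == from_species]
    if len(candidates) < n:
        raise ValueError(
            f"cannot substitute {n} {from_species} molecules; only "
            f"{len(candidates)} present"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(candidates, size=n, replace=False).tolist())

    keep_mask = np.ones(system.n_atoms, dtype=bool)
    new_blocks = {}
    for mid in chosen:
        mask = system.molecule_id == mid
        old_pos = system.positions[mask]
        names = list(system.bead_name[mask])
        head = old_pos[names.index(old_tmpl.head_bead)]
        tail_idx = [names.index(t) for t in old_tmpl.tail_beads]
        axis = old_pos[tail_idx].mean(axis=0) - head if tail_idx else None
        if axis is None or np.linalg.norm(axis) < 1e-9:
            rot = random_rotation_matrix(rng)
        else:
            rot = _rotation_between(new_tmpl.axis, axis / np.linalg.norm(axis))
        new_blocks[mid] = head + new_tmpl.internal_coords @ rot.T
        keep_mask &= ~mask

    # rebuild bead table in molecule order, splicing in the new molecules
    pos, names, types, specs, mids_out, rids, chg = [], [], [], [], [], [], []
    for mid in mids:
        mask = system.molecule_id == mid
        if mid in chosen:
            coords = new_blocks[mid]
            pos.append(coords)
            names.extend(new_tmpl.bead_names)
            types.extend(new_tmpl.bead_types)
            specs.extend([new_tmpl.species] * new_tmpl.n_beads)
            mids_out.extend([mid] * new_tmpl.n_beads)
            rids.extend([int(system.residue_id[mask][0])] * new_tmpl.n_beads)
            chg.extend(new_tmpl.charges)
        else:
            pos.append(system.positions[mask])
            names.extend(system.bead_name[mask])
            types.extend(system.bead_type[mask])
            specs.extend(system.species[mask])
            mids_out.extend(system.molecule_id[mask])
            rids.extend(system.residue_id[mask])
            chg.extend(system.charges[mask])
    return ParticleSystem(
        positions=np.concatenate(pos),
        bead_name=np.array(names, dtype=object),
        bead_type=np.array(types, dtype=object),
        species=np.array(specs, dtype=object),
        molecule_id=np.array(mids_out, dtype=int),
        residue_id=np.array(rids, dtype=int),
        charges=np.array(chg, dtype=float),
        box=system.box.copy(),
        periodic=system.periodic,
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


@dataclass
class PlacementReport:
    """Bookkeeping for a protein placement: which lipids were displaced."""

    removed_molecule_ids: np.ndarray
    n_removed: int


def place_protein_planar(
    system: ParticleSystem,
    protein: ParticleSystem,
    c_term_toward: str = "IV",
    iv_species: Sequence[str] = ("PPCS", "POPC"),
    cp_species: Sequence[str] = ("POPS", "POPE"),
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> tuple[ParticleSystem, PlacementReport]:
    """Insert a protein across the slab seam of a stacked lipid pair.

    The protein is centered laterally, its long (principal) axis aligned
    with z, and translated so its C-terminal bead (the last bead of the
    highest residue) falls inside the z-range of the requested slab.
    Lipid molecules with any bead within the clash cutoff of a protein
    bead are removed and reported.
    """
    slabs = {"IV": iv_species, "CP": cp_species}
    if c_term_toward not in slabs:
        raise ValueError("c_term_toward must be 'IV' or 'CP'")
    target_mask = np.isin(system.species, list(slabs[c_term_toward]))
    if not target_mask.any():
        raise GeometryError(f"no {c_term_toward} marker lipids present in the system")
    z_lo = float(system.positions[target_mask, 2].min())
    z_hi = float(system.positions[target_mask, 2].max())

    pos = protein.positions - protein.positions.mean(axis=0)
    span = pos.max(axis=0) - pos.min(axis=0)
    # principal axis -> z
    _, _, vt = np.linalg.svd(pos - pos.mean(axis=0), full_matrices=False)
    rot = _rotation_between(vt[0] / np.linalg.norm(vt[0]), np.array([0.0, 0.0, 1.0]))
    pos = pos @ rot.T
    if pos[:, 2].max() - pos[:, 2].min() > system.box[2]:
        raise GeometryError("protein is longer than the box height")

    # C-terminal bead: last bead of the highest residue id
    c_idx = int(np.flatnonzero(protein.residue_id == protein.residue_id.max())[-1])
    slab_mid = 0.5 * (z_lo + z_hi)
    system_mid = 0.5 * (system.positions[:, 2].min() + system.positions[:, 2].max())
    # orient: C-term should point toward the requested slab
    if (slab_mid - system_mid) * pos[c_idx, 2] < 0:
        pos[:, [1, 2]] *= -1.0  # 180 degree flip about x
    dz = slab_mid - pos[c_idx, 2]
    dz = min(max(dz, -pos[:, 2].min()), system.box[2] - pos[:, 2].max())
    pos = pos + np.array([system.box[0] / 2.0, system.box[1] / 2.0, dz])
    if not (z_lo <= pos[c_idx, 2] <= z_hi):
        raise GeometryError("could not place the C-terminal bead inside the requested slab")

    placed = protein.with_positions(pos)
    placed.box = system.box.copy()

    tree = cKDTree(pos)
    close = tree.query_ball_point(system.positions, r=clash_cutoff)
    clash_beads = np.array([len(c) > 0 for c in close])
    removed_mids = np.unique(system.molecule_id[clash_beads])
    keep = ~np.isin(system.molecule_id, removed_mids)
    merged = concat(system.select(keep), placed)
    report = PlacementReport(removed_molecule_ids=removed_mids, n_removed=len(removed_mids))
    return merged, report


def solvate(
    system: ParticleSystem,
    water_spacing: float = 0.47,
    exclusion: float = 0.47,
    seed: int = 0,
    jitter: float = 0.1,
) -> ParticleSystem:
    """Fill the box with CG water beads on a jittered cubic lattice.

    Lattice points within ``exclusion`` of any existing bead are discarded.
    """
    rng = np.random.default_rng(seed)
    box = system.box
    axes = [np.arange(water_spacing / 2.0, b, water_spacing) for b in box]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid + rng.uniform(-jitter, jitter, size=grid.shape) * water_spacing
    grid = np.clip(grid, 1e-6, box - 1e-6)
    if system.n_atoms:
        tree = cKDTree(system.positions)
        dmin, _ = tree.query(grid, k=1)
        grid = grid[dmin > exclusion]
    if len(grid) == 0:
        return system.copy()
    w = load_lipid_template("W")
    waters = from_molecules([(w, g.reshape(1, 3)) for g in grid], box=box)
    return concat(system, waters)


def neutralize(system: ParticleSystem, cation: str = "NA", seed: int = 0) -> ParticleSystem:
    """Swap water beads for cations until the net charge is zero."""
    ledger = net_charge(system)
    n = ledger.cations_needed
    if n == 0:
        return system.copy()
    tmpl = load_lipid_template(cation)
    if tmpl.net_charge != 1:
        raise ValueError("neutralize currently supports monovalent cations only")
    water_mask = system.species == "W"
    water_mids = np.unique(system.molecule_id[water_mask])
    if len(water_mids) < n:
        raise SolvationError(
            f"{n} cations needed but only {len(water_mids)} waters available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(water_mids, size=n, replace=False)
    out = system.copy()
    swap = np.isin(out.molecule_id, chosen)
    out.species[swap] = cation
    out.bead_name[swap] = tmpl.bead_names[0]
    out.bead_type[swap] = tmpl.bead_types[0]
    out.charges[swap] = tmpl.charges[0]
    return out


@dataclass
class PlanarBuildResult:
    """A built planar starting configuration plus construction bookkeeping."""

    system: ParticleSystem
    iv_counts: dict[str, int]
    cp_counts: dict[str, int]
    ledger: ChargeLedger
    protein_report: PlacementReport | None = None

    def iv_share(self) -> dict[str, float]:
        """Percent of each lipid species assigned to the IV slab at t=0."""
        out = {}
        for sp in sorted(set(self.iv_counts) | set(self.cp_counts)):
            iv = self.iv_counts.get(sp, 0)
            cp = self.cp_counts.get(sp, 0)
            if iv + cp:
                out[sp] = 100.0 * iv / (iv + cp)
        return out


def build_planar(
    iv_composition: Mapping[str, int],
    cp_composition: Mapping[str, int],
    slab_dims: tuple[float, float, float] = (16.0, 16.0, 5.0),
    merged_dims: tuple[float, float, float] = (16.0, 16.0, 13.0),
    overlap: float = 0.5,
    seed: int = 0,
    pip2_n: int | None = None,
    pip2_frac: float | None = None,
    protein: ParticleSystem | None = None,
    c_term_toward: str = "IV",
    solvate_box: bool = True,
    water_spacing: float = 0.47,
    exclusion: float = 0.47,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> PlanarBuildResult:
    """End-to-end planar construction: pack, stack, substitute, place, solvate.

    The IV slab is packed as the lower box and the CP slab as the upper
    box. If ``pip2_frac`` is given (and ``pip2_n`` is not), the PIP2 count
    is round(frac * phospholipids in the CP slab); PIP2 replaces POPC in
    the CP slab, mirroring where the polyanionic lipid belongs in a
    cytoplasmic leaflet.
    """
    iv = pack_box(SlabSpec(slab_dims, iv_composition, seed=spawn_seed(seed, "iv"),
                           clash_cutoff=clash_cutoff))
    cp = pack_box(SlabSpec(slab_dims, cp_composition, seed=spawn_seed(seed, "cp"),
                           clash_cutoff=clash_cutoff))
    stacked = stack_boxes(iv, cp, StackSpec(overlap=overlap, merged_dims=merged_dims))
    iv_counts = dict(iv.species_counts())
    cp_counts = dict(cp.species_counts())

    n_pip2 = pip2_n
    if n_pip2 is None and pip2_frac is not None:
        phospho = sum(
            n for sp, n in cp_composition.items()
            if load_lipid_template(sp).head_bead == "PO4"
        )
        n_pip2 = int(round(pip2_frac * phospho))
    if n_pip2:
        stacked = substitute_species(
            stacked, "POPC", "PIP2", n_pip2, seed=spawn_seed(seed, "pip2")
        )
        # recount per slab from the system: lower molecule ids are IV-origin
        n_iv_mol = sum(iv_counts.values())
        iv_counts, cp_counts = {}, {}
        for mid, sp in zip(stacked.molecule_ids(), stacked.molecule_species()):
            bucket = iv_counts if mid < n_iv_mol else cp_counts
            bucket[sp] = bucket.get(sp, 0) + 1

    report = None
    if protein is not None:
        stacked, report = place_protein_planar(
            stacked, protein, c_term_toward=c_term_toward, clash_cutoff=clash_cutoff
        )

    out = stacked
    if solvate_box:
        out = solvate(out, water_spacing=water_spacing, exclusion=exclusion,
                      seed=spawn_seed(seed, "solvate"))
        out = neutralize(out, seed=spawn_seed(seed, "neutralize"))
    return PlanarBuildResult(
        system=out,
        iv_counts=iv_counts,
        cp_counts=cp_counts,
        ledger=net_charge(out),
        protein_report=report,
    )
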