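"""Vesicle starting configurations from overlapping concentric lipid shells.

The inner (IV) shell carries the intravesicular leaflet mixture and the
outer (CP) shell the cytoplasmic mixture; the CP shell's inner radius sits
slightly inside the IV shell's outer radius (0.5 nm overlap by default) so
that the seam between the two lipid populations stays lipid-dense. Shell
bounds are radii in nm. Protein copies can be co-placed along random,
minimally separated radial directions with per-residue radial anchors
(e.g. the C-terminus in the IV shell, a tryptophan in the CP shell, the
SNARE motif outside the vesicle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .packing import random_rotation_matrix, spawn_seed
from .planar import (
    DEFAULT_CLASH_CUTOFF,
    DEFAULT_MAX_RETRIES,
    GeometryError,
    _pack_molecules,
    _rotation_between,
    neutralize,
    solvate,
)
from .system import ChargeLedger, ParticleSystem, concat, from_molecules, net_charge

__all__ = [
    "ShellSpec",
    "VesicleSpec",
    "PlacementError",
    "pack_shell",
    "assemble_concentric",
    "place_proteins_radial",
    "build_vesicle",
    "VesicleBuildResult",
]


class PlacementError(RuntimeError):
    """Radial anchor constraints cannot be satisfied."""


@dataclass
class ShellSpec:
    """A spherical lipid shell to pack, bounded by radii in nm."""

    r_inner: float
    r_outer: float
    composition: Mapping[str, int]
    orientation_mode: str = "random"  # random | radial_out | radial_in
    seed: int = 0
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    max_retries: int = DEFAULT_MAX_RETRIES

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError("require 0 < r_inner < r_outer")
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("composition counts must be >= 0")
        if self.orientation_mode not in ("random", "radial_out", "radial_in"):
            raise ValueError(f"unknown orientation mode {self.orientation_mode!r}")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.r_outer**3 - self.r_inner**3)

    @property
    def mid_radius(self) -> float:
        return 0.5 * (self.r_inner + self.r_outer)


@dataclass
class VesicleSpec:
    """Two concentric shells plus the cubic box edge (nm)."""

    iv_shell: ShellSpec
    cp_shell: ShellSpec
    box_edge: float

    def __post_init__(self) -> None:
        if self.cp_shell.r_inner > self.iv_shell.r_outer:
            raise ValueError("shells must touch or overlap (cp.r_inner <= iv.r_outer)")
        if self.box_edge < 2 * self.cp_shell.r_outer:
            raise ValueError("box edge must cover the outer shell diameter")

    @property
    def overlap(self) -> float:
        return self.iv_shell.r_outer - self.cp_shell.r_inner


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def pack_shell(spec: ShellSpec) -> ParticleSystem:
    """Randomly pack the spec's molecules into a spherical shell at the origin.

    Every bead's distance from the center lies within [r_inner, r_outer];
    the clash constraint and determinism match the planar packer. In the
    radial orientation modes the molecular head-to-tail axis points along
    +r (radial_out) or -r (radial_in) instead of being drawn uniformly.
    """
    ri, ro = spec.r_inner, spec.r_outer

    def sample(rng: np.random.Generator, tmpl):
        u = rng.uniform(ri**3, ro**3)
        direction = _random_unit_vector(rng)
        center = u ** (1.0 / 3.0) * direction
        if spec.orientation_mode == "random":
            rot = random_rotation_matrix(rng)
        else:
            target = direction if spec.orientation_mode == "radial_out" else -direction
            rot = _rotation_between(tmpl.axis, target)
        coords = center + tmpl.internal_coords @ rot.T
        r = np.linalg.norm(coords, axis=1)
        if (r < ri).any() or (r > ro).any():
            return None
        return coords

    placements = _pack_molecules(spec, sample, spec.volume)
    edge = 2.0 * ro + 1.0
    return from_molecules(placements, box=(edge, edge, edge))


def assemble_concentric(
    iv: ParticleSystem, cp: ParticleSystem, box_edge: float
) -> ParticleSystem:
    """Merge two origin-centered shells and center them in a cubic box."""
    merged = concat(iv, cp, box=(box_edge, box_edge, box_edge))
    if merged.n_atoms:
        r_max = float(np.linalg.norm(merged.positions, axis=1).max())
        if 2.0 * r_max > box_edge:
            raise GeometryError(
                f"box edge {box_edge} nm too small for radial extent {r_max:.2f} nm"
            )
        merged = merged.with_positions(merged.positions + box_edge / 2.0)
    return merged


@dataclass
class RadialPlacementReport:
    """Directions used per protein copy and the lipids displaced by them."""

    directions: np.ndarray  # (n_copies, 3)
    removed_molecule_ids: np.ndarray
    n_removed: int


def _min_separated_directions(
    n: int, min_angle_deg: float, rng: np.random.Generator, max_tries: int = 20000
) -> np.ndarray:
    cos_min = np.cos(np.radians(min_angle_deg))
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} directions at >= {min_angle_deg} deg separation"
            )
        d = _random_unit_vector(rng)
        if dirs and max(float(d @ e) for e in dirs) > cos_min:
            continue
        dirs.append(d)
    return np.array(dirs)


def place_proteins_radial(
    system: ParticleSystem,
    protein: ParticleSystem,
    n_copies: int,
    anchors: Mapping[int, tuple[float, float | None]],
    min_angle_deg: float = 30.0,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    seed: int = 0,
    center: np.ndarray | None = None,
) -> tuple[ParticleSystem, RadialPlacementReport]:
    """Place protein copies along random radial directions of a vesicle.

    ``anchors`` maps residue ids to radial bands (r_lo, r_hi) in nm from
    the vesicle center (r_hi None means unbounded, i.e. "at the exterior").
    Each copy's long axis is aligned radially, oriented so the anchor with
    the smallest target radius points inward, and slid along its direction
    until every anchor bead's radial distance falls inside its band.
    Lipid molecules clashing with any copy are removed and reported.
    """
    if n_copies == 0:
        return system.copy(), RadialPlacementReport(
            directions=np.zeros((0, 3)), removed_molecule_ids=np.array([], dtype=int),
            n_removed=0,
        )
    if not anchors:
        raise ValueError("at least one radial anchor is required")
    rng = np.random.default_rng(seed)
    if center is None:
        center = system.positions.mean(axis=0) if system.n_atoms else np.zeros(3)
    center = np.asarray(center, dtype=float)

    # protein internal frame: principal axis, signed so the innermost anchor
    # has the most negative axis coordinate
    pos0 = protein.positions - protein.positions.mean(axis=0)
    _, _, vt = np.linalg.svd(pos0, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    anchor_beads = {}
    for rid in anchors:
        idx = np.flatnonzero(protein.residue_id == rid)
        if len(idx) == 0:
            raise PlacementError(f"anchor residue {rid} absent from the protein")
        anchor_beads[rid] = int(idx[0])
    inner_rid = min(anchors, key=lambda r: anchors[r][0])
    outer_rid = max(anchors, key=lambda r: anchors[r][0])
    if pos0[anchor_beads[inner_rid]] @ axis > pos0[anchor_beads[outer_rid]] @ axis:
        axis = -axis

    directions = _min_separated_directions(n_copies, min_angle_deg, rng)
    copies = []
    for d in directions:
        rot = _rotation_between(axis, d)
        q = pos0 @ rot.T
        # feasible band of radial offsets t for each anchor: |t d + q_i| in band
        t_lo, t_hi = -np.inf, np.inf
        for rid, (lo, hi) in anchors.items():
            qi = q[anchor_beads[rid]]
            a = float(qi @ d)
            b2 = float(qi @ qi) - a * a
            hi_eff = np.inf if hi is None else float(hi)
            if hi_eff**2 < b2:
                raise PlacementError(
                    f"anchor residue {rid}: lateral offset {np.sqrt(b2):.2f} nm "
                    f"exceeds its outer radius {hi_eff}"
                )
            lo2 = max(float(lo) ** 2 - b2, 0.0)
            t_lo = max(t_lo, np.sqrt(lo2) - a)
            t_hi = min(t_hi, (np.sqrt(hi_eff**2 - b2) - a) if np.isfinite(hi_eff) else np.inf)
        if t_lo > t_hi:
            raise PlacementError(
                "anchor radial bands are jointly unsatisfiable for this protein length"
            )
        t = t_lo if not np.isfinite(t_hi) else 0.5 * (t_lo + t_hi)
        copies.append(center + t * d + q)

    out = system.copy()
    all_protein = np.concatenate(copies)
    removed_mids = np.array([], dtype=int)
    if out.n_atoms:
        tree = cKDTree(all_protein)
        close = tree.query_ball_point(out.positions, r=clash_cutoff)
        clash = np.array([len(c) > 0 for c in close])
        removed_mids = np.unique(out.molecule_id[clash])
        out = out.select(~np.isin(out.molecule_id, removed_mids))
    for c in copies:
        placed = protein.with_positions(c)
        placed.box = system.box.copy()
        out = concat(out, placed)
    report = RadialPlacementReport(
        directions=directions, removed_molecule_ids=removed_mids,
        n_removed=len(removed_mids),
    )
    return out, report


@dataclass
class VesicleBuildResult:
    """A built vesicle plus construction bookkeeping."""

    system: ParticleSystem
    iv_counts: dict[str, int]
    cp_counts: dict[str, int]
    ledger: ChargeLedger
    protein_report: RadialPlacementReport | None = None

    def iv_share(self) -> dict[str, float]:
        out = {}
        for sp in sorted(set(self.iv_counts) | set(self.cp_counts)):
            iv = self.iv_counts.get(sp, 0)
            cp = self.cp_counts.get(sp, 0)
            if iv + cp:
                out[sp] = 100.0 * iv / (iv + cp)
        return out


def build_vesicle(
    spec: VesicleSpec,
    seed: int = 0,
    solvate_box: bool = False,
    water_spacing: float = 0.47,
    exclusion: float = 0.47,
) -> VesicleBuildResult:
    """Pack both shells, assemble them concentrically, optionally solvate."""
    iv_spec = ShellSpec(
        spec.iv_shell.r_inner, spec.iv_shell.r_outer, spec.iv_shell.composition,
        orientation_mode=spec.iv_shell.orientation_mode,
        seed=spawn_seed(seed, "iv-shell"), clash_cutoff=spec.iv_shell.clash_cutoff,
        max_retries=spec.iv_shell.max_retries,
    )
    cp_spec = ShellSpec(
        spec.cp_shell.r_inner, spec.cp_shell.r_outer, spec.cp_shell.composition,
        orientation_mode=spec.cp_shell.orientation_mode,
        seed=spawn_seed(seed, "cp-shell"), clash_cutoff=spec.cp_shell.clash_cutoff,
        max_retries=spec.cp_shell.max_retries,
    )
    iv = pack_shell(iv_spec)
    cp = pack_shell(cp_spec)
    merged = assemble_concentric(iv, cp, spec.box_edge)
    if solvate_box:
        merged = solvate(merged, water_spacing=water_spacing, exclusion=exclusion,
                         seed=spawn_seed(seed, "solvate"))
        merged = neutralize(merged, seed=spawn_seed(seed, "neutralize"))
    return VesicleBuildResult(
        system=merged,
        iv_counts=dict(iv.species_counts()),
        cp_counts=dict(cp.species_counts()),
        ledger=net_charge(merged),
    )
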