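"""Water-lined pore construct for equilibrating vesicle bilayers.

Transmembrane cylinders (default radius 1.5 nm along +x, -x, +y, -y from
the lipid center of mass) are emptied of lipids; surviving lipids whose
head bead lies within a conversion shell (default 1.7 nm) of a pore's
cylindrical surface have all their bead types set to the water type (P4)
while keeping their bonded identity — so-called wlipids — and each wlipid's
head bead receives an isotropic position restraint (default 300
kJ mol^-1 nm^-2) so the hydrophilic pore lining cannot diffuse away.
Reverting restores the template bead types and drops the restraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .io import RestraintSet
from .system import ParticleSystem
from .templates import UnsupportedSpeciesError, load_lipid_template

__all__ = [
    "PoreSpec",
    "CarveReport",
    "DegeneratePoreError",
    "LineageError",
    "carve_water_lined_pores",
    "revert_wlipids",
]

_DEFAULT_AXES = (
    (1.0, 0.0, 0.0),
    (-1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, -1.0, 0.0),
)


class DegeneratePoreError(ValueError):
    """A pore axis does not pass through the membrane."""


class LineageError(ValueError):
    """A carve report does not match the system it is applied to."""


@dataclass
class PoreSpec:
    """Pore geometry and conversion parameters."""

    axes: tuple[tuple[float, float, float], ...] = _DEFAULT_AXES
    cylinder_radius: float = 1.5  # nm
    conversion_shell: float = 1.7  # nm beyond the cylinder surface
    water_type: str = "P4"
    restraint_k: float = 300.0  # kJ mol^-1 nm^-2
    removal_mode: str = "any_bead"  # any_bead | head_bead

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0 or self.conversion_shell <= 0:
            raise ValueError("radius and shell must be positive")
        if self.removal_mode not in ("any_bead", "head_bead"):
            raise ValueError(f"unknown removal mode {self.removal_mode!r}")
        axes = []
        for a in self.axes:
            v = np.asarray(a, dtype=float)
            n = np.linalg.norm(v)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError(f"axis {a} is not unit length")
            axes.append(tuple(v))
        self.axes = tuple(axes)


@dataclass
class CarveReport:
    """What a carve did: removals, conversions, restraints, per-pore tallies."""

    removed_molecule_ids: np.ndarray
    wlipid_molecule_ids: np.ndarray
    restraints: RestraintSet
    per_pore: list[dict] = field(default_factory=list)
    water_type: str = "P4"


def _lipid_molecule_mask(system: ParticleSystem) -> np.ndarray:
    """Bead mask of molecules that are lipids (templated, multi-bead)."""
    lipidlike = np.zeros(system.n_atoms, dtype=bool)
    for sp in set(system.species.tolist()):
        try:
            tmpl = load_lipid_template(sp)
        except UnsupportedSpeciesError:
            continue
        if tmpl.tail_beads:
            lipidlike |= system.species == sp
    return lipidlike


def _head_bead_mask(system: ParticleSystem, lipid_mask: np.ndarray) -> np.ndarray:
    mask = np.zeros(system.n_atoms, dtype=bool)
    for sp in set(system.species[lipid_mask].tolist()):
        tmpl = load_lipid_template(sp)
        mask |= (system.species == sp) & (system.bead_name == tmpl.head_bead)
    return mask


def carve_water_lined_pores(
    system: ParticleSystem, spec: PoreSpec, center: np.ndarray | None = None
) -> tuple[ParticleSystem, CarveReport]:
    """Carve half-space pore cylinders and convert the lining to wlipids.

    Each axis defines one pore running outward from the lipid center of
    mass. A lipid is removed when (by default) any of its beads lies at
    perpendicular distance < cylinder_radius from the axis on the axis's
    half-space; a surviving lipid becomes a wlipid when its head bead lies
    within the conversion shell of a pore's cylindrical surface. Water,
    ions and protein molecules are never touched.
    """
    lipid_mask = _lipid_molecule_mask(system)
    if not lipid_mask.any():
        warnings.warn("no lipids in system; nothing to carve")
        return system.copy(), CarveReport(
            removed_molecule_ids=np.array([], dtype=int),
            wlipid_molecule_ids=np.array([], dtype=int),
            restraints=RestraintSet(np.array([], dtype=int), np.array([])),
            water_type=spec.water_type,
        )
    if center is None:
        center = system.positions[lipid_mask].mean(axis=0)
    rel = system.positions - np.asarray(center, dtype=float)
    head_mask = _head_bead_mask(system, lipid_mask)

    sel_mask = head_mask if spec.removal_mode == "head_bead" else lipid_mask
    removed = np.zeros(system.n_atoms, dtype=bool)  # bead-level flags
    per_pore: list[dict] = []
    pore_info = []
    for a in spec.axes:
        axis = np.asarray(a)
        s = rel @ axis
        perp = np.linalg.norm(rel - np.outer(s, axis), axis=1)
        in_cyl = (perp < spec.cylinder_radius) & (s >= 0.0)
        if not (in_cyl & lipid_mask).any() and not (
            (perp < spec.cylinder_radius + spec.conversion_shell) & (s >= 0.0) & lipid_mask
        ).any():
            raise DegeneratePoreError(f"pore axis {a} does not intersect the membrane")
        pore_info.append((axis, s, perp))
        removed |= in_cyl & sel_mask
    removed_mids = np.unique(system.molecule_id[removed])

    survivors = ~np.isin(system.molecule_id, removed_mids)
    wlipid_mids: set[int] = set()
    for axis, s, perp in pore_info:
        near_surface = (
            head_mask
            & survivors
            & (s >= 0.0)
            & (perp > spec.cylinder_radius)
            & (perp <= spec.cylinder_radius + spec.conversion_shell)
        )
        pore_w = set(np.unique(system.molecule_id[near_surface]).tolist())
        pore_removed = set(
            np.unique(system.molecule_id[removed & (perp < spec.cylinder_radius) & (s >= 0)]).tolist()
        )
        per_pore.append(
            {"axis": tuple(axis), "n_removed": len(pore_removed), "n_wlipid": len(pore_w)}
        )
        wlipid_mids |= pore_w

    out = system.select(survivors)
    wlipid_arr = np.array(sorted(wlipid_mids), dtype=int)
    w_bead_mask = np.isin(out.molecule_id, wlipid_arr)
    out.bead_type[w_bead_mask] = spec.water_type

    out_head_mask = _head_bead_mask(out, _lipid_molecule_mask(out))
    restrained = np.flatnonzero(out_head_mask & w_bead_mask)
    restraints = RestraintSet(restrained, np.full(len(restrained), spec.restraint_k))
    report = CarveReport(
        removed_molecule_ids=removed_mids,
        wlipid_molecule_ids=wlipid_arr,
        restraints=restraints,
        per_pore=per_pore,
        water_type=spec.water_type,
    )
    return out, report


def revert_wlipids(system: ParticleSystem, report: CarveReport) -> ParticleSystem:
    """Restore every wlipid's bead types from its species template."""
    out = system.copy()
    present = np.unique(out.molecule_id)
    missing = [int(m) for m in report.wlipid_molecule_ids if m not in present]
    if missing:
        raise LineageError(f"wlipid molecule ids {missing} not found in this system")
    for mid in report.wlipid_molecule_ids:
        mask = out.molecule_id == mid
        sp = out.species[mask][0]
        tmpl = load_lipid_template(sp)
        names = list(out.bead_name[mask])
        if tuple(names) != tmpl.bead_names:
            raise LineageError(f"molecule {mid} bead layout does not match its template")
        idx = np.flatnonzero(mask)
        for k, i in enumerate(idx):
            out.bead_type[i] = tmpl.bead_types[k]
    return out
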