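"""Idealized systems and trajectories with known ground truth.

These fixtures are geometric idealizations — lattices, Fibonacci spheres,
scripted walkers — not physical configurations, and must not be used as
simulation inputs. Every generator returns its ground truth alongside the
system so analyses can be validated without molecular dynamics: leaflet
labels for bilayers and vesicles, the input diffusion coefficient for
Brownian trajectories, the contact schedule for ligand trajectories.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import Frame
from .planar import GeometryError
from .system import ParticleSystem, from_molecules
from .templates import load_lipid_template

__all__ = [
    "ideal_bilayer",
    "ideal_vesicle",
    "brownian_traj",
    "contact_traj",
    "helix_protein",
]


def _species_sequence(composition: Mapping[str, int], rng: np.random.Generator) -> list[str]:
    seq = [sp for sp, n in composition.items() for _ in range(int(n))]
    rng.shuffle(seq)
    return seq


def ideal_bilayer(
    iv_composition: Mapping[str, int],
    cp_composition: Mapping[str, int],
    apl: float = 0.65,
    thickness: float = 4.3,
    jitter: float = 0.05,
    seed: int = 0,
    box_side: float | None = None,
    margin: float = 3.0,
) -> tuple[ParticleSystem, dict]:
    """Lipids on a jittered lattice: heads at +-thickness/2, exact leaflets.

    The lateral box side is sqrt(n x APL) for the larger leaflet unless
    given explicitly; lattice jitter is lateral only, so head-group density
    peaks sit exactly at +-thickness/2 around the midplane. IV is the
    lower leaflet. Returns (system, ground_truth) where the ground truth
    maps molecule id -> (species, leaflet label).
    """
    rng = np.random.default_rng(seed)
    n_max = max(sum(iv_composition.values()), sum(cp_composition.values()))
    if n_max == 0:
        raise ValueError("empty composition")
    side = box_side if box_side is not None else float(np.sqrt(n_max * apl))
    if box_side is not None:
        spacing = float(np.sqrt(apl))
        n_fit = int(side / spacing + 1e-9) ** 2
        if n_fit < n_max:
            raise GeometryError(
                f"lattice of side {side:.2f} nm holds {n_fit} lipids at APL {apl}; "
                f"{n_max} requested"
            )
    box_z = thickness + 2.0 * margin
    z_mid = box_z / 2.0
    placements = []
    truth: dict[int, tuple[str, str]] = {}
    mid = 0
    for leaflet, comp, sign in (("IV", iv_composition, -1.0), ("CP", cp_composition, 1.0)):
        seq = _species_sequence(comp, rng)
        per_row = int(np.ceil(np.sqrt(len(seq)))) if seq else 1
        pitch = side / per_row if per_row else side
        for k, sp in enumerate(seq):
            tmpl = load_lipid_template(sp)
            ix, iy = k % per_row, k // per_row
            x = (ix + 0.5) * pitch + rng.uniform(-jitter, jitter)
            y = (iy + 0.5) * pitch + rng.uniform(-jitter, jitter)
            head = np.array([x % side, y % side, z_mid + sign * thickness / 2.0])
            # tails point toward the midplane
            coords = tmpl.internal_coords.copy()
            if sign < 0:
                coords = coords * np.array([1.0, 1.0, -1.0])
            placements.append((tmpl, head + coords))
            truth[mid] = (sp, leaflet)
            mid += 1
    system = from_molecules(placements, box=(side, side, box_z))
    return system, {"leaflets": truth, "thickness": thickness, "apl": apl}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def ideal_vesicle(
    iv_composition: Mapping[str, int],
    cp_composition: Mapping[str, int],
    r_inner: float = 15.6,
    r_outer: float = 20.0,
    seed: int = 0,
    margin: float = 3.0,
) -> tuple[ParticleSystem, dict]:
    """Fibonacci-sphere head shells at r_inner/r_outer, tails to mid-surface.

    Inner-shell (IV) heads sit exactly at radius r_inner with tails
    pointing outward toward the bilayer mid-surface; outer-shell (CP)
    heads at r_outer with tails pointing inward. Returns (system,
    ground_truth) with per-molecule leaflet labels and the shell radii.
    """
    from .planar import _rotation_between

    rng = np.random.default_rng(seed)
    box = 2.0 * r_outer + 2.0 * margin
    center = np.full(3, box / 2.0)
    placements = []
    truth: dict[int, tuple[str, str]] = {}
    mid = 0
    for leaflet, comp, radius, outward in (
        ("IV", iv_composition, r_inner, True),
        ("CP", cp_composition, r_outer, False),
    ):
        seq = _species_sequence(comp, rng)
        n = len(seq)
        if n == 0:
            continue
        dirs = _fibonacci_sphere(n)
        for sp, d in zip(seq, dirs):
            tmpl = load_lipid_template(sp)
            target = d if outward else -d  # head-to-tail axis direction
            rot = _rotation_between(tmpl.axis, target)
            coords = center + radius * d + tmpl.internal_coords @ rot.T
            placements.append((tmpl, coords))
            truth[mid] = (sp, leaflet)
            mid += 1
    system = from_molecules(placements, box=(box, box, box))
    return system, {
        "leaflets": truth,
        "r_inner": r_inner,
        "r_outer": r_outer,
        "center": center.tolist(),
    }


def brownian_traj(
    n_particles: int = 1000,
    n_frames: int = 500,
    D_cm2_s: float = 2.5e-7,
    dt_ps: float = 100.0,
    seed: int = 0,
    box: Sequence[float] = (50.0, 50.0, 10.0),
) -> tuple[ParticleSystem, list[Frame], dict]:
    """2-D Brownian walkers at a stated lateral diffusion coefficient.

    Each particle takes independent Gaussian steps in x and y with
    per-step variance 2 D dt per axis (so the 2-D squared displacement per
    step averages 4 D dt); z is static. Coordinates are unwrapped.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    D_nm2_ps = D_cm2_s / 1.0e-2  # cm^2 s^-1 -> nm^2 ps^-1
    sigma = np.sqrt(2.0 * D_nm2_ps * dt_ps)
    start = rng.uniform(0.0, box, size=(n_particles, 3))
    w = load_lipid_template("W")
    system = from_molecules([(w, p.reshape(1, 3)) for p in start], box=box)
    frames = []
    pos = start.copy()
    for t in range(n_frames):
        frames.append(Frame(time=t * dt_ps, positions=pos.copy(), box=box.copy()))
        step = np.zeros_like(pos)
        step[:, :2] = rng.normal(scale=sigma, size=(n_particles, 2))
        pos = pos + step
    truth = {"D_cm2_s": D_cm2_s, "dt_ps": dt_ps, "n_frames": n_frames}
    return system, frames, truth


def helix_protein(
    n_residues: int = 30,
    rise: float = 0.35,
    radius: float = 0.25,
    start_residue: int = 1,
    species: str = "PROT",
) -> ParticleSystem:
    """A synthetic straight CG helix: one backbone bead per residue along z.

    Residue ids run from ``start_residue`` upward, so the C-terminal bead
    is the last (highest-z) bead. The whole helix is one molecule.
    """
    k = np.arange(n_residues)
    theta = 2.0 * np.pi * k / 3.6
    pos = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k], axis=1
    )
    n = n_residues
    box = (5.0, 5.0, rise * n + 2.0)
    return ParticleSystem(
        positions=pos + np.array([2.5, 2.5, 1.0]),
        bead_name=np.array(["BB"] * n, dtype=object),
        bead_type=np.array(["P5"] * n, dtype=object),
        species=np.array([species] * n, dtype=object),
        molecule_id=np.zeros(n, dtype=int),
        residue_id=np.arange(start_residue, start_residue + n),
        charges=np.zeros(n),
        box=box,
    )


def contact_traj(
    n_frames: int = 100,
    contact_residue: int = 260,
    schedule: Sequence[bool] | None = None,
    cutoff: float = 0.6,
    residue_range: tuple[int, int] = (245, 270),
    seed: int = 0,
) -> tuple[ParticleSystem, list[Frame], dict]:
    """A single ligand bead scripted into/out of contact range of one residue.

    The protein is a straight rod (one backbone bead per residue, 0.35 nm
    apart); the ligand is a lone PIP2-labeled head bead. In "in" frames it
    sits at 0.9 x cutoff from the contact residue's bead, which keeps it
    outside the cutoff of the neighboring residues; in "out" frames it is
    parked far from every residue. Returns (system, frames, truth) where
    the truth records the boolean contact schedule.
    """
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = rng.random(n_frames) < 0.5
    schedule = np.asarray(schedule, dtype=bool)
    n_frames = len(schedule)
    lo, hi = residue_range
    helix = helix_protein(n_residues=hi - lo + 1, start_residue=lo, radius=0.0)
    far = np.array([40.0, 40.0, 40.0])
    n_prot = helix.n_atoms
    ligand = ParticleSystem(
        positions=far.reshape(1, 3),
        bead_name=np.array(["PO4"], dtype=object),
        bead_type=np.array(["Qa"], dtype=object),
        species=np.array(["PIP2"], dtype=object),
        molecule_id=np.array([0]),
        residue_id=np.array([1]),
        charges=np.array([-1.0]),
        box=(80.0, 80.0, 80.0),
    )
    from .system import concat

    system = concat(helix, ligand, box=(80.0, 80.0, 80.0))
    res_idx = int(np.flatnonzero(system.residue_id == contact_residue)[0])
    frames = []
    for t, inside in enumerate(schedule):
        pos = system.positions.copy()
        if inside:
            pos[n_prot] = pos[res_idx] + np.array([0.9 * cutoff, 0.0, 0.0])
        else:
            pos[n_prot] = far
        frames.append(Frame(time=float(t), positions=pos, box=system.box.copy()))
    truth = {
        "schedule": schedule,
        "contact_residue": contact_residue,
        "expected_frequency": float(schedule.mean()),
        "cutoff": cutoff,
    }
    return system, frames, truth
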