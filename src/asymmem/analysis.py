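"""Membrane analyses: leaflet accounting, area per lipid, order parameters,
density and radial-distribution profiles, lateral diffusion, and
lipid-residue contact statistics.

Conventions
-----------
* Leaflets are labeled IV (intravesicular: below the planar midplane, or
  inside the vesicle mid-radius) and CP (cytoplasmic: the other side);
  lipids whose head bead sits inside a dead zone around the mid-surface
  (default 0.5 nm) are labeled ``midplane`` — cholesterol resident in the
  membrane center ends up there rather than being forced into a leaflet.
* Head beads are PO4 for phospholipids and ROH for cholesterol.
* The second-rank order parameter is S2 = (3<cos^2 theta> - 1)/2 for the
  angle theta between a bond vector and the membrane normal; it is bounded
  by [-1/2, 1] and vanishes for isotropic orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .io import Frame
from .planar import GeometryError, _rotation_between
from .pores import _head_bead_mask, _lipid_molecule_mask
from .system import ParticleSystem
from .templates import load_lipid_template

__all__ = [
    "LeafletTable",
    "APLResult",
    "OrderTable",
    "RDFProfile",
    "DiffusionResult",
    "ContactTable",
    "assign_leaflets",
    "composition_report",
    "phospholipid_percentages",
    "excise_patch",
    "voronoi_apl",
    "periodic_voronoi_areas",
    "sphere_apl",
    "second_rank_order",
    "order_parameter",
    "density_profile",
    "com_rdf",
    "vesicle_radii",
    "lateral_diffusion",
    "contact_frequency",
    "aligned_density",
]

BEAD_MASS = 72.0  # amu; the standard 4-to-1 CG mapping mass


# ---------------------------------------------------------------------------
# leaflet assignment and composition accounting
# ---------------------------------------------------------------------------

@dataclass
class LeafletTable:
    """Per-lipid leaflet labels plus per-species counts and IV fractions."""

    molecule_ids: np.ndarray
    species: np.ndarray
    labels: np.ndarray  # 'IV' | 'CP' | 'midplane'

    @classmethod
    def from_counts(
        cls,
        iv: Mapping[str, int],
        cp: Mapping[str, int],
        midplane: Mapping[str, int] | None = None,
    ) -> "LeafletTable":
        """Build a table from per-leaflet species counts (one row per lipid)."""
        mids, specs, labels = [], [], []
        i = 0
        for label, counts in (("IV", iv), ("CP", cp), ("midplane", midplane or {})):
            for sp, n in counts.items():
                for _ in range(int(n)):
                    mids.append(i)
                    specs.append(sp)
                    labels.append(label)
                    i += 1
        return cls(
            molecule_ids=np.array(mids, dtype=int),
            species=np.array(specs, dtype=object),
            labels=np.array(labels, dtype=object),
        )

    def counts(self, label: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.species[self.labels == label]:
            out[sp] = out.get(sp, 0) + 1
        return out

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species:
            seen.setdefault(sp, None)
        return list(seen)

    def iv_fraction(self) -> dict[str, float]:
        """Percent of each species in IV over its IV+CP total (midplane excluded)."""
        iv, cp = self.counts("IV"), self.counts("CP")
        out = {}
        for sp in self.species_names():
            tot = iv.get(sp, 0) + cp.get(sp, 0)
            if tot:
                out[sp] = 100.0 * iv.get(sp, 0) / tot
        return out


def assign_leaflets(
    system: ParticleSystem,
    geometry: str = "planar",
    dead_zone: float = 0.5,
    center: np.ndarray | None = None,
) -> LeafletTable:
    """Label every lipid IV, CP or midplane.

    Planar: labels follow the head bead's z relative to the bilayer
    midplane, taken as the center of mass of all lipid tail beads (IV is
    the lower side). Vesicle: labels follow the head bead's radial
    distance relative to the mid-radius, the mean of per-lipid head radii
    (IV is inside). Heads within ``dead_zone`` of the mid-surface are
    labeled midplane.
    """
    lipid_mask = _lipid_molecule_mask(system)
    if not lipid_mask.any():
        raise ValueError("no lipid molecules in system")
    head_mask = _head_bead_mask(system, lipid_mask)
    mids = system.molecule_id[head_mask]
    specs = system.species[head_mask]
    heads = system.positions[head_mask]

    if geometry == "planar":
        tails = _tail_bead_mask(system, lipid_mask)
        midplane = float(system.positions[tails, 2].mean())
        coord = heads[:, 2] - midplane
    elif geometry == "vesicle":
        if center is None:
            center = system.positions[lipid_mask].mean(axis=0)
        r = np.linalg.norm(heads - np.asarray(center, dtype=float), axis=1)
        coord = r - float(r.mean())
    else:
        raise ValueError("geometry must be 'planar' or 'vesicle'")

    labels = np.where(
        np.abs(coord) <= dead_zone / 2.0,
        "midplane",
        np.where(coord < 0, "IV", "CP"),
    ).astype(object)
    return LeafletTable(molecule_ids=mids, species=specs, labels=labels)


def _tail_bead_mask(system: ParticleSystem, lipid_mask: np.ndarray) -> np.ndarray:
    mask = np.zeros(system.n_atoms, dtype=bool)
    for sp in set(system.species[lipid_mask].tolist()):
        tmpl = load_lipid_template(sp)
        for tb in tmpl.tail_beads:
            mask |= (system.species == sp) & (system.bead_name == tb)
    return mask


def phospholipid_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Each species' molecule count as a percent of total phospholipids.

    Cholesterol (and any other non-phosphate lipid) is reported on the
    same denominator, the convention used for cholesterol:phospholipid
    ratios in membrane composition tables.
    """
    phospho = 0
    for sp, n in counts.items():
        try:
            if load_lipid_template(sp).head_bead == "PO4":
                phospho += n
        except Exception:
            continue
    if phospho == 0:
        raise ValueError("no phospholipids in the composition")
    return {sp: 100.0 * n / phospho for sp, n in counts.items()}


def composition_report(table: LeafletTable) -> dict:
    """Three normalizations of the leaflet composition.

    Returns a dict with, per species: ``overall_pct`` (% of all lipids),
    ``iv_pct``/``cp_pct`` (% within each leaflet), and ``iv_share_pct``
    (% of the species' IV+CP total residing in IV). Midplane lipids count
    toward the overall total but are excluded from IV-share denominators.
    """
    if len(table.molecule_ids) == 0:
        raise ValueError("empty leaflet table")
    iv, cp, mid = table.counts("IV"), table.counts("CP"), table.counts("midplane")
    total = len(table.molecule_ids)
    n_iv = sum(iv.values())
    n_cp = sum(cp.values())
    share = table.iv_fraction()
    out: dict[str, dict[str, float]] = {}
    for sp in table.species_names():
        n_sp = iv.get(sp, 0) + cp.get(sp, 0) + mid.get(sp, 0)
        out[sp] = {
            "total": n_sp,
            "iv_count": iv.get(sp, 0),
            "cp_count": cp.get(sp, 0),
            "midplane_count": mid.get(sp, 0),
            "overall_pct": 100.0 * n_sp / total,
            "iv_pct": 100.0 * iv.get(sp, 0) / n_iv if n_iv else float("nan"),
            "cp_pct": 100.0 * cp.get(sp, 0) / n_cp if n_cp else float("nan"),
            "iv_share_pct": share.get(sp, float("nan")),
        }
    return out


# ---------------------------------------------------------------------------
# patches and area per lipid
# ---------------------------------------------------------------------------

def excise_patch(
    system: ParticleSystem,
    size: float = 14.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    center: np.ndarray | None = None,
    pad: float = 2.0,
) -> ParticleSystem:
    """Cut a flat size x size bilayer patch from a vesicle at the +axis pole.

    Lipids whose head bead projects into the lateral window around the
    pole (on the +axis hemisphere) are extracted whole; the local frame is
    rotated so the membrane normal becomes +z and shifted so the patch is
    centered laterally in its new box.
    """
    lipid_mask = _lipid_molecule_mask(system)
    if not lipid_mask.any():
        raise ValueError("no lipid molecules in system")
    if center is None:
        center = system.positions[lipid_mask].mean(axis=0)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = system.positions - np.asarray(center, dtype=float)
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    rel = rel @ rot.T

    head_mask = _head_bead_mask(system, lipid_mask)
    r_max = float(np.linalg.norm(rel[head_mask], axis=1).max())
    if size > 2.0 * r_max:
        raise GeometryError(f"patch size {size} nm exceeds the vesicle extent")
    sel_heads = (
        head_mask
        & (rel[:, 2] > 0)
        & (np.abs(rel[:, 0]) <= size / 2.0)
        & (np.abs(rel[:, 1]) <= size / 2.0)
    )
    keep_mids = np.unique(system.molecule_id[sel_heads])
    keep = np.isin(system.molecule_id, keep_mids)
    patch = system.select(keep)
    coords = rel[keep]
    z_lo = coords[:, 2].min()
    coords = coords + np.array([size / 2.0, size / 2.0, -z_lo + pad / 2.0])
    patch = patch.with_positions(coords)
    patch.box = np.array([size, size, coords[:, 2].max() + pad / 2.0])
    return patch


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def periodic_voronoi_areas(points: np.ndarray, dims: Sequence[float]) -> np.ndarray:
    """Voronoi cell areas of 2-D sites under periodic boundary conditions.

    The sites are tiled into the 8 neighboring images, the Euclidean
    Voronoi diagram computed once, and the areas of the central-copy cells
    returned. Their sum equals the box area exactly (up to round-off).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 1:
        raise ValueError("at least one site required")
    lx, ly = float(dims[0]), float(dims[1])
    shifts = [
        (dx * lx, dy * ly) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
    ]
    tiled = np.concatenate([points + np.array(s) for s in shifts])
    if len(points) < 3:
        # scipy needs >= 4 non-degenerate sites; with tiling we always have
        # enough unless the points coincide
        pass
    vor = Voronoi(tiled)
    # the central copy is the block with zero shift
    central_offset = shifts.index((0.0, 0.0)) * len(points)
    areas = np.empty(len(points))
    for i in range(len(points)):
        region = vor.regions[vor.point_region[central_offset + i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell in the central copy")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


@dataclass
class APLResult:
    """Per-lipid Voronoi areas of one monolayer (nm^2)."""

    leaflet: str
    areas: np.ndarray
    patch_area: float

    @property
    def mean(self) -> float:
        return float(self.areas.mean())

    @property
    def std(self) -> float:
        return float(self.areas.std())


def voronoi_apl(
    patch: ParticleSystem,
    table: LeafletTable | None = None,
    dead_zone: float = 0.5,
) -> dict[str, APLResult]:
    """Voronoi-tessellation area per lipid for each monolayer of a patch.

    Sites are the lateral (x, y) head-bead coordinates — PO4 for
    phospholipids, ROH for cholesterol — tessellated with periodic images
    in the patch plane. Requires at least 3 sites per monolayer.
    """
    if table is None:
        table = assign_leaflets(patch, geometry="planar", dead_zone=dead_zone)
    lipid_mask = _lipid_molecule_mask(patch)
    head_mask = _head_bead_mask(patch, lipid_mask)
    head_mid = patch.molecule_id[head_mask]
    head_xy = patch.positions[head_mask][:, :2]
    label_of = dict(zip(table.molecule_ids.tolist(), table.labels.tolist()))
    out = {}
    for leaflet in ("IV", "CP"):
        sel = np.array([label_of.get(int(m)) == leaflet for m in head_mid])
        sites = head_xy[sel]
        if len(sites) < 3:
            raise GeometryError(
                f"monolayer {leaflet}: {len(sites)} sites; need >= 3 for tessellation"
            )
        areas = periodic_voronoi_areas(sites, patch.box[:2])
        out[leaflet] = APLResult(
            leaflet=leaflet, areas=areas, patch_area=float(patch.box[0] * patch.box[1])
        )
    return out


def sphere_apl(radius_nm: float, n_lipids: int) -> float:
    """Area per lipid of a spherical monolayer, in Angstrom^2.

    The monolayer surface 4 pi r^2 is shared evenly by its n lipids.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if n_lipids < 1:
        raise ValueError("need at least one lipid")
    area_nm2 = 4.0 * np.pi * radius_nm**2
    return area_nm2 / n_lipids * 100.0  # nm^2 -> A^2


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def second_rank_order(cos_theta: np.ndarray) -> float:
    """S2 = (3<cos^2 theta> - 1) / 2."""
    c = np.asarray(cos_theta, dtype=float)
    return float((3.0 * np.mean(c * c) - 1.0) / 2.0)


@dataclass
class OrderTable:
    """S2 per species and consecutive-bond label."""

    values: dict[tuple[str, str], float]
    normal: str

    def by_species(self, species: str) -> dict[str, float]:
        return {b: v for (sp, b), v in self.values.items() if sp == species}


def _species_block_indices(system: ParticleSystem, species: str) -> np.ndarray:
    """(n_mol, n_beads) bead-index matrix for a templated species."""
    tmpl = load_lipid_template(species)
    idx = np.flatnonzero(system.species == species)
    if len(idx) % tmpl.n_beads:
        raise ValueError(f"{species}: bead count not a multiple of the template size")
    return idx.reshape(-1, tmpl.n_beads)


def order_parameter(
    system: ParticleSystem,
    frames: Iterable[Frame] | None = None,
    species: Sequence[str] | None = None,
    normal: str = "z",
    center: np.ndarray | None = None,
) -> OrderTable:
    """Second-rank order parameter of consecutive-bead bonds.

    ``normal='z'`` measures angles against the laboratory z axis (planar
    bilayers and excised patches); ``normal='radial'`` against the local
    radial direction from the vesicle center. The average runs over
    molecules and frames. Zero-length bond vectors are skipped with a
    warning.
    """
    if species is None:
        lipid_mask = _lipid_molecule_mask(system)
        species = sorted(set(system.species[lipid_mask].tolist()))
    frame_positions = (
        [f.positions for f in frames] if frames is not None else [system.positions]
    )
    values: dict[tuple[str, str], float] = {}
    for sp in species:
        tmpl = load_lipid_template(sp)
        blocks = _species_block_indices(system, sp)
        if blocks.size == 0:
            continue
        names = tmpl.bead_names
        for i, j in tmpl.bonds:
            label = f"{names[i]}-{names[j]}"
            cosines = []
            for pos in frame_positions:
                a = pos[blocks[:, i]]
                b = pos[blocks[:, j]]
                bond = b - a
                norms = np.linalg.norm(bond, axis=1)
                ok = norms > 1e-9
                if not ok.all():
                    warnings.warn(f"{sp} {label}: skipped {np.sum(~ok)} zero-length bonds")
                bond = bond[ok]
                norms = norms[ok]
                if normal == "z":
                    cos = bond[:, 2] / norms
                elif normal == "radial":
                    c = (
                        np.asarray(center, dtype=float)
                        if center is not None
                        else pos.mean(axis=0)
                    )
                    midpoints = 0.5 * (a[ok] + b[ok]) - c
                    rhat = midpoints / np.linalg.norm(midpoints, axis=1, keepdims=True)
                    cos = np.einsum("ij,ij->i", bond, rhat) / norms
                else:
                    raise ValueError("normal must be 'z' or 'radial'")
                cosines.append(cos)
            if cosines and sum(len(c) for c in cosines):
                values[(sp, label)] = second_rank_order(np.concatenate(cosines))
    return OrderTable(values=values, normal=normal)


# ---------------------------------------------------------------------------
# density profiles and RDF
# ---------------------------------------------------------------------------

def standard_groups(system: ParticleSystem) -> dict[str, np.ndarray]:
    """Named bead masks for the conventional profile groups."""
    lipid = _lipid_molecule_mask(system)
    name = system.bead_name.astype(str)
    groups = {
        "water": system.species == "W",
        "PO4": lipid & (name == "PO4"),
        "HG": lipid & np.isin(name, ["NC3", "NH3", "CNO", "P1", "P2", "ROH"]),
        "GL": lipid & np.isin(name, ["GL1", "GL2", "AM1", "AM2"]),
        "tails": lipid
        & (
            np.char.startswith(name, "C")
            | np.char.startswith(name, "D")
            | np.char.startswith(name, "T")
        )
        & ~np.isin(name, ["CNO"]),
    }
    terminal = np.zeros(system.n_atoms, dtype=bool)
    for sp in set(system.species[lipid].tolist()):
        tmpl = load_lipid_template(sp)
        for tb in tmpl.tail_beads:
            terminal |= (system.species == sp) & (system.bead_name == tb)
    groups["terminal"] = terminal
    return groups


@dataclass
class DensityProfiles:
    """Mass density (amu nm^-3) vs coordinate, midplane at 0."""

    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    cross_section: float


def density_profile(
    system: ParticleSystem,
    groups: Mapping[str, np.ndarray] | None = None,
    frames: Iterable[Frame] | None = None,
    axis: int = 2,
    bin_width: float = 0.1,
    bead_mass: float = BEAD_MASS,
) -> DensityProfiles:
    """Frame-averaged partial density profiles along a box axis.

    The coordinate origin is placed at the bilayer midplane (the lipid
    tail-bead center of mass, recomputed per frame). An empty group yields
    a zero profile with a warning.
    """
    if groups is None:
        groups = standard_groups(system)
    lateral = [i for i in range(3) if i != axis]
    cross = float(system.box[lateral[0]] * system.box[lateral[1]])
    half = float(system.box[axis]) / 2.0
    edges = np.arange(-half, half + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    lipid = _lipid_molecule_mask(system)
    tails = _tail_bead_mask(system, lipid) if lipid.any() else None
    frame_positions = (
        [f.positions for f in frames] if frames is not None else [system.positions]
    )
    sums = {name: np.zeros(len(centers)) for name in groups}
    for pos in frame_positions:
        origin = float(pos[tails, axis].mean()) if tails is not None and tails.any() else half
        coord = pos[:, axis] - origin
        for name, mask in groups.items():
            if not np.asarray(mask).any():
                warnings.warn(f"density group {name!r} is empty")
                continue
            hist, _ = np.histogram(coord[mask], bins=edges)
            sums[name] += hist
    n_frames = len(frame_positions)
    vol = cross * bin_width
    densities = {n: s * bead_mass / (vol * n_frames) for n, s in sums.items()}
    return DensityProfiles(
        bin_centers=centers, densities=densities, bin_width=bin_width, cross_section=cross
    )


@dataclass
class RDFProfile:
    """Shell-normalized radial density about a center of mass."""

    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    selection: str = ""


def com_rdf(
    system: ParticleSystem,
    selection: np.ndarray,
    frames: Iterable[Frame] | None = None,
    bin_width: float = 0.1,
    r_max: float | None = None,
    description: str = "",
) -> RDFProfile:
    """g(r) of selected beads about the selection's own center of mass.

    Normalized so that uniformly distributed points inside the r_max ball
    give g = 1: counts in each shell are divided by the shell volume and
    the mean density N / (4/3 pi r_max^3).
    """
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty selection")
    if r_max is None:
        r_max = float(system.box.min()) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    frame_positions = (
        [f.positions for f in frames] if frames is not None else [system.positions]
    )
    counts = np.zeros(len(centers))
    n_sel = int(selection.sum())
    for pos in frame_positions:
        p = pos[selection]
        com = p.mean(axis=0)
        r = np.linalg.norm(p - com, axis=1)
        hist, _ = np.histogram(r, bins=edges)
        counts += hist
    counts /= len(frame_positions)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = n_sel / (4.0 / 3.0 * np.pi * edges[-1] ** 3)
    g = counts / (shell_vol * rho)
    return RDFProfile(bin_centers=centers, g=g, bin_width=bin_width, selection=description)


def vesicle_radii(
    profile: RDFProfile, smooth_bins: int = 3, min_separation_bins: int = 5
) -> tuple[float, float, float]:
    """Inner/outer head-group peak radii and their separation (nm).

    Peaks are local maxima of the moving-average-smoothed g(r); the two
    largest maxima at least ``min_separation_bins`` apart are returned in
    radius order (ties broken toward larger g). A single-peak profile
    returns outer = inner with zero separation.
    """
    g = profile.g
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        g = np.convolve(g, kernel, mode="same")
    peaks = [
        i
        for i in range(1, len(g) - 1)
        if g[i] > 0 and g[i] >= g[i - 1] and g[i] >= g[i + 1]
    ]
    if not peaks:
        raise ValueError("no peaks found in the profile")
    peaks.sort(key=lambda i: g[i], reverse=True)
    chosen = [peaks[0]]
    for i in peaks[1:]:
        if abs(i - chosen[0]) >= min_separation_bins:
            chosen.append(i)
            break
    top = sorted(chosen)
    r_inner = float(profile.bin_centers[top[0]])
    r_outer = float(profile.bin_centers[top[-1]])
    return r_inner, r_outer, r_outer - r_inner


# ---------------------------------------------------------------------------
# lateral diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    """Lateral diffusion coefficient from an MSD fit."""

    D_cm2_s: float
    times_ps: np.ndarray
    msd_nm2: np.ndarray
    fit_window_ps: tuple[float, float]
    dimensionality: int = 2


NM2_PER_PS_TO_CM2_PER_S = 1.0e-2


def lateral_diffusion(
    frames: Sequence[Frame],
    selection: np.ndarray,
    fit_window: tuple[float, float] | None = None,
    dims: Sequence[int] = (0, 1),
) -> DiffusionResult:
    """Lateral diffusion coefficient from the 2-D mean-squared displacement.

    The MSD is averaged over the selected particles and all time origins;
    D is the least-squares slope of MSD(t) over the fit window divided by
    2 x dimensionality (MSD = 4 D t in 2-D). Times are read from the
    frames (ps); D is reported in cm^2 s^-1.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    selection = np.asarray(selection, dtype=bool)
    pos = np.stack([f.positions[selection][:, list(dims)] for f in frames])  # (T, N, d)
    times = np.array([f.time for f in frames])
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("frames must be evenly spaced in time")
    T = len(frames)
    lags = np.arange(1, T)
    msd = np.empty(T - 1)
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[k] = float(np.mean(np.sum(d * d, axis=-1)))
    lag_times = lags * dt[0]
    if fit_window is None:
        fit_window = (float(lag_times[0]), float(lag_times[(T - 1) // 2]))
    lo, hi = fit_window
    sel = (lag_times >= lo) & (lag_times <= hi)
    if not sel.any():
        raise ValueError(f"fit window {fit_window} outside trajectory span")
    slope, _ = np.polyfit(lag_times[sel], msd[sel], 1)
    ndim = len(dims)
    D = max(slope, 0.0) / (2.0 * ndim) * NM2_PER_PS_TO_CM2_PER_S
    return DiffusionResult(
        D_cm2_s=float(D),
        times_ps=lag_times,
        msd_nm2=msd,
        fit_window_ps=(float(lo), float(hi)),
        dimensionality=ndim,
    )


# ---------------------------------------------------------------------------
# contacts and aligned densities
# ---------------------------------------------------------------------------

@dataclass
class ContactTable:
    """Relative contact frequency of a ligand species with protein residues."""

    residues: np.ndarray
    frequency: np.ndarray  # in [0, 1], one per residue
    cutoff: float
    per_molecule: dict[int, np.ndarray] = field(default_factory=dict)  # (n_res, n_frames)

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(f) for r, f in zip(self.residues, self.frequency)}


def contact_frequency(
    system: ParticleSystem,
    frames: Sequence[Frame],
    ligand_species: str = "PIP2",
    residue_range: tuple[int, int] = (245, 270),
    cutoff: float = 0.6,
) -> ContactTable:
    """Per-residue contact frequency of a lipid ligand with a protein.

    A residue is in contact in a frame when any bead of any ligand
    molecule lies within the cutoff of any bead of that residue. The
    frequency is the fraction of frames with a contact; per-ligand
    contact traces are retained for occupancy timelines.
    """
    lig_mask = system.species == ligand_species
    if not lig_mask.any():
        raise ValueError(f"no {ligand_species} molecules in system")
    lipidlike = _lipid_molecule_mask(system) | np.isin(system.species, ["W", "NA"])
    lo, hi = residue_range
    residues = np.arange(lo, hi + 1)
    res_masks = []
    for rid in residues:
        m = (~lipidlike) & (system.residue_id == rid)
        res_masks.append(m)
    if not any(m.any() for m in res_masks):
        raise ValueError(f"residue range {residue_range} absent from the protein")
    lig_mids = np.unique(system.molecule_id[lig_mask])
    n_frames = len(frames)
    per_mol = {int(m): np.zeros((len(residues), n_frames), dtype=bool) for m in lig_mids}
    any_contact = np.zeros((len(residues), n_frames), dtype=bool)
    for t, fr in enumerate(frames):
        pos = fr.positions
        trees = {
            int(m): cKDTree(pos[lig_mask & (system.molecule_id == m)]) for m in lig_mids
        }
        for k, m in enumerate(res_masks):
            if not m.any():
                continue
            rp = pos[m]
            for mid, tree in trees.items():
                d, _ = tree.query(rp, k=1)
                if (d <= cutoff).any():
                    per_mol[mid][k, t] = True
                    any_contact[k, t] = True
    freq = any_contact.mean(axis=1)
    return ContactTable(
        residues=residues, frequency=freq, cutoff=cutoff, per_molecule=per_mol
    )


def aligned_density(
    system: ParticleSystem,
    frames: Sequence[Frame],
    reference: np.ndarray,
    target: np.ndarray,
    grid_spacing: float = 0.3,
    extent: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """3-D occupancy map of target beads after rigid alignment on a reference.

    Each frame is least-squares superposed (rotation + translation of the
    reference selection onto its first-frame geometry) before the target
    bead positions are accumulated on a regular grid centered on the
    reference centroid. Returns (edges, counts) with edges shared by all
    three axes.
    """
    from scipy.spatial.transform import Rotation

    reference = np.asarray(reference, dtype=bool)
    target = np.asarray(target, dtype=bool)
    if not reference.any() or not target.any():
        raise ValueError("reference and target selections must be nonempty")
    ref0 = frames[0].positions[reference]
    c0 = ref0.mean(axis=0)
    if extent is None:
        extent = float(system.box.max()) / 2.0
    edges = np.arange(-extent, extent + grid_spacing, grid_spacing)
    counts = np.zeros((len(edges) - 1,) * 3)
    for fr in frames:
        ref = fr.positions[reference]
        c = ref.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref0 - c0, ref - c)
        moved = rot.apply(fr.positions[target] - c)
        h, _ = np.histogramdd(moved, bins=(edges, edges, edges))
        counts += h
    return edges, counts
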