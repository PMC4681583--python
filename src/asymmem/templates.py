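"""Coarse-grained lipid templates.

Each supported species ships with a bead list (name, MARTINI-style bead
type, charge), a bonded topology, and an idealized internal geometry used
only for initial packing: beads are laid out head-down along a canonical
molecular axis (-z) with ~0.47 nm spacing, the standard CG bond length.
The head reference bead (PO4 for phospholipids, ROH for cholesterol) sits
at the origin of the internal frame.

Charges follow common CG conventions: POPS carries -1 (serine phosphate),
PIP2 carries -5 (phosphate plus two doubly charged ring phosphates), the
zwitterionic lipids and cholesterol are net neutral, water is neutral and
NA is +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LipidTemplate",
    "UnsupportedSpeciesError",
    "load_lipid_template",
    "supported_species",
    "register_template",
    "template_to_text",
    "templates_from_text",
    "write_species_file",
    "read_species_file",
]

BOND_LENGTH = 0.47  # nm, canonical CG bead spacing
TAIL_OFFSET = 0.11  # nm, lateral half-separation of the two acyl tails


class UnsupportedSpeciesError(KeyError):
    """Raised when a species name has no registered template."""

    def __init__(self, species: str, known: Sequence[str]):
        super().__init__(species)
        self.species = species
        self.known = sorted(known)

    def __str__(self) -> str:  # pragma: no cover - trivial formatting
        return (
            f"unsupported species {self.species!r}; "
            f"supported species are: {', '.join(self.known)}"
        )


@dataclass(eq=False)
class LipidTemplate:
    """Per-species bead decomposition and idealized internal geometry."""

    species: str
    beads: tuple[tuple[str, str, float], ...]  # (bead_name, bead_type, charge)
    bonds: tuple[tuple[int, int], ...]
    head_bead: str
    tail_beads: tuple[str, ...]
    internal_coords: np.ndarray = field(repr=False)  # (n_beads, 3), nm

    def __post_init__(self) -> None:
        self.beads = tuple((str(n), str(t), float(q)) for n, t, q in self.beads)
        self.bonds = tuple((int(i), int(j)) for i, j in self.bonds)
        self.tail_beads = tuple(self.tail_beads)
        self.internal_coords = np.asarray(self.internal_coords, dtype=float)
        names = self.bead_names
        if len(set(names)) != len(names):
            raise ValueError(f"{self.species}: bead names must be unique")
        if self.head_bead not in names:
            raise ValueError(f"{self.species}: head bead {self.head_bead} not in beads")
        for tb in self.tail_beads:
            if tb not in names:
                raise ValueError(f"{self.species}: tail bead {tb} not in beads")
        n = len(names)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"{self.species}: invalid bond ({i}, {j})")
        if self.internal_coords.shape != (n, 3):
            raise ValueError(f"{self.species}: internal_coords must be ({n}, 3)")
        if not np.isclose(round(self.net_charge), self.net_charge):
            raise ValueError(f"{self.species}: net charge must be an integer")
        head = self.internal_coords[self.head_index]
        if not np.allclose(head, 0.0):
            raise ValueError(f"{self.species}: head bead must sit at the origin")

    @property
    def bead_names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.beads)

    @property
    def bead_types(self) -> tuple[str, ...]:
        return tuple(b[1] for b in self.beads)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b[2] for b in self.beads], dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def head_index(self) -> int:
        return self.bead_names.index(self.head_bead)

    @property
    def tail_indices(self) -> tuple[int, ...]:
        names = self.bead_names
        return tuple(names.index(t) for t in self.tail_beads)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from head toward the tail centroid (the packing axis)."""
        if not self.tail_beads:
            return np.array([0.0, 0.0, -1.0])
        v = self.internal_coords[list(self.tail_indices)].mean(axis=0)
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([0.0, 0.0, -1.0])

    @property
    def radius(self) -> float:
        """Maximum bead distance from the head bead, nm."""
        return float(np.linalg.norm(self.internal_coords, axis=1).max())


def _chain(x: float, z0: float, n: int) -> list[tuple[float, float, float]]:
    return [(x, 0.0, z0 - k * BOND_LENGTH) for k in range(n)]


def _glycerolipid(
    species: str,
    head: Sequence[tuple[str, str, float]],
    tail_a: Sequence[str],
    tail_b: Sequence[str],
    linker: tuple[str, str] = ("GL1", "GL2"),
) -> LipidTemplate:
    """Two-tailed lipid: head stack above PO4, two tails below the linkers."""
    beads: list[tuple[str, str, float]] = []
    coords: list[tuple[float, float, float]] = []
    # head-group beads stacked on +z above the PO4 reference bead
    for k, (name, btype, q) in enumerate(head):
        beads.append((name, btype, q))
        coords.append((0.0, 0.0, BOND_LENGTH * (len(head) - k)))
    i_po4 = len(beads)
    beads.append(("PO4", "Qa", -1.0))
    coords.append((0.0, 0.0, 0.0))
    i_gl1 = len(beads)
    beads.append((linker[0], "Na", 0.0))
    coords.append((-TAIL_OFFSET, 0.0, -BOND_LENGTH))
    i_gl2 = len(beads)
    beads.append((linker[1], "Na", 0.0))
    coords.append((TAIL_OFFSET, 0.0, -BOND_LENGTH))
    a0 = len(beads)
    for name, (x, y, z) in zip(tail_a, _chain(-TAIL_OFFSET, -2 * BOND_LENGTH, len(tail_a))):
        btype = "C3" if name.startswith("D") else "C1"
        beads.append((name, btype, 0.0))
        coords.append((x, y, z))
    b0 = len(beads)
    for name, (x, y, z) in zip(tail_b, _chain(TAIL_OFFSET, -2 * BOND_LENGTH, len(tail_b))):
        btype = "C3" if name.startswith("D") else "C1"
        beads.append((name, btype, 0.0))
        coords.append((x, y, z))
    bonds: list[tuple[int, int]] = []
    for k in range(len(head) - 1):
        bonds.append((k, k + 1))
    if head:
        bonds.append((len(head) - 1, i_po4))
    bonds += [(i_po4, i_gl1), (i_gl1, i_gl2)]
    bonds.append((i_gl1, a0))
    bonds += [(a0 + k, a0 + k + 1) for k in range(len(tail_a) - 1)]
    bonds.append((i_gl2, b0))
    bonds += [(b0 + k, b0 + k + 1) for k in range(len(tail_b) - 1)]
    return LipidTemplate(
        species=species,
        beads=tuple(beads),
        bonds=tuple(bonds),
        head_bead="PO4",
        tail_beads=(tail_a[-1], tail_b[-1]),
        internal_coords=np.array(coords),
    )


def _cholesterol() -> LipidTemplate:
    beads = (
        ("ROH", "SP1", 0.0),
        ("R1", "SC1", 0.0),
        ("R2", "SC3", 0.0),
        ("R3", "SC1", 0.0),
        ("R4", "SC1", 0.0),
        ("R5", "SC1", 0.0),
        ("C1", "C1", 0.0),
        ("C2", "C1", 0.0),
    )
    coords = np.array(
        [
            (0.0, 0.0, 0.0),
            (0.0, 0.0, -0.35),
            (0.22, 0.0, -0.45),
            (0.0, 0.0, -0.70),
            (0.22, 0.0, -0.80),
            (0.0, 0.0, -1.05),
            (0.0, 0.0, -1.45),
            (0.0, 0.0, -1.92),
        ]
    )
    bonds = ((0, 1), (1, 2), (1, 3), (2, 4), (3, 4), (3, 5), (4, 5), (5, 6), (6, 7))
    return LipidTemplate("CHOL", beads, bonds, "ROH", ("C2",), coords)


def _single_bead(species: str, bead: str, btype: str, charge: float) -> LipidTemplate:
    return LipidTemplate(
        species=species,
        beads=((bead, btype, charge),),
        bonds=(),
        head_bead=bead,
        tail_beads=(),
        internal_coords=np.zeros((1, 3)),
    )


def _builtin_templates() -> dict[str, LipidTemplate]:
    t: dict[str, LipidTemplate] = {}
    t["POPC"] = _glycerolipid(
        "POPC",
        head=[("NC3", "Q0", 1.0)],
        tail_a=["C1A", "D2A", "C3A", "C4A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
    )
    t["POPE"] = _glycerolipid(
        "POPE",
        head=[("NH3", "Qd", 1.0)],
        tail_a=["C1A", "D2A", "C3A", "C4A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
    )
    t["POPS"] = _glycerolipid(
        "POPS",
        head=[("CNO", "P5", 0.0)],
        tail_a=["C1A", "D2A", "C3A", "C4A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
    )
    t["DPPC"] = _glycerolipid(
        "DPPC",
        head=[("NC3", "Q0", 1.0)],
        tail_a=["C1A", "C2A", "C3A", "C4A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
    )
    t["PPCS"] = _glycerolipid(
        "PPCS",
        head=[("NC3", "Q0", 1.0)],
        tail_a=["T1A", "C2A", "C3A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
        linker=("AM1", "AM2"),
    )
    t["PIP2"] = _glycerolipid(
        "PIP2",
        head=[("P1", "Qa", -2.0), ("P2", "Qa", -2.0)],
        tail_a=["C1A", "D2A", "C3A", "C4A"],
        tail_b=["C1B", "C2B", "C3B", "C4B"],
    )
    t["CHOL"] = _cholesterol()
    t["W"] = _single_bead("W", "W", "P4", 0.0)
    t["NA"] = _single_bead("NA", "NA", "Qd", 1.0)
    return t


_REGISTRY: dict[str, LipidTemplate] = _builtin_templates()


def supported_species() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def load_lipid_template(species: str) -> LipidTemplate:
    """Return the registered template for ``species``.

    Raises
    ------
    UnsupportedSpeciesError
        If the species has no registered template; the message lists the
        supported names.
    """
    try:
        return _REGISTRY[species]
    except KeyError:
        raise UnsupportedSpeciesError(species, supported_species()) from None


def register_template(template: LipidTemplate, overwrite: bool = False) -> None:
    """Register a user-defined species template."""
    if template.species in _REGISTRY and not overwrite:
        raise ValueError(f"species {template.species!r} already registered")
    _REGISTRY[template.species] = template


# ---------------------------------------------------------------------------
# plain-text species definition format
#
#   [species NAME]
#   bead <name> <type> <charge> <x> <y> <z>     (one per bead, nm)
#   bond <i> <j>                                 (0-based bead indices)
#   head <bead name>
#   tails <bead name> [<bead name> ...]
# ---------------------------------------------------------------------------

def template_to_text(template: LipidTemplate) -> str:
    lines = [f"[species {template.species}]"]
    for (name, btype, q), (x, y, z) in zip(template.beads, template.internal_coords):
        lines.append(f"bead {name} {btype} {q:.4f} {x:.4f} {y:.4f} {z:.4f}")
    for i, j in template.bonds:
        lines.append(f"bond {i} {j}")
    lines.append(f"head {template.head_bead}")
    if template.tail_beads:
        lines.append("tails " + " ".join(template.tail_beads))
    return "\n".join(lines) + "\n"


def templates_from_text(text: str) -> list[LipidTemplate]:
    blocks: list[dict] = []
    cur: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[species"):
            name = line.strip("[]").split(None, 1)[1].strip()
            cur = {"species": name, "beads": [], "coords": [], "bonds": [], "tails": []}
            blocks.append(cur)
            continue
        if cur is None:
            raise ValueError(f"line {lineno}: content before any [species] header")
        key, *rest = line.split()
        if key == "bead":
            name, btype, q, x, y, z = rest
            cur["beads"].append((name, btype, float(q)))
            cur["coords"].append((float(x), float(y), float(z)))
        elif key == "bond":
            cur["bonds"].append((int(rest[0]), int(rest[1])))
        elif key == "head":
            cur["head"] = rest[0]
        elif key == "tails":
            cur["tails"] = list(rest)
        else:
            raise ValueError(f"line {lineno}: unknown directive {key!r}")
    out = []
    for b in blocks:
        out.append(
            LipidTemplate(
                species=b["species"],
                beads=tuple(b["beads"]),
                bonds=tuple(b["bonds"]),
                head_bead=b["head"],
                tail_beads=tuple(b["tails"]),
                internal_coords=np.array(b["coords"]),
            )
        )
    return out


def write_species_file(templates: Iterable[LipidTemplate], path) -> None:
    with open(path, "w") as fh:
        for t in templates:
            fh.write(template_to_text(t))
            fh.write("\n")


def read_species_file(path, register: bool = False) -> list[LipidTemplate]:
    with open(path) as fh:
        templates = templates_from_text(fh.read())
    if register:
        for t in templates:
            register_template(t, overwrite=True)
    return templates
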