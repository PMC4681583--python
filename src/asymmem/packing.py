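"""Seeded rejection packing with cell-list clash detection.

The builders place whole template molecules one at a time: draw a position
and a uniform random orientation, reject the draw if any bead leaves the
allowed region or comes closer than the clash cutoff to a bead of a
previously accepted molecule, and retry up to a bounded number of times.
A uniform-occupancy cell list keeps the clash test O(1) per bead.
"""

from __future__ import annotations

import zlib
from collections import defaultdict

import numpy as np

__all__ = ["PackingError", "CellList", "random_rotation_matrix", "spawn_seed"]


class PackingError(RuntimeError):
    """Packing could not satisfy the clash constraint within the retry budget."""


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed (< 2**31) from a global seed."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode()) & 0x7FFFFFFF]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class CellList:
    """Point container answering "any stored point within cutoff?" queries."""

    def __init__(self, cutoff: float):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.cutoff = float(cutoff)
        self._cells: dict[tuple[int, int, int], list[np.ndarray]] = defaultdict(list)

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        c = np.floor(p / self.cutoff).astype(int)
        return (int(c[0]), int(c[1]), int(c[2]))

    def add(self, points: np.ndarray) -> None:
        for p in np.atleast_2d(points):
            self._cells[self._key(p)].append(p)

    def any_within_cutoff(self, points: np.ndarray) -> bool:
        cut2 = self.cutoff * self.cutoff
        for p in np.atleast_2d(points):
            kx, ky, kz = self._key(p)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for q in self._cells.get((kx + dx, ky + dy, kz + dz), ()):
                            d = p - q
                            if d @ d < cut2:
                                return True
        return False
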