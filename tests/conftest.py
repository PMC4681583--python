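import numpy as np
import pytest

from asymmem.fixtures import ideal_bilayer, ideal_vesicle
from asymmem.planar import SlabSpec, pack_box


@pytest.fixture(scope="session")
def small_bilayer():
    """100+100-lipid lattice bilayer with known leaflet ground truth."""
    system, truth = ideal_bilayer(
        {"POPC": 90, "PPCS": 10}, {"POPE": 70, "POPS": 30}, seed=11
    )
    return system, truth


@pytest.fixture(scope="session")
def small_vesicle():
    """Idealized vesicle with head shells at 15.6 / 20.0 nm."""
    system, truth = ideal_vesicle(
        {"POPC": 800, "PPCS": 200}, {"POPE": 900, "POPS": 300},
        r_inner=15.6, r_outer=20.0, seed=13,
    )
    return system, truth


@pytest.fixture(scope="session")
def tiny_packed_box():
    """10-lipid random packing, small enough for O(N^2) oracles."""
    spec = SlabSpec((6.0, 6.0, 6.0), {"POPC": 6, "CHOL": 4}, seed=5)
    return pack_box(spec), spec


def brute_force_min_intermolecular_distance(system):
    """O(N^2) oracle: minimum bead distance between different molecules."""
    best = np.inf
    pos = system.positions
    mid = system.molecule_id
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if mid[i] == mid[j]:
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            best = min(best, d)
    return best
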