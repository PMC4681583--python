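import numpy as np
import pytest

from asymmem.packing import PackingError
from asymmem.planar import (
    GeometryError,
    SlabSpec,
    SolvationError,
    StackSpec,
    build_planar,
    neutralize,
    pack_box,
    place_protein_planar,
    solvate,
    stack_boxes,
    substitute_species,
)
from asymmem.fixtures import helix_protein
from asymmem.system import net_charge
from conftest import brute_force_min_intermolecular_distance

CP_COMPOSITION = {"POPS": 63, "POPE": 210, "CHOL": 256}
IV_COMPOSITION = {"PPCS": 36, "POPC": 180, "CHOL": 144}


class TestPackBox:
    def test_cp_slab_counts_and_bounds(self):
        system = pack_box(SlabSpec((16, 16, 5), CP_COMPOSITION, seed=1))
        assert system.n_molecules == 529
        assert system.species_counts() == CP_COMPOSITION
        assert (system.positions > 0).all()
        assert (system.positions < np.array([16, 16, 5])).all()

    def test_empty_composition_gives_empty_system(self):
        system = pack_box(SlabSpec((5, 5, 5), {}, seed=0))
        assert system.n_atoms == 0

    def test_clash_constraint_verified_by_brute_force(self, tiny_packed_box):
        system, spec = tiny_packed_box
        dmin = brute_force_min_intermolecular_distance(system)
        assert dmin >= spec.clash_cutoff

    def test_determinism_per_seed(self):
        spec = SlabSpec((8, 8, 5), {"POPC": 20, "CHOL": 10}, seed=42)
        a = pack_box(spec)
        b = pack_box(spec)
        assert np.array_equal(a.positions, b.positions)
        c = pack_box(SlabSpec((8, 8, 5), {"POPC": 20, "CHOL": 10}, seed=43))
        assert not np.array_equal(a.positions, c.positions)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            pack_box(SlabSpec((2, 2, 2), {"POPC": 500}, seed=0))


class TestStackBoxes:
    def test_overlap_arithmetic(self):
        lower = pack_box(SlabSpec((8, 8, 5), {"POPC": 10}, seed=1))
        upper = pack_box(SlabSpec((8, 8, 5), {"POPE": 10}, seed=2))
        for overlap, expected_extent in ((0.0, 10.0), (0.5, 9.5)):
            merged = stack_boxes(lower, upper, StackSpec(overlap, (8, 8, 13)))
            # combined lipid z-extent shrinks by the overlap
            extent = merged.positions[:, 2].max() - merged.positions[:, 2].min()
            span_lower = lower.positions[:, 2].max() - lower.positions[:, 2].min()
            span_upper = upper.positions[:, 2].max() - upper.positions[:, 2].min()
            # the shift of the upper center of mass is (height - overlap)
            com_shift = (
                merged.positions[lower.n_atoms:, 2].mean()
                - merged.positions[: lower.n_atoms, 2].mean()
            ) - (upper.positions[:, 2].mean() - lower.positions[:, 2].mean())
            assert com_shift == pytest.approx(5.0 - overlap, abs=1e-9)
            assert extent <= expected_extent
        assert merged.n_molecules == 20

    def test_mismatched_lateral_dims_rejected(self):
        lower = pack_box(SlabSpec((8, 8, 5), {"POPC": 5}, seed=1))
        upper = pack_box(SlabSpec((6, 6, 5), {"POPE": 5}, seed=2))
        with pytest.raises(GeometryError):
            stack_boxes(lower, upper, StackSpec(0.5, (8, 8, 13)))

    def test_merged_centered_in_box(self):
        lower = pack_box(SlabSpec((8, 8, 5), {"POPC": 10}, seed=1))
        upper = pack_box(SlabSpec((8, 8, 5), {"POPE": 10}, seed=2))
        merged = stack_boxes(lower, upper, StackSpec(0.5, (8, 8, 13)))
        lo, hi = merged.positions[:, 2].min(), merged.positions[:, 2].max()
        assert lo + hi == pytest.approx(13.0, abs=1e-9)


class TestSubstituteSpecies:
    def test_counts_after_substitution(self):
        system = pack_box(SlabSpec((12, 12, 5), {"POPC": 180, "CHOL": 20}, seed=3))
        swapped = substitute_species(system, "POPC", "PIP2", 16, seed=9)
        counts = swapped.species_counts()
        assert counts == {"POPC": 164, "PIP2": 16, "CHOL": 20}

    def test_zero_substitution_is_identity(self):
        system = pack_box(SlabSpec((8, 8, 5), {"POPC": 10}, seed=3))
        same = substitute_species(system, "POPC", "PIP2", 0, seed=9)
        assert np.array_equal(same.positions, system.positions)
        assert (same.species == system.species).all()

    def test_charge_ledger_delta(self):
        system = pack_box(SlabSpec((12, 12, 5), {"POPC": 50}, seed=3))
        before = net_charge(system).system_charge
        swapped = substitute_species(system, "POPC", "PIP2", 4, seed=9)
        after = net_charge(swapped).system_charge
        assert after - before == 4 * (-5 - 0)

    def test_head_bead_anchored(self):
        system = pack_box(SlabSpec((10, 10, 5), {"POPC": 5}, seed=4))
        swapped = substitute_species(system, "POPC", "PIP2", 5, seed=1)
        old_heads = system.positions[system.bead_name == "PO4"]
        new_heads = swapped.positions[swapped.bead_name == "PO4"]
        assert np.allclose(np.sort(old_heads, axis=0), np.sort(new_heads, axis=0))

    def test_insufficient_source_molecules(self):
        system = pack_box(SlabSpec((8, 8, 5), {"POPC": 3}, seed=3))
        with pytest.raises(ValueError, match="only 3"):
            substitute_species(system, "POPC", "PIP2", 5)


class TestPlaceProtein:
    @pytest.fixture()
    def stacked(self):
        lower = pack_box(SlabSpec((10, 10, 5), {"PPCS": 10, "POPC": 40}, seed=1))
        upper = pack_box(SlabSpec((10, 10, 5), {"POPS": 15, "POPE": 35}, seed=2))
        return stack_boxes(lower, upper, StackSpec(0.5, (10, 10, 13)))

    def test_c_term_lands_in_requested_slab(self, stacked):
        helix = helix_protein(n_residues=30)
        merged, report = place_protein_planar(stacked, helix, c_term_toward="IV")
        iv_mask = np.isin(merged.species, ["PPCS", "POPC"])
        z_lo = merged.positions[iv_mask, 2].min()
        z_hi = merged.positions[iv_mask, 2].max()
        c_bead = merged.positions[merged.residue_id == 30][-1]
        assert z_lo <= c_bead[2] <= z_hi

    def test_removed_set_matches_brute_force(self, stacked):
        helix = helix_protein(n_residues=30)
        merged, report = place_protein_planar(stacked, helix, c_term_toward="IV")
        prot_pos = merged.positions[merged.species == "PROT"]
        # brute force on the original stacked system against placed protein
        removed = set()
        for mid in stacked.molecule_ids():
            mol = stacked.positions[stacked.molecule_id == mid]
            d = np.linalg.norm(mol[:, None, :] - prot_pos[None, :, :], axis=-1)
            if (d < 0.3).any():
                removed.add(int(mid))
        assert removed == set(report.removed_molecule_ids.tolist())
        assert merged.n_molecules == stacked.n_molecules - len(removed) + 1

    def test_no_clash_leaves_counts_unchanged(self, stacked):
        helix = helix_protein(n_residues=5)
        far = helix.with_positions(helix.positions)  # tiny helix near box center
        merged, report = place_protein_planar(stacked, far, c_term_toward="IV",
                                              clash_cutoff=1e-6)
        assert report.n_removed == 0
        assert merged.n_molecules == stacked.n_molecules + 1

    def test_protein_taller_than_box_rejected(self, stacked):
        tall = helix_protein(n_residues=60)  # 60 x 0.35 nm = 21 nm > 13 nm
        with pytest.raises(GeometryError):
            place_protein_planar(stacked, tall, c_term_toward="IV")


class TestSolvateNeutralize:
    def test_fully_excluded_box_gets_no_water(self):
        system = pack_box(SlabSpec((4, 4, 4), {"POPC": 5}, seed=1))
        out = solvate(system, water_spacing=0.47, exclusion=10.0)
        assert "W" not in out.species_counts()

    def test_exclusion_verified_by_brute_force(self):
        system = pack_box(SlabSpec((5, 5, 5), {"POPC": 8}, seed=2))
        out = solvate(system, exclusion=0.5, seed=3)
        lipid = np.isin(out.species, ["POPC"])
        water = out.species == "W"
        d = np.linalg.norm(
            out.positions[water][:, None, :] - out.positions[lipid][None, :, :], axis=-1
        )
        assert d.min() > 0.5

    def test_neutralize_adds_expected_cations(self):
        system = pack_box(SlabSpec((10, 10, 5), {"POPS": 63, "POPE": 30}, seed=4))
        out = neutralize(solvate(system, seed=1), seed=2)
        counts = out.species_counts()
        assert counts["NA"] == 63
        assert net_charge(out).system_charge == 0

    def test_neutralize_without_enough_water_raises(self):
        system = pack_box(SlabSpec((6, 6, 4), {"POPS": 20}, seed=4))
        with pytest.raises(SolvationError):
            neutralize(system)  # no waters at all


class TestBuildPlanar:
    def test_initial_asymmetry_is_exact(self):
        result = build_planar(IV_COMPOSITION, CP_COMPOSITION, seed=7, solvate_box=False)
        share = result.iv_share()
        assert share["PPCS"] == 100.0
        assert share["POPC"] == 100.0
        assert share["POPS"] == 0.0
        assert share["POPE"] == 0.0
        assert share["CHOL"] == pytest.approx(36.0)

    def test_determinism_end_to_end(self):
        a = build_planar({"POPC": 10}, {"POPE": 12}, slab_dims=(6, 6, 5),
                         merged_dims=(6, 6, 13), seed=5)
        b = build_planar({"POPC": 10}, {"POPE": 12}, slab_dims=(6, 6, 5),
                         merged_dims=(6, 6, 13), seed=5)
        assert np.array_equal(a.system.positions, b.system.positions)
        assert (a.system.species == b.system.species).all()

    def test_pip2_fraction_substitution(self):
        result = build_planar(
            {"POPC": 60, "PPCS": 10}, {"POPS": 20, "POPE": 80}, slab_dims=(10, 10, 5),
            merged_dims=(10, 10, 13), seed=2, pip2_frac=0.03, solvate_box=False,
        )
        counts = result.system.species_counts()
        # 3% of the 100 CP phospholipids, substituted from the POPC pool
        assert counts["PIP2"] == 3
        assert counts["POPC"] == 57
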