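"""fnat, i-rmsd, CAPRI classification and success-rate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclopep.assess import (CLUSTER_N, SINGLE_N, CapriClass, QualityRecord,
                             capri_classify, capri_classify_irmsd,
                             cluster_success, fnat, i_rmsd, native_contacts,
                             peptide_rmsd, single_structure_success)
from cyclopep.core import CyclopepError
from cyclopep.fixtures import make_quality_table, make_toy_complex
from cyclopep.geometry import rotate_about_axis


@pytest.fixture(scope="module")
def toy():
    return make_toy_complex(seed=0, n_native_contacts=4)


class TestFnat:
    def test_reference_against_itself_is_one(self, toy):
        ref = (toy.receptor, toy.peptide)
        assert fnat(ref, ref) == 1.0

    def test_displaced_peptide_scores_zero(self, toy):
        far = toy.peptide.with_coords(toy.peptide.coords + 50.0)
        assert fnat((toy.receptor, far), (toy.receptor, toy.peptide)) == 0.0

    def test_three_of_four_contacts(self, toy):
        pert = toy.perturbed(break_contacts=1)
        ref = (toy.receptor, toy.peptide)
        assert fnat((pert.receptor, pert.peptide), ref) == 0.75

    def test_matches_brute_force_contact_enumeration(self, toy):
        pert = toy.perturbed(break_contacts=2, seed=3)
        ref_pairs = set()
        for i in range(toy.receptor.n_atoms):
            for j in range(toy.peptide.n_atoms):
                if np.linalg.norm(toy.receptor.coords[i]
                                  - toy.peptide.coords[j]) <= 5.0:
                    ref_pairs.add((int(toy.receptor.resid[i]),
                                   int(toy.peptide.resid[j])))
        mod_pairs = set()
        for i in range(pert.receptor.n_atoms):
            for j in range(pert.peptide.n_atoms):
                if np.linalg.norm(pert.receptor.coords[i]
                                  - pert.peptide.coords[j]) <= 5.0:
                    mod_pairs.add((int(pert.receptor.resid[i]),
                                   int(pert.peptide.resid[j])))
        expected = len(ref_pairs & mod_pairs) / len(ref_pairs)
        got = fnat((pert.receptor, pert.peptide), (toy.receptor, toy.peptide))
        assert got == pytest.approx(expected)

    def test_rigid_transform_invariance(self, toy):
        ref = (toy.receptor, toy.peptide)
        rec = toy.receptor.with_coords(rotate_about_axis(
            toy.receptor.coords, np.zeros(3), np.array([1.0, 0.5, 0.2]), 40.0) + 3.0)
        pep = toy.peptide.with_coords(rotate_about_axis(
            toy.peptide.coords, np.zeros(3), np.array([1.0, 0.5, 0.2]), 40.0) + 3.0)
        assert fnat((rec, pep), ref) == 1.0

    def test_contactless_reference_rejected(self, toy):
        far = toy.peptide.with_coords(toy.peptide.coords + 500.0)
        with pytest.raises(CyclopepError):
            fnat((toy.receptor, toy.peptide), (toy.receptor, far))


class TestInterfaceRmsd:
    def test_identity_is_zero(self, toy):
        ref = (toy.receptor, toy.peptide)
        assert i_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_whole_complex_transform_is_zero(self, toy):
        ref = (toy.receptor, toy.peptide)
        rec = toy.receptor.with_coords(rotate_about_axis(
            toy.receptor.coords, np.ones(3), np.array([0.0, 1.0, 1.0]), 85.0) - 4.0)
        pep = toy.peptide.with_coords(rotate_about_axis(
            toy.peptide.coords, np.ones(3), np.array([0.0, 1.0, 1.0]), 85.0) - 4.0)
        assert i_rmsd((rec, pep), ref) == pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_superposition(self, toy):
        ref = (toy.receptor, toy.peptide)
        rng = np.random.default_rng(4)
        pep = toy.peptide.with_coords(toy.peptide.coords
                                      + 0.5 * rng.standard_normal((toy.peptide.n_atoms, 3)))
        got = i_rmsd((toy.receptor, pep), ref)
        # oracle: brute-force quaternion-free Kabsch on the interface atoms
        from cyclopep.assess import _backbone_coords, _interface_resids
        r_res, p_res = _interface_resids(ref, 10.0)
        a = np.vstack([_backbone_coords(toy.receptor, r_res),
                       _backbone_coords(pep, p_res)])
        b = np.vstack([_backbone_coords(toy.receptor, r_res),
                       _backbone_coords(toy.peptide, p_res)])
        from cyclopep.geometry import rmsd_after_superposition
        assert got == pytest.approx(rmsd_after_superposition(a, b), abs=1e-9)

    def test_quality_degrades_monotonically_with_displacement(self, toy):
        ref = (toy.receptor, toy.peptide)
        fnats, irmsds = [], []
        for shift in (0.0, 1.0, 3.0, 10.0):
            pep = toy.peptide.with_coords(toy.peptide.coords
                                          + np.array([0.0, shift, 0.0]))
            fnats.append(fnat((toy.receptor, pep), ref))
            irmsds.append(i_rmsd((toy.receptor, pep), ref))
        assert fnats == sorted(fnats, reverse=True)
        assert irmsds == sorted(irmsds)


class TestPeptideRmsd:
    def test_identical_is_zero(self, toy):
        assert peptide_rmsd(toy.peptide, toy.peptide) == pytest.approx(0.0, abs=1e-9)

    def test_mask_excludes_perturbed_tail(self, toy):
        pep = toy.peptide.copy()
        tail = int(pep.resid.max())
        pep.coords[pep.resid == tail] += 8.0
        masked = peptide_rmsd(pep, toy.peptide, cyclic_region_only=True,
                              cyclic_region=(1, tail - 1))
        assert masked == pytest.approx(0.0, abs=1e-9)
        assert peptide_rmsd(pep, toy.peptide) > 0.0

    def test_empty_mask_rejected(self, toy):
        with pytest.raises(CyclopepError):
            peptide_rmsd(toy.peptide, toy.peptide, cyclic_region_only=True,
                         cyclic_region=(90, 99))


class TestCapriClassification:
    @pytest.mark.parametrize("f,expected", [
        (0.81, CapriClass.HIGH),
        (0.8, CapriClass.MEDIUM),
        (0.51, CapriClass.MEDIUM),
        (0.5, CapriClass.ACCEPTABLE),
        (0.21, CapriClass.ACCEPTABLE),
        (0.2, CapriClass.INCORRECT),
        (0.0, CapriClass.INCORRECT),
        (1.0, CapriClass.HIGH),
    ])
    def test_fnat_boundaries_are_strict(self, f, expected):
        assert capri_classify(f) is expected

    @pytest.mark.parametrize("v,expected", [
        (0.49, CapriClass.HIGH),
        (0.5, CapriClass.MEDIUM),
        (0.99, CapriClass.MEDIUM),
        (1.0, CapriClass.ACCEPTABLE),
        (1.99, CapriClass.ACCEPTABLE),
        (2.0, CapriClass.INCORRECT),
    ])
    def test_irmsd_boundaries_are_strict(self, v, expected):
        assert capri_classify_irmsd(v) is expected

    def test_out_of_range_fnat_rejected(self):
        with pytest.raises(CyclopepError):
            capri_classify(1.2)


def _record(name, rank, cls):
    f = {CapriClass.HIGH: 0.9, CapriClass.MEDIUM: 0.6,
         CapriClass.ACCEPTABLE: 0.3, CapriClass.INCORRECT: 0.1}[cls]
    return QualityRecord(model_id=f"{name}_{rank}", rank=rank, f_nat=f,
                         capri_class=cls)


class TestSingleStructureSuccess:
    def test_high_at_rank_one_everywhere_gives_100(self):
        table = {f"c{i}": [_record(f"c{i}", 1, CapriClass.HIGH)] for i in range(5)}
        curve = single_structure_success(table, SINGLE_N, CapriClass.MEDIUM)
        assert all(r == 100.0 for r in curve.rates)

    def test_worked_example_60_percent_at_top10(self):
        planted = {
            "complex_1": [(4, "medium")], "complex_2": [(4, "medium")],
            "complex_3": [(4, "medium")],
            "complex_4": [(10, "high")], "complex_5": [(10, "high")],
            "complex_6": [(10, "high")],
            "complex_7": [(11, "medium")],
            "complex_8": [(1, "acceptable")], "complex_9": [(1, "acceptable")],
        }
        table = make_quality_table(seed=0, n_complexes=10, planted=planted)
        curve = single_structure_success(table, SINGLE_N, CapriClass.MEDIUM)
        assert curve.rate_at(10) == 60.0

    def test_matches_brute_force_scan_on_random_tables(self):
        rng = np.random.default_rng(21)
        classes = list(CapriClass)
        table = {}
        for c in range(8):
            recs = [QualityRecord(f"c{c}_m{r}", r,
                                  [0.1, 0.3, 0.6, 0.9][cls], classes[cls])
                    for r, cls in enumerate(rng.integers(0, 4, size=25), start=1)]
            table[f"c{c}"] = recs
        for level in (CapriClass.ACCEPTABLE, CapriClass.MEDIUM, CapriClass.HIGH):
            curve = single_structure_success(table, (1, 5, 10, 20), level)
            for n, rate in zip(curve.n_values, curve.rates):
                hits = sum(
                    any(r.capri_class >= level for r in recs if r.rank <= n)
                    for recs in table.values())
                assert rate == pytest.approx(100.0 * hits / len(table))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from(list(CapriClass)), min_size=1,
                             max_size=30), min_size=1, max_size=8))
    def test_monotonicity_properties(self, planted_classes):
        table = {
            f"c{i}": [QualityRecord(f"c{i}_m{r}", r, 0.0 if cls is CapriClass.INCORRECT
                                    else {1: 0.3, 2: 0.6, 3: 0.9}[cls], cls)
                      for r, cls in enumerate(classes, start=1)]
            for i, classes in enumerate(planted_classes)}
        curves = {lvl: single_structure_success(table, (1, 5, 10, 20), lvl)
                  for lvl in (CapriClass.ACCEPTABLE, CapriClass.MEDIUM,
                              CapriClass.HIGH)}
        for curve in curves.values():
            assert list(curve.rates) == sorted(curve.rates)   # non-decreasing in N
        for n_idx in range(4):
            assert (curves[CapriClass.ACCEPTABLE].rates[n_idx]
                    >= curves[CapriClass.MEDIUM].rates[n_idx]
                    >= curves[CapriClass.HIGH].rates[n_idx])

    def test_empty_table_rejected(self):
        with pytest.raises(CyclopepError):
            single_structure_success({}, SINGLE_N, CapriClass.MEDIUM)


class TestClusterSuccess:
    def _clusters(self, placements):
        """placements: list of clusters, each a list of member classes."""
        return [[_record("c", m + 1, cls) for m, cls in enumerate(cluster)]
                for cluster in placements]

    def test_fifth_member_of_top_cluster_never_counts(self):
        inc = CapriClass.INCORRECT
        clusters = self._clusters([[inc, inc, inc, inc, CapriClass.MEDIUM]])
        table = {"c1": clusters}
        curve = cluster_success(table, CLUSTER_N, CapriClass.MEDIUM)
        assert all(r == 0.0 for r in curve.rates)

    def test_first_member_of_fourth_cluster_counts_only_at_n4(self):
        inc = CapriClass.INCORRECT
        clusters = self._clusters([[inc] * 4, [inc] * 4, [inc] * 4,
                                   [CapriClass.MEDIUM, inc, inc, inc]])
        curve = cluster_success({"c1": clusters}, CLUSTER_N, CapriClass.MEDIUM)
        assert curve.rates == (0.0, 0.0, 0.0, 100.0)

    def test_small_clusters_use_available_members(self):
        clusters = self._clusters([[CapriClass.MEDIUM]])
        curve = cluster_success({"c1": clusters}, CLUSTER_N, CapriClass.MEDIUM)
        assert curve.rate_at(1) == 100.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(31)
        classes = list(CapriClass)
        table = {}
        for c in range(6):
            clusters = [[_record(f"c{c}", m + 1, classes[k])
                         for m, k in enumerate(rng.integers(0, 4, size=6))]
                        for _ in range(5)]
            table[f"c{c}"] = clusters
        for level in (CapriClass.ACCEPTABLE, CapriClass.MEDIUM):
            curve = cluster_success(table, CLUSTER_N, level)
            for n, rate in zip(curve.n_values, curve.rates):
                hits = 0
                for clusters in table.values():
                    found = any(r.capri_class >= level
                                for cl in clusters[:n] for r in cl[:4])
                    hits += found
                assert rate == pytest.approx(100.0 * hits / len(table))
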