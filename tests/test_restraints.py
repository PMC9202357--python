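"""Restraint generation: cyclization values, AIRs, body restraints, tbl I/O."""

import numpy as np
import pytest

from cyclopep.builder import build_linear_peptide
from cyclopep.core import (AtomSelector, Conformation, CyclopepError,
                           DistanceRestraint, PeptideSpec, RestraintKind,
                           RestraintSet, concatenate)
from cyclopep.geometry import rotate_about_axis
from cyclopep.restraints import (ambiguous_interaction_restraints,
                                 backbone_cyclization_restraints, body_restraints,
                                 combined_cyclization_restraints, detect_bodies,
                                 disulfide_cyclization_restraints,
                                 interface_from_complex, parse_tbl, write_tbl)


def _by_atoms(rset):
    return {(r.sel_i.name, r.sel_j[0].name): r for r in rset}


class TestCyclizationRestraints:
    def test_backbone_values(self, gly6_spec):
        rset = backbone_cyclization_restraints(gly6_spec)
        assert len(rset) == 2
        pairs = _by_atoms(rset)
        assert pairs[("C", "N")].target == 1.3
        assert pairs[("O", "N")].target == 2.3
        assert all(r.lower == 0.1 and r.upper == 0.1 for r in rset)

    def test_backbone_restraints_link_last_to_first(self, gly6_spec):
        rset = backbone_cyclization_restraints(gly6_spec)
        assert all(r.sel_i.resid == 6 and r.sel_j[0].resid == 1 for r in rset)

    def test_disulfide_values(self, ss_spec):
        rset = disulfide_cyclization_restraints(ss_spec)
        assert len(rset) == 3
        pairs = _by_atoms(rset)
        assert pairs[("CA", "CA")].target == 4.0
        assert pairs[("CB", "CB")].target == 3.5
        assert pairs[("SG", "SG")].target == 2.0
        assert all(r.lower == 0.1 and r.upper == 0.1 for r in rset)

    def test_combined_is_union_minus_cb_cb(self, combined_spec):
        combined = combined_cyclization_restraints(combined_spec)
        assert len(combined) == 4
        bb = backbone_cyclization_restraints(combined_spec)
        ss = disulfide_cyclization_restraints(combined_spec)
        union = {(r.sel_i, r.sel_j, r.target) for r in list(bb) + list(ss)}
        kept = {(r.sel_i, r.sel_j, r.target) for r in combined}
        dropped = union - kept
        assert kept < union
        assert {r[0].name for r in dropped} == {"CB"}

    def test_capped_termini_rejected(self):
        spec = PeptideSpec("ACGCA", "disulfide", "ACE_NME", (2, 4))
        with pytest.raises(CyclopepError, match="head-to-tail"):
            backbone_cyclization_restraints(spec)


def _toy_pair():
    """3-residue receptor / 2-residue peptide with tabulated coordinates."""
    receptor = Conformation(
        resid=np.array([1, 1, 2, 2, 3, 3]),
        resname=np.array(["GLY"] * 6),
        atom_name=np.array(["CA", "C"] * 3),
        element=np.array(["C"] * 6),
        coords=np.array([[0, 0, 0], [1.5, 0, 0],
                         [8, 0, 0], [9.5, 0, 0],
                         [20, 0, 0], [21.5, 0, 0]], float))
    peptide = Conformation(
        resid=np.array([1, 2]),
        resname=np.array(["ALA", "ALA"]),
        atom_name=np.array(["CA", "CA"]),
        element=np.array(["C", "C"]),
        coords=np.array([[1.5, 4.0, 0], [9.5, 4.9, 0]], float))
    return receptor, peptide


class TestInterfaceExtraction:
    def test_far_peptide_gives_empty_interface(self):
        receptor, peptide = _toy_pair()
        far = peptide.with_coords(peptide.coords + 100.0)
        with pytest.warns(UserWarning):
            assert interface_from_complex(receptor, far) == []

    def test_cutoff_boundary(self):
        receptor, peptide = _toy_pair()
        near = peptide.with_coords(np.array([[0, 4.9, 0], [50, 0, 0]], float))
        assert interface_from_complex(receptor, near) == [1]
        out = peptide.with_coords(np.array([[0, 5.1, 0], [50, 0, 0]], float))
        with pytest.warns(UserWarning):
            assert interface_from_complex(receptor, out) == []

    def test_matches_all_pairs_scan(self):
        receptor, peptide = _toy_pair()
        expected = set()
        for i in range(receptor.n_atoms):
            for j in range(peptide.n_atoms):
                if np.linalg.norm(receptor.coords[i] - peptide.coords[j]) <= 5.0:
                    expected.add(int(receptor.resid[i]))
        assert interface_from_complex(receptor, peptide) == sorted(expected)

    def test_invariant_under_rigid_transform(self):
        receptor, peptide = _toy_pair()
        before = interface_from_complex(receptor, peptide)
        axis = np.array([1.0, 2.0, 0.5])
        origin = np.array([3.0, -1.0, 2.0])
        r2 = receptor.with_coords(
            rotate_about_axis(receptor.coords, origin, axis, 61.0) + 7.0)
        p2 = peptide.with_coords(
            rotate_about_axis(peptide.coords, origin, axis, 61.0) + 7.0)
        assert interface_from_complex(r2, p2) == before


class TestAmbiguousRestraints:
    def test_one_restraint_per_active_residue(self):
        rset = ambiguous_interaction_restraints(list(range(10, 17)),
                                                list(range(1, 10)))
        assert len(rset) == 7
        assert rset.kind is RestraintKind.AIR

    def test_air_target_and_corrections(self):
        rset = ambiguous_interaction_restraints([5], [1, 2])
        r = rset[0]
        assert (r.target, r.lower, r.upper) == (2.0, 2.0, 0.0)

    def test_empty_active_list_rejected(self):
        with pytest.raises(CyclopepError):
            ambiguous_interaction_restraints([], [1, 2])

    def test_each_restraint_enumerates_all_passive_residues(self):
        passive = list(range(1, 10))
        rset = ambiguous_interaction_restraints([42, 43], passive)
        text = write_tbl(rset)
        parsed = parse_tbl(text)
        for r in parsed:
            assert sorted(s.resid for s in r.sel_j) == passive
        # each AIR line block contains len(passive)-1 "or" separators
        assert text.count("or") == 2 * (len(passive) - 1)

    def test_effective_distance_bounded_by_minimum_pair(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            coords = rng.uniform(-5, 5, size=(6, 3))
            conf = Conformation(
                resid=np.array([1, 1, 2, 2, 3, 3]),
                resname=np.array(["GLY"] * 6),
                atom_name=np.array(["CA", "CB"] * 3),
                element=np.array(["C"] * 6),
                coords=coords)
            r = DistanceRestraint(AtomSelector(1, None), (AtomSelector(2, None),
                                                          AtomSelector(3, None)),
                                  target=2.0, lower=2.0, upper=0.0)
            deff = r.effective_distance(conf)
            dmin = min(np.linalg.norm(coords[i] - coords[j])
                       for i in (0, 1) for j in (2, 3, 4, 5))
            assert deff <= dmin + 1e-9


def _multibody(n_bodies):
    parts = []
    resid = 1
    for b in range(n_bodies):
        offset = np.array([b * 30.0, b * 5.0, 0.0])
        for k in range(2):
            parts.append(Conformation(
                resid=np.array([resid] * 3),
                resname=np.array(["GLY"] * 3),
                atom_name=np.array(["N", "CA", "C"]),
                element=np.array(["N", "C", "C"]),
                coords=offset + np.array([[0, 0, 0], [1.5, 0, 0], [2.5, 1, 0]])
                + np.array([k * 3.8, 0, 0])))
            resid += 1
        resid += 1      # numbering gap between bodies
    out = parts[0]
    for p in parts[1:]:
        out = concatenate(out, p)
    return out


class TestBodyRestraints:
    def test_single_continuous_chain_gives_no_restraints(self, gly6_starts):
        rset = body_restraints(gly6_starts[0])
        assert len(rset) == 0

    def test_two_body_targets_equal_measured_distances(self):
        structure = _multibody(2)
        rset = body_restraints(structure)
        assert len(rset) == 2
        for r in rset:
            i = structure.index_of(r.sel_i.resid, "CA")
            j = structure.index_of(r.sel_j[0].resid, "CA")
            measured = np.linalg.norm(structure.coords[i] - structure.coords[j])
            assert r.target == pytest.approx(measured, abs=1e-3)
            assert r.lower == 0.0 and r.upper == 0.0

    def test_three_bodies_form_connected_component(self):
        structure = _multibody(3)
        bodies = detect_bodies(structure)
        assert len(bodies) == 3
        rset = body_restraints(structure)
        # union-find over bodies using the emitted restraints
        body_of = {r: k for k, body in enumerate(bodies) for r in body}
        parent = list(range(len(bodies)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for r in rset:
            a, b = find(body_of[r.sel_i.resid]), find(body_of[r.sel_j[0].resid])
            parent[a] = b
        assert len({find(k) for k in range(len(bodies))}) == 1

    def test_too_small_structure_rejected(self):
        conf = Conformation(resid=np.array([1]), resname=np.array(["GLY"]),
                            atom_name=np.array(["CA"]), element=np.array(["C"]),
                            coords=np.zeros((1, 3)))
        with pytest.raises(CyclopepError):
            body_restraints(conf)


class TestTblSerialization:
    def test_backbone_line_contains_values(self, gly6_spec):
        text = write_tbl(backbone_cyclization_restraints(gly6_spec))
        assert "1.3 0.1 0.1" in text
        assert "2.3 0.1 0.1" in text

    def test_write_parse_write_is_byte_identical(self, combined_spec):
        rset = combined_cyclization_restraints(combined_spec)
        text = write_tbl(rset)
        again = write_tbl(parse_tbl(text, rset.kind))
        assert text == again

    def test_air_round_trip_byte_identical(self):
        rset = ambiguous_interaction_restraints([7, 9], [1, 2, 3])
        text = write_tbl(rset)
        assert write_tbl(parse_tbl(text)) == text

    def test_air_assign_count_equals_active_residues(self):
        rset = ambiguous_interaction_restraints(list(range(1, 8)), [10, 11])
        text = write_tbl(rset)
        assert text.count("assign") == 7

    def test_selector_without_name_or_segid_rejected(self):
        bad = RestraintSet([DistanceRestraint(AtomSelector(1, None),
                                              (AtomSelector(2, "CA"),),
                                              2.0, 0.1, 0.1)],
                           RestraintKind.BACKBONE_CYCLE)
        with pytest.raises(CyclopepError):
            write_tbl(bad)
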