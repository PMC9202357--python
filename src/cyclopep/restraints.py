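"""Distance-restraint generation and CNS ``tbl`` serialization.

Three restraint families drive the protocol:

* **Cyclization restraints** pull the bond-forming atoms of a peptide
  together before the covalent cycle is closed: C–N 1.3 Å and O–N 2.3 Å
  for a head-to-tail bond; Cα–Cα 4 Å, Cβ–Cβ 3.5 Å and Sγ–Sγ 2 Å for a
  disulfide bridge (mean distances observed in such cyclic peptides).
  The combined mode uses both sets minus the Cβ–Cβ entry.  All carry
  ±0.1 Å bound corrections.
* **Ambiguous interaction restraints (AIRs)** bias docking toward a known
  binding site: one effective-distance restraint per active receptor
  residue against every passive peptide residue.
* **Body restraints** keep the rigid bodies of a gapped/multichain
  receptor together during flexible refinement.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .core import (AtomSelector, Conformation, Cyclization, CyclopepError,
                   DistanceRestraint, PeptideSpec, RestraintKind, RestraintSet)

__all__ = [
    "backbone_cyclization_restraints",
    "disulfide_cyclization_restraints",
    "combined_cyclization_restraints",
    "cyclization_restraints",
    "interface_from_complex",
    "ambiguous_interaction_restraints",
    "body_restraints",
    "write_tbl",
    "parse_tbl",
    "read_active_passive",
]

CORRECTION = 0.1          # Å, cyclization restraint bounds
CN_TARGET = 1.3           # Å, C(term) to N(term) peptide-bond restraint
ON_TARGET = 2.3           # Å, O(term) to N(term), restrains the O-C-N angle
CACA_TARGET = 4.0         # Å, Cys Cα-Cα
CBCB_TARGET = 3.5         # Å, Cys Cβ-Cβ
SGSG_TARGET = 2.0         # Å, Cys Sγ-Sγ
AIR_TARGET = 2.0          # Å, ambiguous restraint target
AIR_LOWER = 2.0           # Å, lower correction (bound reaches 0)
AIR_UPPER = 0.0           # Å, upper correction
CHAIN_BREAK_CN = 2.5      # Å, C(i)-N(i+1) beyond this starts a new body


def _pair(resid_i, name_i, resid_j, name_j, target) -> DistanceRestraint:
    return DistanceRestraint(
        sel_i=AtomSelector(resid_i, name_i),
        sel_j=(AtomSelector(resid_j, name_j),),
        target=target, lower=CORRECTION, upper=CORRECTION)


def backbone_cyclization_restraints(spec: PeptideSpec) -> RestraintSet:
    """Head-to-tail restraints: C–N 1.3 Å and O–N 2.3 Å (±0.1)."""
    if spec.cyclization not in (Cyclization.BACKBONE, Cyclization.COMBINED):
        raise CyclopepError("spec is not head-to-tail cyclized")
    if spec.capped:
        raise CyclopepError("capped termini cannot form a head-to-tail bond")
    first = spec.resid_of(1)
    last = spec.resid_of(spec.n_residues)
    return RestraintSet(
        [_pair(last, "C", first, "N", CN_TARGET),
         _pair(last, "O", first, "N", ON_TARGET)],
        kind=RestraintKind.BACKBONE_CYCLE)


def disulfide_cyclization_restraints(spec: PeptideSpec) -> RestraintSet:
    """Disulfide restraints: Cα–Cα 4 Å, Cβ–Cβ 3.5 Å, Sγ–Sγ 2 Å (±0.1)."""
    if spec.disulfide_pair is None:
        raise CyclopepError("spec declares no disulfide pair")
    i, j = (spec.resid_of(p) for p in spec.disulfide_pair)
    return RestraintSet(
        [_pair(i, "CA", j, "CA", CACA_TARGET),
         _pair(i, "CB", j, "CB", CBCB_TARGET),
         _pair(i, "SG", j, "SG", SGSG_TARGET)],
        kind=RestraintKind.DISULFIDE_CYCLE)


def combined_cyclization_restraints(spec: PeptideSpec) -> RestraintSet:
    """Head-to-tail plus disulfide restraints, without the Cβ–Cβ entry."""
    if spec.cyclization is not Cyclization.COMBINED:
        raise CyclopepError("spec is not combined-cyclized")
    bb = backbone_cyclization_restraints(spec)
    ss = disulfide_cyclization_restraints(spec)
    keep = [r for r in ss if r.sel_i.name != "CB"]
    return RestraintSet(list(bb) + keep, kind=RestraintKind.COMBINED_CYCLE)


def cyclization_restraints(spec: PeptideSpec) -> RestraintSet:
    """The restraint set matching ``spec.cyclization``."""
    if spec.cyclization is Cyclization.BACKBONE:
        return backbone_cyclization_restraints(spec)
    if spec.cyclization is Cyclization.DISULFIDE:
        return disulfide_cyclization_restraints(spec)
    return combined_cyclization_restraints(spec)


def interface_from_complex(receptor: Conformation, peptide: Conformation,
                           cutoff: float = 5.0) -> list[int]:
    """Receptor residues with any heavy atom within ``cutoff`` Å of any
    peptide heavy atom (the binding-site definition used for AIRs)."""
    rmask = receptor.heavy_mask
    pmask = peptide.heavy_mask
    tree = cKDTree(peptide.coords[pmask])
    hits = tree.query_ball_point(receptor.coords[rmask], cutoff)
    resids = sorted({int(r) for r, h in zip(receptor.resid[rmask], hits) if h})
    if not resids:
        warnings.warn("no receptor residue within cutoff of the peptide "
                      "(non-binding reference?)", stacklevel=2)
    return resids


def ambiguous_interaction_restraints(active_receptor: list[int],
                                     passive_peptide: list[int],
                                     target: float = AIR_TARGET,
                                     receptor_segid: str = "A",
                                     peptide_segid: str = "B") -> RestraintSet:
    """One AIR per active receptor residue against all passive peptide
    residues (2.0 Å target, 2.0 lower / 0.0 upper corrections)."""
    if not active_receptor or not passive_peptide:
        raise CyclopepError("active and passive residue lists must be non-empty")
    if receptor_segid == peptide_segid and set(active_receptor) & set(passive_peptide):
        raise CyclopepError("active/passive lists overlap on the same molecule")
    restraints = [
        DistanceRestraint(
            sel_i=AtomSelector(int(a), None, receptor_segid),
            sel_j=tuple(AtomSelector(int(p), None, peptide_segid)
                        for p in passive_peptide),
            target=target, lower=AIR_LOWER, upper=AIR_UPPER)
        for a in active_receptor]
    return RestraintSet(restraints, kind=RestraintKind.AIR)


def detect_bodies(structure: Conformation) -> list[list[int]]:
    """Partition residues into rigid bodies at chain breaks.

    A break is a C(i)→N(i+1) distance above 2.5 Å or a gap in residue
    numbering between consecutive residues.
    """
    resids = [int(r) for r in structure.residue_ids]
    if len(resids) < 2:
        raise CyclopepError("body detection needs at least 2 residues")
    bodies = [[resids[0]]]
    for prev, cur in zip(resids, resids[1:]):
        broken = cur != prev + 1
        if not broken:
            try:
                ci = structure.index_of(prev, "C")
                ni = structure.index_of(cur, "N")
                broken = np.linalg.norm(
                    structure.coords[ci] - structure.coords[ni]) > CHAIN_BREAK_CN
            except CyclopepError:
                broken = True
        if broken:
            bodies.append([cur])
        else:
            bodies[-1].append(cur)
    return bodies


def body_restraints(structure: Conformation) -> RestraintSet:
    """Cα–Cα restraints tying successive rigid bodies together.

    Two restraints per consecutive body pair — first-residue to
    first-residue and last-residue to last-residue — each fixing the
    measured distance with zero corrections.  A single continuous body
    yields an empty set.
    """
    bodies = detect_bodies(structure)
    restraints: list[DistanceRestraint] = []
    for a, b in zip(bodies, bodies[1:]):
        for ra, rb in ((a[0], b[0]), (a[-1], b[-1])):
            ia = structure.index_of(ra, "CA")
            ib = structure.index_of(rb, "CA")
            d = float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))
            restraints.append(DistanceRestraint(
                sel_i=AtomSelector(ra, "CA"), sel_j=(AtomSelector(rb, "CA"),),
                target=round(d, 3), lower=0.0, upper=0.0))
    return RestraintSet(restraints, kind=RestraintKind.BODY)


# -- tbl serialization ---------------------------------------------------

def _fmt(x: float) -> str:
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_tbl(rset: RestraintSet) -> str:
    """Serialize a restraint set in the CNS ``assign`` tbl dialect.

    Unambiguous restraints are one line each; ambiguous restraints expand
    their partner selection as parenthesized ``or`` alternatives.  Output
    round-trips losslessly through :func:`parse_tbl`.
    """
    if len(rset) == 0 and rset.kind is not RestraintKind.BODY:
        raise CyclopepError(f"empty restraint set of kind {rset.kind.value}")
    lines = []
    for r in rset:
        if r.sel_i.name is None and r.sel_i.segid is None:
            raise CyclopepError("selector carries neither atom name nor segid")
        tail = f"{_fmt(r.target)} {_fmt(r.lower)} {_fmt(r.upper)}"
        if len(r.sel_j) == 1:
            lines.append(f"assign {r.sel_i.to_cns()} {r.sel_j[0].to_cns()} {tail}")
        else:
            lines.append(f"assign {r.sel_i.to_cns()}")
            lines.append("       (")
            for k, s in enumerate(r.sel_j):
                if k:
                    lines.append("     or")
                lines.append(f"        {s.to_cns()}")
            lines.append(f"       ) {tail}")
        lines.append("")
    return "\n".join(lines)


_SEL_RE = re.compile(r"\(\s*([^()]*?)\s*\)")


def _parse_selector(text: str) -> AtomSelector:
    resid = name = segid = None
    for clause in text.split(" and "):
        key, _, val = clause.strip().partition(" ")
        if key == "resid":
            resid = int(val)
        elif key == "name":
            name = val.strip()
        elif key == "segid":
            segid = val.strip()
        else:
            raise CyclopepError(f"unsupported selection clause {clause!r}")
    if resid is None:
        raise CyclopepError(f"selection without resid: {text!r}")
    return AtomSelector(resid, name, segid)


def parse_tbl(text: str, kind: RestraintKind | str = RestraintKind.AIR) -> RestraintSet:
    """Parse CNS tbl ``assign`` statements back into a restraint set."""
    statements = [s.strip() for s in text.split("assign") if s.strip()]
    restraints = []
    for stmt in statements:
        # strip selections; the trailing bare numbers are d, d-, d+
        numbers = _SEL_RE.sub(" ", stmt.replace("or", " ")).split()
        if len(numbers) < 3:
            raise CyclopepError(f"malformed assign statement: {stmt!r}")
        target, lower, upper = (float(x) for x in numbers[-3:])
        sels = _SEL_RE.findall(stmt)
        inner = [s for s in sels if s]
        if len(inner) < 2:
            raise CyclopepError(f"assign needs two selections: {stmt!r}")
        sel_i = _parse_selector(inner[0])
        sel_j = tuple(_parse_selector(s) for s in inner[1:])
        restraints.append(DistanceRestraint(sel_i, sel_j, target, lower, upper))
    return RestraintSet(restraints, kind=RestraintKind(kind))


def read_active_passive(text: str) -> tuple[list[int], list[int]]:
    """Active/passive residue lists: two whitespace-separated lines."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 2:
        raise CyclopepError("expected exactly two lines: active then passive")
    return [int(x) for x in lines[0].split()], [int(x) for x in lines[1].split()]
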