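"""Build linear all-atom peptides from sequence in defined backbone states.

The builder places the backbone by internal coordinates (NeRF) at the
requested (φ, ψ) state with trans peptide bonds, grafts idealised residue
geometry (heavy atoms, hydrogens and intra-residue bonds) from the Chemical
Component Dictionary shipped with biotite, applies pH-7 protonation rules,
and sets all side-chain χ torsions to the extended (180°) rotamer.
Cyclization is handled downstream — the output here is a linear conformer
with either charged termini (NH3+/COO−) or ACE/NME caps.

Backbone states
---------------
``beta``      (φ, ψ) = (−140°, 135°)  — extended β-strand
``polypro``   (φ, ψ) = (−78°, 149°)   — polyproline-II helix

Both are configurable via :data:`BACKBONE_DIHEDRALS`.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import biotite.structure.info as struc_info

from .core import (AMINO3, BackboneState, Caps, Conformation, Cyclization,
                   CyclopepError, PeptideSpec)
from .geometry import dihedral, place_atom, rotate_about_axis, superpose

__all__ = ["build_linear_peptide", "end_to_end_distance", "BACKBONE_DIHEDRALS"]

#: (phi, psi) in degrees per supported backbone state.
BACKBONE_DIHEDRALS: dict[BackboneState, tuple[float, float]] = {
    BackboneState.BETA: (-140.0, 135.0),
    BackboneState.POLYPRO: (-78.0, 149.0),
}

OMEGA = 180.0

# ideal backbone internal coordinates (lengths Å, angles deg)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "N-H": 1.010, "C-CH3": 1.507, "N-CH3": 1.455}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
      "CA-C-O": 120.4, "N-C-O": 123.0, "C-N-C": 121.7}

# standard side-chain chi torsion quadruples (rotated to 180 deg at build)
_CHI: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_TEMPLATE_CACHE: dict[str, dict] = {}


def _template(resname: str) -> dict:
    """Idealised residue geometry from the bundled CCD: names, elements,
    coordinates and intra-residue bonds."""
    if resname not in _TEMPLATE_CACHE:
        arr = struc_info.residue(resname)
        _TEMPLATE_CACHE[resname] = {
            "names": [str(n) for n in arr.atom_name],
            "elements": [str(e).capitalize() for e in arr.element],
            "coords": np.array(arr.coord, float),
            "bonds": [(int(i), int(j)) for i, j, _ in arr.bonds.as_array()],
        }
    return _TEMPLATE_CACHE[resname]


def _template_subset(resname: str, drop: set[str]):
    t = _template(resname)
    keep = [i for i, n in enumerate(t["names"]) if n not in drop]
    index = {old: new for new, old in enumerate(keep)}
    names = [t["names"][i] for i in keep]
    elements = [t["elements"][i] for i in keep]
    coords = t["coords"][keep]
    bonds = [(index[i], index[j]) for i, j in t["bonds"]
             if i in index and j in index]
    return names, elements, coords, bonds


def _dropped_atoms(resname: str, *, first: bool, last: bool, capped: bool,
                   in_ss_pair: bool) -> set[str]:
    """Hydrogens/oxygens to strip from the neutral CCD template so the
    residue matches its position and pH-7 protonation state."""
    # amide/amine hydrogens are always re-placed geometrically
    drop = {"H", "H2"}
    if last and not capped:
        drop |= {"HXT"}            # charged C-terminus: COO-, no acid proton
    else:
        drop |= {"OXT", "HXT"}
    if resname == "ASP":
        drop |= {"HD2"}
    elif resname == "GLU":
        drop |= {"HE2"}
    elif resname == "HIS":
        drop |= {"HD1"}            # neutral His, Nε2-H tautomer
    elif resname == "CYS" and in_ss_pair:
        drop |= {"HG"}
    return drop


class _Assembler:
    def __init__(self):
        self.resid: list[int] = []
        self.resname: list[str] = []
        self.name: list[str] = []
        self.element: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add_atom(self, resid, resname, name, element, xyz) -> int:
        self.resid.append(resid)
        self.resname.append(resname)
        self.name.append(name)
        self.element.append(element)
        self.coords.append(np.asarray(xyz, float))
        return len(self.name) - 1

    def index(self, resid: int, name: str) -> int:
        for i in range(len(self.name) - 1, -1, -1):
            if self.resid[i] == resid and self.name[i] == name:
                return i
        raise KeyError((resid, name))

    def xyz(self, resid: int, name: str) -> np.ndarray:
        return self.coords[self.index(resid, name)]


def _graft_residue(asm: _Assembler, resid: int, resname: str,
                   drop: set[str], bb_n, bb_ca, bb_c):
    """Superimpose the residue template onto the placed backbone triad and
    transfer every non-backbone atom plus the intra-residue bonds."""
    names, elements, coords, bonds = _template_subset(resname, drop)
    tri = [names.index("N"), names.index("CA"), names.index("C")]
    fitted, rot, trans = superpose(coords[tri], np.array([bb_n, bb_ca, bb_c]))
    placed = coords @ rot.T + trans
    # exact backbone positions win over the fitted template triad
    placed[tri[0]], placed[tri[1]], placed[tri[2]] = bb_n, bb_ca, bb_c
    local_index = {}
    for k, nm in enumerate(names):
        if nm == "O":              # carbonyl O is re-placed by the caller
            continue
        local_index[k] = asm.add_atom(resid, resname, nm, elements[k], placed[k])
    o_slot = names.index("O") if "O" in names else None
    for i, j in bonds:
        if o_slot is not None and o_slot in (i, j):
            continue
        asm.bonds.append((local_index[i], local_index[j]))


def _set_chi_extended(asm: _Assembler, resid: int, resname: str):
    if resname not in _CHI or resname == "PRO":
        return
    # adjacency over this residue's atoms only
    atom_ids = [i for i, r in enumerate(asm.resid) if r == resid]
    adj = defaultdict(set)
    for i, j in asm.bonds:
        if i in atom_ids and j in atom_ids:
            adj[i].add(j)
            adj[j].add(i)
    for ichi, quad in enumerate(_CHI[resname]):
        try:
            ia, ib, ic, id_ = (asm.index(resid, n) for n in quad)
        except KeyError:
            continue
        # extended chain except aromatic chi2, where the ring sits
        # perpendicular to the Calpha-Cbeta-Cgamma plane (Trp flipped:
        # its fused ring otherwise rides over the i+1 carbonyl in PPII)
        if ichi == 1 and resname in ("HIS", "PHE", "TYR", "TRP"):
            target = -90.0 if resname == "TRP" else 90.0
        else:
            target = 180.0
        current = dihedral(asm.coords[ia], asm.coords[ib],
                           asm.coords[ic], asm.coords[id_])
        delta = target - current
        if abs(delta) < 1e-9:
            continue
        # atoms distal to the b-c bond (component of c with b removed)
        stack, seen = [ic], {ib, ic}
        distal = []
        while stack:
            k = stack.pop()
            for nb in adj[k]:
                if nb not in seen:
                    seen.add(nb)
                    distal.append(nb)
                    stack.append(nb)
        axis = asm.coords[ic] - asm.coords[ib]
        moving = np.array([asm.coords[k] for k in distal])
        rotated = rotate_about_axis(moving, asm.coords[ib], axis, delta)
        for k, xyz in zip(distal, rotated):
            asm.coords[k] = xyz


def _place_nterm_hydrogens(asm: _Assembler, resid: int, resname: str, charged: bool):
    """NH3+ hydrogens (or a secondary-amine pair for proline), staggered
    about the N-CA bond."""
    n = asm.xyz(resid, "N")
    ca = asm.xyz(resid, "CA")
    c = asm.xyz(resid, "C")
    i_n = asm.index(resid, "N")
    torsions = (60.0, 180.0, -60.0)
    labels = ("H1", "H2", "H3")
    if resname == "PRO":           # ring CD occupies one site
        torsions, labels = (60.0, 180.0), ("H1", "H2")
    if not charged:
        torsions, labels = (180.0,), ("H",)
    for t, lbl in zip(torsions, labels):
        xyz = place_atom(c, ca, n, _B["N-H"], 109.5, t)
        k = asm.add_atom(resid, resname, lbl, "H", xyz)
        asm.bonds.append((i_n, k))


def _place_amide_h(asm: _Assembler, resid: int, resname: str, prev_c: np.ndarray):
    if resname == "PRO":
        return
    n = asm.xyz(resid, "N")
    ca = asm.xyz(resid, "CA")
    u = (prev_c - n) / np.linalg.norm(prev_c - n)
    v = (ca - n) / np.linalg.norm(ca - n)
    h = n - _B["N-H"] * (u + v) / np.linalg.norm(u + v)
    k = asm.add_atom(resid, resname, "H", "H", h)
    asm.bonds.append((asm.index(resid, "N"), k))


def build_linear_peptide(spec: PeptideSpec,
                         state: BackboneState | str) -> Conformation:
    """Build a linear all-atom conformer of ``spec`` in a backbone state.

    The result is deterministic: identical (spec, state) pairs give
    bit-identical coordinates.  Residues are numbered from 1; with ACE/NME
    caps the caps are residues of their own (ACE first, NME last).

    Parameters
    ----------
    spec
        Peptide specification (sequence, cyclization mode, terminal
        chemistry, optional disulfide pair).
    state
        ``beta`` or ``polypro``.

    Returns
    -------
    Conformation
        Clash-free extended conformer with full heavy-atom and hydrogen
        complement and explicit covalent bonds.
    """
    state = BackboneState(state)
    phi, psi = BACKBONE_DIHEDRALS[state]
    seq = spec.sequence
    n_res = len(seq)
    capped = spec.capped
    ss_pair = set(spec.disulfide_pair or ())

    asm = _Assembler()

    # ---- backbone trace (N, CA, C per sequence residue) -----------------
    bb = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A["N-CA-C"])
    c0 = ca0 + _B["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    bb.append((n0, ca0, c0))
    for i in range(1, n_res):
        pn, pca, pc = bb[-1]
        # proline's pyrrolidine ring fixes phi near -75 deg; all other
        # residues take the state's configured value
        phi_i = -75.0 if seq[i] == "P" else phi
        nn = place_atom(pn, pca, pc, _B["C-N"], _A["CA-C-N"], psi)
        nca = place_atom(pca, pc, nn, _B["N-CA"], _A["C-N-CA"], OMEGA)
        nc = place_atom(pc, nn, nca, _B["CA-C"], _A["N-CA-C"], phi_i)
        bb.append((nn, nca, nc))

    offset = 1 if capped else 0
    first_resid, last_resid = 1 + offset, n_res + offset

    # ---- residues --------------------------------------------------------
    prev_c_index: int | None = None
    for i, letter in enumerate(seq):
        resid = i + 1 + offset
        resname = AMINO3[letter]
        if resname not in _TEMPLATE_CACHE and resname not in AMINO3.values():
            raise CyclopepError(f"unknown residue letter {letter!r} at position {i + 1}")
        drop = _dropped_atoms(resname, first=(i == 0), last=(i == n_res - 1),
                              capped=capped, in_ss_pair=(i + 1) in ss_pair)
        bb_n, bb_ca, bb_c = bb[i]
        _graft_residue(asm, resid, resname, drop, bb_n, bb_ca, bb_c)

        # carbonyl O (and OXT at a charged C-terminus) from psi
        i_c = asm.index(resid, "C")
        o_xyz = place_atom(bb_n, bb_ca, bb_c, _B["C-O"], _A["CA-C-O"], psi + 180.0)
        k = asm.add_atom(resid, resname, "O", "O", o_xyz)
        asm.bonds.append((i_c, k))
        if i == n_res - 1 and not capped:
            oxt = place_atom(bb_n, bb_ca, bb_c, _B["C-O"], _A["CA-C-O"], psi)
            asm.coords[asm.index(resid, "OXT")] = oxt

        _set_chi_extended(asm, resid, resname)

        # peptide bond to the previous residue
        if prev_c_index is not None:
            asm.bonds.append((prev_c_index, asm.index(resid, "N")))
            _place_amide_h(asm, resid, resname, asm.coords[prev_c_index])
        prev_c_index = i_c

    # ---- termini ---------------------------------------------------------
    if capped:
        _build_ace(asm, bb[0], first_resid - 1, phi)
        _place_amide_h(asm, first_resid, AMINO3[seq[0]], asm.xyz(first_resid - 1, "C"))
        _build_nme(asm, bb[-1], last_resid + 1, psi)
    else:
        _place_nterm_hydrogens(asm, first_resid, AMINO3[seq[0]], charged=True)

    # atoms in residue order (caps were appended last), bonds remapped
    order = np.argsort(np.array(asm.resid), kind="stable")
    inverse = np.empty(len(order), int)
    inverse[order] = np.arange(len(order))
    asm.resid = [asm.resid[i] for i in order]
    asm.resname = [asm.resname[i] for i in order]
    asm.name = [asm.name[i] for i in order]
    asm.element = [asm.element[i] for i in order]
    asm.coords = [asm.coords[i] for i in order]
    asm.bonds = [(int(inverse[i]), int(inverse[j])) for i, j in asm.bonds]

    conf = Conformation(
        resid=np.array(asm.resid), resname=np.array(asm.resname),
        atom_name=np.array(asm.name), element=np.array(asm.element),
        coords=np.array(asm.coords), bonds=np.array(asm.bonds, int).reshape(-1, 2),
        labels={"state": state.value, "stage": "build", "sequence": seq,
                "cyclization": spec.cyclization.value, "caps": spec.caps.value},
    )
    return conf


def _build_ace(asm: _Assembler, first_bb, ace_resid: int, phi: float):
    bb_n, bb_ca, bb_c = first_bb
    c = place_atom(bb_c, bb_ca, bb_n, _B["C-N"], _A["C-N-CA"], phi)
    o = place_atom(bb_ca, bb_n, c, _B["C-O"], _A["N-C-O"], 0.0)
    ch3 = place_atom(bb_ca, bb_n, c, _B["C-CH3"], _A["CA-C-N"], 180.0)
    i_c = asm.add_atom(ace_resid, "ACE", "C", "C", c)
    i_o = asm.add_atom(ace_resid, "ACE", "O", "O", o)
    i_m = asm.add_atom(ace_resid, "ACE", "CH3", "C", ch3)
    asm.bonds += [(i_c, i_o), (i_c, i_m), (i_c, asm.index(ace_resid + 1, "N"))]
    names, elements, coords, _ = _template_subset("ACE", {"H"})
    tri = [names.index("C"), names.index("O"), names.index("CH3")]
    _, rot, trans = superpose(coords[tri], np.array([c, o, ch3]))
    placed = coords @ rot.T + trans
    for k, nm in enumerate(names):
        if nm.startswith("H"):
            j = asm.add_atom(ace_resid, "ACE", nm, "H", placed[k])
            asm.bonds.append((i_m, j))


def _build_nme(asm: _Assembler, last_bb, nme_resid: int, psi: float):
    bb_n, bb_ca, bb_c = last_bb
    n = place_atom(bb_n, bb_ca, bb_c, _B["C-N"], _A["CA-C-N"], psi)
    cm = place_atom(bb_ca, bb_c, n, _B["N-CH3"], _A["C-N-CA"], 180.0)
    i_n = asm.add_atom(nme_resid, "NME", "N", "N", n)
    i_m = asm.add_atom(nme_resid, "NME", "C", "C", cm)
    asm.bonds += [(i_n, i_m), (asm.index(nme_resid - 1, "C"), i_n)]
    # planar amide H on the cap nitrogen
    u = (bb_c - n) / np.linalg.norm(bb_c - n)
    v = (cm - n) / np.linalg.norm(cm - n)
    h = n - _B["N-H"] * (u + v) / np.linalg.norm(u + v)
    i_h = asm.add_atom(nme_resid, "NME", "HN1", "H", h)
    asm.bonds.append((i_n, i_h))
    names, elements, coords, _ = _template_subset("NME", {"HN2"})
    tri = [names.index("N"), names.index("C"), names.index("HN1")]
    _, rot, trans = superpose(coords[tri], np.array([n, cm, h]))
    placed = coords @ rot.T + trans
    for k, nm in enumerate(names):
        if nm in ("H1", "H2", "H3"):
            j = asm.add_atom(nme_resid, "NME", nm, "H", placed[k])
            asm.bonds.append((i_m, j))


def end_to_end_distance(conf: Conformation, mode: Cyclization | str) -> float:
    """Distance (Å) between the bond-forming atoms of a cyclization mode.

    ``backbone``: C-terminal carbonyl C to N-terminal amide N (cap residues
    excluded).  ``disulfide``: the two cysteine Sγ atoms.
    """
    mode = Cyclization(mode)
    if mode is Cyclization.DISULFIDE:
        sg = np.flatnonzero(conf.atom_name == "SG")
        if len(sg) != 2:
            raise CyclopepError(
                f"disulfide distance needs exactly two SG atoms, found {len(sg)}")
        return float(np.linalg.norm(conf.coords[sg[0]] - conf.coords[sg[1]]))
    amino = ~np.isin(conf.resname, ("ACE", "NME"))
    if not amino.any():
        raise CyclopepError("no amino-acid residues present")
    resids = conf.resid[amino]
    first, last = int(resids.min()), int(resids.max())
    try:
        i = conf.index_of(first, "N")
        j = conf.index_of(last, "C")
    except CyclopepError as exc:
        raise CyclopepError(f"terminus atom missing: {exc}") from exc
    return float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
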