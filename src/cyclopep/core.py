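"""Shared domain types: peptide specifications, conformations, restraints.

A :class:`Conformation` is the package's in-memory molecule: flat numpy
arrays over atoms (residue id, residue name, atom name, element, coordinates)
plus an explicit covalent bond list and free-form provenance labels.  It is
deliberately simpler than a full structural-biology container — single
model, single (anonymous) chain after preparation, no altlocs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Cyclization",
    "Caps",
    "BackboneState",
    "PeptideSpec",
    "Conformation",
    "AtomSelector",
    "DistanceRestraint",
    "RestraintKind",
    "RestraintSet",
    "CyclopepError",
]

AMINO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class CyclopepError(ValueError):
    """Domain-level rejection (invalid spec, selection, or file)."""


class Cyclization(str, Enum):
    BACKBONE = "backbone"
    DISULFIDE = "disulfide"
    COMBINED = "combined"


class Caps(str, Enum):
    CHARGED_TERMINI = "charged_termini"
    ACE_NME = "ACE_NME"


class BackboneState(str, Enum):
    BETA = "beta"
    POLYPRO = "polypro"


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide to cyclize: sequence plus cyclization chemistry.

    Parameters
    ----------
    sequence
        One-letter amino-acid string (typically 6-14 residues).
    cyclization
        ``backbone`` (head-to-tail peptide bond), ``disulfide`` (one
        Sγ-Sγ bridge) or ``combined`` (both).
    caps
        Terminal chemistry: charged termini (NH3+/COO-) or ACE/NME caps.
        A head-to-tail bond requires charged termini.
    disulfide_pair
        1-based sequence positions of the two bridging cysteines; required
        for ``disulfide`` and ``combined``.
    """

    sequence: str
    cyclization: Cyclization = Cyclization.BACKBONE
    caps: Caps = Caps.CHARGED_TERMINI
    disulfide_pair: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "cyclization", Cyclization(self.cyclization))
        object.__setattr__(self, "caps", Caps(self.caps))
        if len(self.sequence) < 3:
            raise CyclopepError(
                f"sequence must have at least 3 residues, got {len(self.sequence)!r}")
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in AMINO3:
                raise CyclopepError(
                    f"unknown residue letter {letter!r} at position {pos}")
        if self.cyclization in (Cyclization.DISULFIDE, Cyclization.COMBINED):
            pair = self.disulfide_pair
            if pair is None or len(pair) != 2 or pair[0] == pair[1]:
                raise CyclopepError(
                    "disulfide cyclization requires two distinct cysteine positions")
            for pos in pair:
                if not 1 <= pos <= len(self.sequence):
                    raise CyclopepError(f"disulfide position {pos} outside sequence")
                if self.sequence[pos - 1] != "C":
                    raise CyclopepError(
                        f"disulfide position {pos} is {self.sequence[pos - 1]!r}, not Cys")
        if self.cyclization is Cyclization.BACKBONE and self.caps is not Caps.CHARGED_TERMINI:
            raise CyclopepError("head-to-tail cyclization precludes ACE/NME caps")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def capped(self) -> bool:
        return self.caps is Caps.ACE_NME

    def resid_of(self, seq_pos: int) -> int:
        """Conformation residue id of a 1-based sequence position.

        ACE/NME caps are residues of their own (ACE is residue 1), so
        capped peptides shift sequence positions by one.
        """
        return seq_pos + (1 if self.capped else 0)


@dataclass
class Conformation:
    """All-atom single-model structure with explicit covalent topology."""

    resid: np.ndarray          # (n,) int
    resname: np.ndarray        # (n,) <U3
    atom_name: np.ndarray      # (n,) <U4
    element: np.ndarray        # (n,) <U2
    coords: np.ndarray         # (n, 3) float
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    chain: np.ndarray | None = None      # per-atom chain id ('' when stripped)
    het: np.ndarray | None = None        # per-atom HETATM flag
    occupancy: np.ndarray | None = None
    bfactor: np.ndarray | None = None
    icode: np.ndarray | None = None      # insertion codes, '' when absent
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.resid)
        self.resid = np.asarray(self.resid, int)
        self.resname = np.asarray(self.resname, dtype="U3")
        self.atom_name = np.asarray(self.atom_name, dtype="U4")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, float).reshape(n, 3)
        self.bonds = np.asarray(self.bonds, int).reshape(-1, 2)
        if self.chain is None:
            self.chain = np.full(n, "", dtype="U1")
        if self.het is None:
            self.het = np.zeros(n, bool)
        if self.occupancy is None:
            self.occupancy = np.ones(n, float)
        if self.bfactor is None:
            self.bfactor = np.zeros(n, float)
        if self.icode is None:
            self.icode = np.full(n, "", dtype="U1")

    # -- basic queries ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.resid)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue ids in order of first appearance."""
        _, idx = np.unique(self.resid, return_index=True)
        return self.resid[np.sort(idx)]

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def index_of(self, resid: int, atom_name: str) -> int:
        hits = np.flatnonzero((self.resid == resid) & (self.atom_name == atom_name))
        if len(hits) == 0:
            raise CyclopepError(f"atom {atom_name!r} of residue {resid} not found")
        return int(hits[0])

    def has_atom(self, resid: int, atom_name: str) -> bool:
        return bool(np.any((self.resid == resid) & (self.atom_name == atom_name)))

    def backbone_mask(self, resids: Iterable[int] | None = None) -> np.ndarray:
        mask = np.isin(self.atom_name, BACKBONE_ATOMS) & (self.element != "H")
        if resids is not None:
            mask &= np.isin(self.resid, list(resids))
        return mask

    def copy(self) -> "Conformation":
        return Conformation(
            resid=self.resid.copy(), resname=self.resname.copy(),
            atom_name=self.atom_name.copy(), element=self.element.copy(),
            coords=self.coords.copy(), bonds=self.bonds.copy(),
            chain=self.chain.copy(), het=self.het.copy(),
            occupancy=self.occupancy.copy(), bfactor=self.bfactor.copy(),
            icode=self.icode.copy(), labels=dict(self.labels),
        )

    def subset(self, mask: np.ndarray) -> "Conformation":
        """Atom subset; bonds are remapped, bonds crossing the cut dropped."""
        mask = np.asarray(mask, bool)
        new_index = -np.ones(self.n_atoms, int)
        new_index[mask] = np.arange(int(mask.sum()))
        keep = mask[self.bonds[:, 0]] & mask[self.bonds[:, 1]] if len(self.bonds) else np.zeros(0, bool)
        return Conformation(
            resid=self.resid[mask], resname=self.resname[mask],
            atom_name=self.atom_name[mask], element=self.element[mask],
            coords=self.coords[mask], bonds=new_index[self.bonds[keep]],
            chain=self.chain[mask], het=self.het[mask],
            occupancy=self.occupancy[mask], bfactor=self.bfactor[mask],
            icode=self.icode[mask], labels=dict(self.labels),
        )

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        new = self.copy()
        new.coords = np.asarray(coords, float).reshape(self.n_atoms, 3)
        return new


def concatenate(a: Conformation, b: Conformation) -> Conformation:
    """Stack two conformations into one (atoms of ``b`` appended)."""
    return Conformation(
        resid=np.concatenate([a.resid, b.resid]),
        resname=np.concatenate([a.resname, b.resname]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
        bonds=np.vstack([a.bonds, b.bonds + a.n_atoms]) if len(b.bonds) or len(a.bonds)
        else np.empty((0, 2), int),
        chain=np.concatenate([a.chain, b.chain]),
        het=np.concatenate([a.het, b.het]),
        occupancy=np.concatenate([a.occupancy, b.occupancy]),
        bfactor=np.concatenate([a.bfactor, b.bfactor]),
        icode=np.concatenate([a.icode, b.icode]),
    )


# -- restraints ----------------------------------------------------------


@dataclass(frozen=True)
class AtomSelector:
    """CNS-style atom selection: residue id, optional atom name / segid.

    ``name=None`` selects every atom of the residue (the convention used
    by ambiguous interaction restraints).
    """

    resid: int
    name: str | None = None
    segid: str | None = None

    def to_cns(self) -> str:
        parts = [f"resid {self.resid}"]
        if self.segid is not None:
            parts.append(f"segid {self.segid}")
        if self.name is not None:
            parts.append(f"name {self.name}")
        return "(" + " and ".join(parts) + ")"

    def atom_indices(self, conf: Conformation, heavy_only: bool = False) -> np.ndarray:
        mask = self.resid == conf.resid
        if self.name is not None:
            mask &= conf.atom_name == self.name
        if heavy_only:
            mask &= conf.heavy_mask
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint ``d`` with lower/upper corrections.

    Satisfied iff the measured (effective, for ambiguous restraints)
    distance lies in ``[d - lower, d + upper]``.
    """

    sel_i: AtomSelector
    sel_j: tuple[AtomSelector, ...]   # >1 selector = ambiguous OR branches
    target: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.target <= 0:
            raise CyclopepError("restraint target distance must be positive")
        if self.lower < 0 or self.upper < 0:
            raise CyclopepError("restraint corrections must be non-negative")
        object.__setattr__(self, "sel_j", tuple(self.sel_j))

    @property
    def ambiguous(self) -> bool:
        return len(self.sel_j) > 1 or any(s.name is None for s in self.sel_j)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.target - self.lower, self.target + self.upper)

    def effective_distance(self, conf_i: Conformation,
                           conf_j: Conformation | None = None) -> float:
        """Measured distance; ambiguous restraints use the r^-6 soft minimum.

        ``(Σ_pairs d^-6)^(-1/6)`` over all atom pairs of all branches — the
        effective-distance semantics of ambiguous interaction restraints.
        It is bounded above by the minimum pairwise distance.
        """
        conf_j = conf_i if conf_j is None else conf_j
        ii = self.sel_i.atom_indices(conf_i, heavy_only=self.sel_i.name is None)
        jj = np.concatenate([
            s.atom_indices(conf_j, heavy_only=s.name is None) for s in self.sel_j])
        if len(ii) == 0 or len(jj) == 0:
            raise CyclopepError(f"restraint selection matched no atoms: {self}")
        diff = conf_i.coords[ii][:, None, :] - conf_j.coords[jj][None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1)).ravel()
        if len(d) == 1:
            return float(d[0])
        return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))

    def satisfied(self, conf_i: Conformation, conf_j: Conformation | None = None) -> bool:
        lo, hi = self.bounds
        return lo <= self.effective_distance(conf_i, conf_j) <= hi


class RestraintKind(str, Enum):
    BACKBONE_CYCLE = "backbone_cycle"
    DISULFIDE_CYCLE = "disulfide_cycle"
    COMBINED_CYCLE = "combined_cycle"
    AIR = "air"
    BODY = "body"


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint]
    kind: RestraintKind

    def __post_init__(self):
        self.kind = RestraintKind(self.kind)
        self.restraints = list(self.restraints)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]
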