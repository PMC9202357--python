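"""Synthetic fixtures: toy complexes with planted native contacts and
ranked quality tables with planted successes.

Everything here is seed-deterministic and built in memory, so the full
pipeline — restraint generation, docking configuration and CAPRI-style
assessment — can be exercised without downloading a single structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assess import CapriClass, QualityRecord
from .core import Conformation, CyclopepError

__all__ = ["make_toy_complex", "make_quality_table", "ToyComplex"]

_CONTACT_DISTANCE = 4.5    # Å, planted contact distance (inside the 5 Å cutoff)
_BREAK_SHIFT = 40.0        # Å, displacement that destroys a contact


def _mini_residue(resid: int, resname: str, center: np.ndarray, chain: str = ""):
    """A coarse residue: N, CA, C, O backbone cross around ``center``."""
    offsets = {"N": (-0.7, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (0.7, 0.0, 0.0), "O": (0.7, 0.9, 0.0)}
    atoms = []
    for name, off in offsets.items():
        atoms.append((resid, resname, name, name[0], center + np.array(off), chain))
    return atoms


def _assemble(atom_rows) -> Conformation:
    return Conformation(
        resid=np.array([a[0] for a in atom_rows]),
        resname=np.array([a[1] for a in atom_rows]),
        atom_name=np.array([a[2] for a in atom_rows]),
        element=np.array([a[3] for a in atom_rows]),
        coords=np.array([a[4] for a in atom_rows]),
        chain=np.array([a[5] for a in atom_rows], dtype="U1"),
    )


@dataclass
class ToyComplex:
    """A rigid mini receptor/peptide pair with known interface contacts."""

    receptor: Conformation
    peptide: Conformation
    contacts: list[tuple[int, int]]     # (receptor resid, peptide resid)

    def perturbed(self, break_contacts: int, seed: int = 0) -> "ToyComplex":
        """Copy with ``break_contacts`` planted contacts destroyed.

        The corresponding peptide residues are moved far from the
        receptor, so the surviving-contact count is exact by construction.
        """
        if not 0 <= break_contacts <= len(self.contacts):
            raise CyclopepError("break_contacts outside [0, n_contacts]")
        rng = np.random.default_rng([seed, break_contacts])
        peptide = self.peptide.copy()
        order = rng.permutation(len(self.contacts))[:break_contacts]
        for k in order:
            _, p_resid = self.contacts[k]
            sel = peptide.resid == p_resid
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            peptide.coords[sel] += _BREAK_SHIFT * direction
        return ToyComplex(self.receptor.copy(), peptide, list(self.contacts))


def make_toy_complex(seed: int = 0, n_native_contacts: int = 4) -> ToyComplex:
    """Build a reference mini-complex with exactly ``n`` planted contacts.

    Receptor residues sit on a line with 12 Å spacing (far beyond the
    contact cutoff from each other's partners); each of the first ``n``
    receptor residues gets a peptide residue planted 4.5 Å away.
    """
    if n_native_contacts < 1:
        raise CyclopepError("need at least one native contact")
    rng = np.random.default_rng(seed)
    spacing = 12.0
    receptor_rows = []
    n_receptor = n_native_contacts + 2     # a couple of non-contact residues
    for i in range(n_receptor):
        center = np.array([i * spacing, 0.0, 0.0])
        receptor_rows += _mini_residue(i + 1, "GLY", center, chain="A")
    peptide_rows = []
    contacts = []
    for i in range(n_native_contacts):
        center = np.array([i * spacing, _CONTACT_DISTANCE, 0.0])
        jitter = 0.2 * rng.standard_normal(3)
        jitter[1] = 0.0                    # keep the contact distance exact
        peptide_rows += _mini_residue(i + 1, "ALA", center + jitter, chain="B")
        contacts.append((i + 1, i + 1))
    return ToyComplex(_assemble(receptor_rows), _assemble(peptide_rows), contacts)


def make_quality_table(seed: int, n_complexes: int,
                       planted: dict[str, list[tuple[int, CapriClass | str]]]
                       ) -> dict[str, list[QualityRecord]]:
    """Ranked per-complex quality records with planted events.

    ``planted`` maps a complex name to ``(rank, class)`` events; every
    other rank (up to the largest planted rank, at least 10) is filled
    with incorrect models.  Complex names absent from ``planted`` get only
    incorrect models.  Representative fnat values are drawn per class so
    classification round-trips.
    """
    rng = np.random.default_rng(seed)
    fnat_by_class = {
        CapriClass.HIGH: (0.81, 1.0),
        CapriClass.MEDIUM: (0.51, 0.8),
        CapriClass.ACCEPTABLE: (0.21, 0.5),
        CapriClass.INCORRECT: (0.0, 0.2),
    }
    names = [f"complex_{i + 1}" for i in range(n_complexes)]
    unknown = set(planted) - set(names)
    if unknown:
        raise CyclopepError(f"planted events for unknown complexes: {sorted(unknown)}")
    table: dict[str, list[QualityRecord]] = {}
    for name in names:
        events = {rank: CapriClass.parse(cls)
                  for rank, cls in planted.get(name, [])}
        depth = max([10, *events.keys()])
        records = []
        for rank in range(1, depth + 1):
            cls = events.get(rank, CapriClass.INCORRECT)
            lo, hi = fnat_by_class[cls]
            f = float(rng.uniform(lo, hi))
            records.append(QualityRecord(model_id=f"{name}_m{rank}", rank=rank,
                                         f_nat=f, capri_class=cls))
        table[name] = records
    return table
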