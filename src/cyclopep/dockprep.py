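"""Receptor preparation and docking run configuration.

Receptor preparation mirrors the pdb-tools-based cleanup pipeline: split
and merge chains into a single anonymous chain, drop hetero atoms, make
residue numbering unique (continuous renumbering or per-chain shifting
that preserves internal gaps), and emit body restraints whenever the
structure falls apart into several rigid bodies (missing loops, former
chains).

Run configurations implement the nine benchmarked docking protocols.  All
of them share the base setup — 5000/400/400 sampled models per stage,
semiflexible-stage step counts multiplied by four, the cyclic-peptide
flag, and interface-ligand-RMSD clustering at 5 Å — and differ in the
peptide ensemble size, extra peptide flexibility, and explicit
solvent-shell refinement.  The combined protocol switches flexibility and
solvent on only for long peptides (> 10 residues).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformation, CyclopepError
from .restraints import body_restraints, detect_bodies, write_tbl

__all__ = ["RunConfig", "ReceptorPrepReport", "prepare_receptor",
           "protocol_config", "write_run_params", "parse_run_params",
           "PROTOCOLS", "LONG_PEPTIDE_MIN"]

LONG_PEPTIDE_MIN = 11     # residues; > 10 counts as a long cyclic peptide

#: protocol id -> (ensemble_max, extra flexibility, explicit solvent shell)
PROTOCOLS: dict[str, tuple[int, bool, bool]] = {
    "5STR": (5, False, False),
    "30STR": (30, False, False),
    "40STR": (40, False, False),
    "50STR": (50, False, False),
    "60STR": (60, False, False),
    "50STR_FLEX": (50, True, False),
    "50STR_SOLVSHELL": (50, False, True),
    "50STR_FLEX_SOLVSHELL": (50, True, True),
    "50STR_COMB": (50, None, None),      # length-dependent, see protocol_config
}


@dataclass(frozen=True)
class RunConfig:
    """Sampling counts and flags of one docking protocol."""

    protocol_id: str
    models_it0: int = 5000
    models_it1: int = 400
    models_itw: int = 400
    it1_step_multiplier: int = 4
    peptide_fully_flexible: bool = False
    solvent_shell: bool = False
    cyclic_peptide: bool = True
    clustering_method: str = "interface_ligand_rmsd"
    clustering_cutoff: float = 5.0
    ensemble_max: int = 50


@dataclass
class ReceptorPrepReport:
    chains_merged: list[str]
    hetero_removed: int
    renumbering: dict[tuple[str, int], int]   # (original chain, resid) -> new
    bodies: list[list[int]]
    body_restraint_file: str | None = None


def prepare_receptor(structure: Conformation, renumber: str = "reres"
                     ) -> tuple[Conformation, ReceptorPrepReport]:
    """Clean a receptor structure for docking.

    Hetero atoms are removed, chain ids stripped, and residues renumbered
    (``reres``: continuously from 1; ``shiftres``: later chains shifted by
    a constant to avoid overlap, preserving gaps; ``none``: keep, but
    reject collisions).  Multi-body structures additionally get body
    restraints (conventionally stored as ``hbonds.tbl``).
    """
    if renumber not in ("reres", "shiftres", "none"):
        raise CyclopepError(f"unknown renumbering mode {renumber!r}")
    keep = ~structure.het
    if not keep.any():
        raise CyclopepError("structure contains no polymer atoms")
    conf = structure.subset(keep)
    hetero_removed = int(structure.het.sum())
    chains = list(dict.fromkeys(conf.chain.tolist()))

    # residues in file order, keyed by (chain, resid, icode)
    keys: list[tuple[str, int, str]] = []
    for ch, rid, ic in zip(conf.chain, conf.resid, conf.icode):
        key = (str(ch), int(rid), str(ic))
        if not keys or keys[-1] != key:
            keys.append(key)

    mapping: dict[tuple[str, int, str], int] = {}
    if renumber == "reres":
        for new, key in enumerate(keys, start=1):
            mapping[key] = new
    elif renumber == "shiftres":
        # per-chain constant shift past everything assigned so far;
        # numbering gaps inside a chain survive untouched
        max_seen = None
        offset = 0
        prev_chain = None
        for ch, rid, ic in keys:
            if ch != prev_chain:
                if max_seen is None:
                    offset = 0
                else:
                    chain_min = min(r for c, r, _ in keys if c == ch)
                    offset = max(0, max_seen - chain_min + 1)
                prev_chain = ch
            mapping[(ch, rid, ic)] = rid + offset
            max_seen = rid + offset if max_seen is None else max(max_seen, rid + offset)
    else:
        seen = set()
        for key in keys:
            if key[1] in seen:
                raise CyclopepError(
                    f"residue number collision at {key[1]} after chain merge; "
                    "use reres or shiftres renumbering")
            seen.add(key[1])
            mapping[key] = key[1]

    new_resid = np.array([mapping[(str(c), int(r), str(i))]
                          for c, r, i in zip(conf.chain, conf.resid, conf.icode)])
    conf.resid = new_resid
    conf.chain = np.full(conf.n_atoms, "", dtype="U1")
    conf.icode = np.full(conf.n_atoms, "", dtype="U1")

    bodies = detect_bodies(conf) if len(conf.residue_ids) >= 2 else [list(conf.residue_ids)]
    report = ReceptorPrepReport(
        chains_merged=chains,
        hetero_removed=hetero_removed,
        renumbering={(c, r): mapping[(c, r, i)] for c, r, i in keys},
        bodies=bodies,
        body_restraint_file="hbonds.tbl" if len(bodies) > 1 else None,
    )
    return conf, report


def emit_body_restraints(conf: Conformation) -> str:
    """Body-restraint tbl text for a prepared receptor (may be empty)."""
    rset = body_restraints(conf)
    return write_tbl(rset)


def protocol_config(protocol_id: str, peptide_length: int | None = None) -> RunConfig:
    """Exact configuration of one of the nine docking protocols.

    ``peptide_length`` is only needed for the combined protocol, where
    extra flexibility and the explicit solvent shell switch on for long
    peptides (> 10 residues) and off for short ones.
    """
    if protocol_id not in PROTOCOLS:
        raise CyclopepError(f"unknown protocol id {protocol_id!r}")
    ensemble_max, flex, solv = PROTOCOLS[protocol_id]
    if protocol_id == "50STR_COMB":
        if peptide_length is None:
            raise CyclopepError("50STR_COMB needs the peptide length")
        long = peptide_length >= LONG_PEPTIDE_MIN
        flex = solv = long
    return RunConfig(protocol_id=protocol_id, ensemble_max=ensemble_max,
                     peptide_fully_flexible=bool(flex), solvent_shell=bool(solv))


_PARAM_ORDER = ["protocol", "structures_0", "structures_1", "waterrefine",
                "it1_step_multiplier", "cyclicpept_2", "clust_meth", "clust_cutoff",
                "ensemble_max", "nfle_2", "start_fle_2_1", "end_fle_2_1",
                "solvshell", "ensemble_file", "receptor_file", "restraint_file"]


def write_run_params(config: RunConfig, ensemble_file: str, receptor_file: str,
                     restraint_file: str, peptide_length: int | None = None) -> str:
    """Flat ``key=value`` run-parameter file (deviations from defaults).

    When flexibility is on, the flexible segment spans the whole peptide,
    so its first/last residue fields need ``peptide_length``.
    """
    for path, label in ((ensemble_file, "ensemble"), (receptor_file, "receptor"),
                        (restraint_file, "restraints")):
        if not path:
            raise CyclopepError(f"missing {label} file path")
    pairs = {
        "protocol": config.protocol_id,
        "structures_0": config.models_it0,
        "structures_1": config.models_it1,
        "waterrefine": config.models_itw,
        "it1_step_multiplier": config.it1_step_multiplier,
        "cyclicpept_2": str(config.cyclic_peptide).lower(),
        "clust_meth": config.clustering_method,
        "clust_cutoff": config.clustering_cutoff,
        "ensemble_max": config.ensemble_max,
        "solvshell": str(config.solvent_shell).lower(),
        "ensemble_file": ensemble_file,
        "receptor_file": receptor_file,
        "restraint_file": restraint_file,
    }
    if config.peptide_fully_flexible:
        if peptide_length is None:
            raise CyclopepError("flexible-segment fields need the peptide length")
        pairs["nfle_2"] = 1
        pairs["start_fle_2_1"] = 1
        pairs["end_fle_2_1"] = peptide_length
    lines = [f"{k}={pairs[k]}" for k in _PARAM_ORDER if k in pairs]
    return "\n".join(lines) + "\n"


def parse_run_params(text: str) -> dict[str, str]:
    """Parse a run-parameter file back into a key->value dict."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise CyclopepError(f"malformed parameter line {lineno}: {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
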