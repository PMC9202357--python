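"""PDB v3 reading and writing for :class:`~cyclopep.core.Conformation`.

The reader/writer pair handles exactly the conventions this toolkit needs —
fixed-column ATOM/HETATM records, MODEL/ENDMDL ensembles, insertion codes,
altloc collapse by occupancy — and guarantees that files written by the
package survive a read→write round trip byte-identically.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .core import Conformation, CyclopepError

__all__ = ["read_pdb", "read_ensemble", "write_pdb", "pdb_string"]

_RECORDS = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise CyclopepError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not name:
        raise CyclopepError(f"malformed ATOM/HETATM record at line {lineno}: empty atom name")
    if not element:
        # fall back on the PDB name convention: element in columns 13-14
        element = name[0] if name[0].isalpha() else name[1]
    return dict(name=name, altloc=altloc.strip(), resname=resname, chain=chain,
                resid=resid, icode=icode, xyz=(x, y, z), occ=occ, bfac=bfac,
                element=element, het=line.startswith("HETATM"))


def _collapse_altlocs(atoms: list[dict]) -> list[dict]:
    """Keep the highest-occupancy altloc of each atom; warn if any dropped."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    dropped = 0
    for i, a in enumerate(atoms):
        key = (a["chain"], a["resid"], a["icode"], a["name"])
        if key not in best:
            best[key] = i
            order.append(key)
        else:
            dropped += 1
            if a["occ"] > atoms[best[key]]["occ"]:
                best[key] = i
    if dropped:
        warnings.warn(f"collapsed {dropped} alternate-location atoms "
                      "(kept highest occupancy)", stacklevel=3)
    return [atoms[best[k]] for k in order]


def _to_conformation(atoms: list[dict]) -> Conformation:
    if any(a["altloc"] for a in atoms):
        atoms = _collapse_altlocs(atoms)
    return Conformation(
        resid=np.array([a["resid"] for a in atoms]),
        resname=np.array([a["resname"] for a in atoms]),
        atom_name=np.array([a["name"] for a in atoms]),
        element=np.array([a["element"] for a in atoms]),
        coords=np.array([a["xyz"] for a in atoms]),
        chain=np.array([a["chain"] for a in atoms], dtype="U1"),
        het=np.array([a["het"] for a in atoms]),
        occupancy=np.array([a["occ"] for a in atoms]),
        bfactor=np.array([a["bfac"] for a in atoms]),
        icode=np.array([a["icode"] for a in atoms], dtype="U1"),
    )


def read_ensemble(path) -> list[Conformation]:
    """Read a PDB file as a list of models (one per MODEL/ENDMDL block)."""
    models: list[list[dict]] = []
    current: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in _RECORDS:
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
            elif rec.startswith("ENDMDL"):
                models.append(current)
                current = []
    if current:
        models.append(current)
    if not models or all(len(m) == 0 for m in models):
        raise CyclopepError(f"no ATOM/HETATM records found in {path}")
    return [_to_conformation(m) for m in models if m]


def read_pdb(path):
    """Read a PDB file; a single :class:`Conformation`, or a list for ensembles."""
    models = read_ensemble(path)
    return models[0] if len(models) == 1 else models


def _format_name(name: str, element: str) -> str:
    # one-letter elements start in column 14 unless the name fills 4 chars
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(serial: int, conf: Conformation, i: int) -> str:
    rec = "HETATM" if conf.het[i] else "ATOM  "
    name = _format_name(str(conf.atom_name[i]), str(conf.element[i]))
    return (f"{rec}{serial:5d} {name} {conf.resname[i]:<3s} "
            f"{conf.chain[i]:1s}{conf.resid[i]:4d}{conf.icode[i]:1s}   "
            f"{conf.coords[i, 0]:8.3f}{conf.coords[i, 1]:8.3f}{conf.coords[i, 2]:8.3f}"
            f"{conf.occupancy[i]:6.2f}{conf.bfactor[i]:6.2f}          "
            f"{conf.element[i]:>2s}")


def pdb_string(conformations: Conformation | list[Conformation]) -> str:
    """Serialize one model or an ensemble to PDB text."""
    if isinstance(conformations, Conformation):
        models = [conformations]
        multi = False
    else:
        models = list(conformations)
        multi = True
    lines: list[str] = []
    for imodel, conf in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL {imodel:>8d}")
        lines.extend(_atom_line(i + 1, conf, i) for i in range(conf.n_atoms))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(conformations, path) -> None:
    Path(path).write_text(pdb_string(conformations))
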