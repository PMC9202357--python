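"""Model quality assessment: fnat, interface RMSD, CAPRI classes and
success rates.

The fraction of native contacts (fnat) counts the reference complex's
residue–residue interface contacts (any heavy-atom pair within 5 Å, one
residue per side) that a docked model reproduces.  CAPRI peptide-docking
quality tiers follow from fnat with strict inequalities: above 0.8 high,
above 0.5 medium, above 0.2 acceptable, otherwise incorrect.  The
interface RMSD (i-rmsd) — backbone RMSD over reference-interface residues
after superposition on that interface — has its own tier thresholds
(below 0.5/1.0/2.0 Å) and is reported separately, never merged with the
fnat class.

Success rates aggregate per-complex ranked model lists: the
single-structure rate at top-N is the percentage of complexes with at
least one model of the requested tier (or better) among their N
best-ranked models; the cluster rate searches the top four members of the
best N clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .core import Conformation, CyclopepError
from .geometry import rmsd_after_superposition, superpose

__all__ = ["CapriClass", "QualityRecord", "SuccessCurve", "fnat",
           "native_contacts", "i_rmsd", "peptide_rmsd", "capri_classify",
           "capri_classify_irmsd", "single_structure_success",
           "cluster_success", "SINGLE_N", "CLUSTER_N"]

SINGLE_N = (1, 5, 10, 20, 50, 100, 200)
CLUSTER_N = (1, 2, 3, 4)
CONTACT_CUTOFF = 5.0        # Å, heavy-atom contact distance
IRMSD_INTERFACE_CUTOFF = 10.0  # Å, reference-interface residue selection
CLUSTER_TOP_MEMBERS = 4


class CapriClass(IntEnum):
    """Quality tiers, ordered so that ``>=`` means "at least this good"."""

    INCORRECT = 0
    ACCEPTABLE = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def parse(cls, value) -> "CapriClass":
        if isinstance(value, cls):
            return value
        return cls[str(value).upper()]


@dataclass(frozen=True)
class QualityRecord:
    """Per-model assessment: rank by external score, fnat and its CAPRI
    class, plus the separately reported i-rmsd."""

    model_id: str
    rank: int
    f_nat: float
    capri_class: CapriClass
    i_rmsd: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.f_nat <= 1.0:
            raise CyclopepError(f"fnat outside [0, 1]: {self.f_nat}")


@dataclass
class SuccessCurve:
    """Success rate (%) per top-N cut, for one quality level."""

    level: CapriClass
    n_values: tuple[int, ...]
    rates: tuple[float, ...]

    def rate_at(self, n: int) -> float:
        return self.rates[self.n_values.index(n)]


def capri_classify(f_nat: float) -> CapriClass:
    """fnat > 0.8 high, > 0.5 medium, > 0.2 acceptable, else incorrect."""
    if not 0.0 <= f_nat <= 1.0:
        raise CyclopepError(f"fnat outside [0, 1]: {f_nat}")
    if f_nat > 0.8:
        return CapriClass.HIGH
    if f_nat > 0.5:
        return CapriClass.MEDIUM
    if f_nat > 0.2:
        return CapriClass.ACCEPTABLE
    return CapriClass.INCORRECT


def capri_classify_irmsd(i_rmsd_value: float) -> CapriClass:
    """i-rmsd < 0.5 high, < 1.0 medium, < 2.0 acceptable, else incorrect."""
    if i_rmsd_value < 0.5:
        return CapriClass.HIGH
    if i_rmsd_value < 1.0:
        return CapriClass.MEDIUM
    if i_rmsd_value < 2.0:
        return CapriClass.ACCEPTABLE
    return CapriClass.INCORRECT


def native_contacts(receptor: Conformation, peptide: Conformation,
                    cutoff: float = CONTACT_CUTOFF) -> set[tuple[int, int]]:
    """Residue pairs (receptor resid, peptide resid) with any heavy-atom
    pair within ``cutoff``."""
    rmask = receptor.heavy_mask
    pmask = peptide.heavy_mask
    tree = cKDTree(peptide.coords[pmask])
    hits = tree.query_ball_point(receptor.coords[rmask], cutoff)
    p_resid = peptide.resid[pmask]
    pairs = set()
    for r_resid, h in zip(receptor.resid[rmask], hits):
        for k in h:
            pairs.add((int(r_resid), int(p_resid[k])))
    return pairs


def fnat(model: tuple[Conformation, Conformation],
         reference: tuple[Conformation, Conformation],
         cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of the reference's interface contacts present in the model.

    Both arguments are (receptor, peptide) pairs sharing residue numbering
    with the reference.
    """
    ref_contacts = native_contacts(*reference, cutoff)
    if not ref_contacts:
        raise CyclopepError("reference complex has no interface contacts; "
                            "fnat undefined")
    model_contacts = native_contacts(*model, cutoff)
    return len(ref_contacts & model_contacts) / len(ref_contacts)


def _interface_resids(reference: tuple[Conformation, Conformation],
                      cutoff: float) -> tuple[list[int], list[int]]:
    receptor, peptide = reference
    rmask = receptor.heavy_mask
    pmask = peptide.heavy_mask
    rtree = cKDTree(receptor.coords[rmask])
    ptree = cKDTree(peptide.coords[pmask])
    r_hit = ptree.query_ball_point(receptor.coords[rmask], cutoff)
    p_hit = rtree.query_ball_point(peptide.coords[pmask], cutoff)
    r_res = sorted({int(r) for r, h in zip(receptor.resid[rmask], r_hit) if h})
    p_res = sorted({int(r) for r, h in zip(peptide.resid[pmask], p_hit) if h})
    return r_res, p_res


def _backbone_coords(conf: Conformation, resids) -> np.ndarray:
    coords = []
    for resid in resids:
        for name in ("N", "CA", "C", "O"):
            if conf.has_atom(resid, name):
                coords.append(conf.coords[conf.index_of(resid, name)])
    return np.array(coords).reshape(-1, 3)


def i_rmsd(model: tuple[Conformation, Conformation],
           reference: tuple[Conformation, Conformation],
           interface_cutoff: float = IRMSD_INTERFACE_CUTOFF) -> float:
    """Backbone RMSD over reference-interface residues after superposition
    on that interface (10 Å reference cutoff, the CAPRI convention)."""
    r_res, p_res = _interface_resids(reference, interface_cutoff)
    if not r_res or not p_res:
        raise CyclopepError("empty reference interface; i-rmsd undefined")
    ref_xyz = np.vstack([_backbone_coords(reference[0], r_res),
                         _backbone_coords(reference[1], p_res)])
    mod_xyz = np.vstack([_backbone_coords(model[0], r_res),
                         _backbone_coords(model[1], p_res)])
    if ref_xyz.shape != mod_xyz.shape:
        raise CyclopepError("model/reference interface atoms do not match 1:1")
    return rmsd_after_superposition(mod_xyz, ref_xyz)


def peptide_rmsd(model_peptide: Conformation, reference_peptide: Conformation,
                 cyclic_region_only: bool = False,
                 cyclic_region: tuple[int, int] | None = None) -> float:
    """Backbone RMSD between two peptide conformations.

    With ``cyclic_region_only`` the calculation is restricted to residues
    inside ``cyclic_region`` (inclusive resid bounds) — disordered tails
    outside a disulfide macrocycle are excluded this way.
    """
    if cyclic_region_only:
        if cyclic_region is None:
            raise CyclopepError("cyclic_region_only requires cyclic_region bounds")
        lo, hi = cyclic_region
        resids = [r for r in reference_peptide.residue_ids if lo <= r <= hi]
        if not resids:
            raise CyclopepError("cyclic-region mask selects no residues")
    else:
        resids = [int(r) for r in reference_peptide.residue_ids]
    a = _backbone_coords(model_peptide, resids)
    b = _backbone_coords(reference_peptide, resids)
    if a.shape != b.shape or len(a) == 0:
        raise CyclopepError("peptide backbone selections do not match 1:1")
    return rmsd_after_superposition(a, b)


def _best_class(records) -> CapriClass:
    return max((r.capri_class for r in records), default=CapriClass.INCORRECT)


def single_structure_success(per_complex: dict[str, list[QualityRecord]],
                             n_list: tuple[int, ...] = SINGLE_N,
                             level: CapriClass | str = CapriClass.ACCEPTABLE
                             ) -> SuccessCurve:
    """Percentage of complexes with >= 1 model at ``level`` or better
    within the top N ranked models, for each N."""
    if not per_complex:
        raise CyclopepError("no complexes to evaluate")
    level = CapriClass.parse(level)
    rates = []
    for n in n_list:
        hits = 0
        for records in per_complex.values():
            top = [r for r in sorted(records, key=lambda r: (r.rank, r.model_id))
                   if r.rank <= n]
            if _best_class(top) >= level:
                hits += 1
        rates.append(100.0 * hits / len(per_complex))
    return SuccessCurve(level=level, n_values=tuple(n_list), rates=tuple(rates))


def cluster_success(per_complex: dict[str, list[list[QualityRecord]]],
                    n_list: tuple[int, ...] = CLUSTER_N,
                    level: CapriClass | str = CapriClass.ACCEPTABLE
                    ) -> SuccessCurve:
    """Cluster-based success: a complex succeeds at N if any of the top
    four members of any of its best N clusters reaches ``level``.

    Each complex maps to clusters in rank order, each cluster a list of
    members in within-cluster rank order.  Clusters with fewer than four
    members contribute the members they have.
    """
    if not per_complex:
        raise CyclopepError("no complexes to evaluate")
    level = CapriClass.parse(level)
    rates = []
    for n in n_list:
        hits = 0
        for clusters in per_complex.values():
            pool = [r for cluster in clusters[:n]
                    for r in cluster[:CLUSTER_TOP_MEMBERS]]
            if _best_class(pool) >= level:
                hits += 1
        rates.append(100.0 * hits / len(per_complex))
    return SuccessCurve(level=level, n_values=tuple(n_list), rates=tuple(rates))


def quality_table(records: dict[str, list[QualityRecord]]) -> str:
    """Per-model TSV: complex, model, rank, fnat, class, i-rmsd."""
    lines = ["complex\tmodel_id\trank\tfnat\tcapri_class\ti_rmsd"]
    for cpx, recs in records.items():
        for r in sorted(recs, key=lambda r: r.rank):
            irmsd = f"{r.i_rmsd:.3f}" if r.i_rmsd is not None else "NA"
            lines.append(f"{cpx}\t{r.model_id}\t{r.rank}\t{r.f_nat:.3f}\t"
                         f"{r.capri_class.name.lower()}\t{irmsd}")
    return "\n".join(lines) + "\n"


def success_table(curves: list[SuccessCurve]) -> str:
    """Success-rate TSV: level, then one column per top-N cut."""
    if not curves:
        raise CyclopepError("no curves")
    n_values = curves[0].n_values
    lines = ["level\t" + "\t".join(f"top{n}" for n in n_values)]
    for c in curves:
        lines.append(c.level.name.lower() + "\t"
                     + "\t".join(f"{r:.1f}" for r in c.rates))
    return "\n".join(lines) + "\n"
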