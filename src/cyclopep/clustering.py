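"""Pairwise-RMSD conformer clustering and representative selection.

Clustering follows the greedy largest-neighbourhood algorithm (Daura et
al.): at a given RMSD cutoff, the model with the most neighbours forms a
cluster with them, all members are removed, and the procedure repeats.
Every model ends up in exactly one cluster (possibly a singleton).  The
cluster *center* — the member with minimal mean RMSD to its co-members —
serves as the representative conformation.

Ties are broken deterministically by lower model id, making the partition
invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformation, CyclopepError
from .geometry import rmsd_after_superposition

__all__ = ["Cluster", "kabsch_rmsd", "pairwise_rmsd_matrix", "cluster_by_rmsd",
           "select_representatives", "cluster_report"]


@dataclass
class Cluster:
    members: list[int]            # model ids (indices into the model list)
    center: int                   # member with minimal mean RMSD to the rest
    rank: int = 0                 # 1-based, by decreasing population

    @property
    def population(self) -> int:
        return len(self.members)


def kabsch_rmsd(a: Conformation, b: Conformation,
                selection: np.ndarray | None = None) -> float:
    """Minimal RMSD (Å) between two conformations over rigid superposition.

    ``selection`` is a boolean atom mask applied to both; atom counts must
    match one-to-one.
    """
    ca = a.coords if selection is None else a.coords[selection]
    cb = b.coords if selection is None else b.coords[selection]
    if ca.shape != cb.shape:
        raise CyclopepError(
            f"selection size mismatch: {ca.shape[0]} vs {cb.shape[0]} atoms")
    return rmsd_after_superposition(ca, cb)


def pairwise_rmsd_matrix(models: list[Conformation],
                         selection: np.ndarray | None = None) -> np.ndarray:
    coords = [m.coords if selection is None else m.coords[selection] for m in models]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd_after_superposition(coords[i], coords[j])
    return mat


def cluster_by_rmsd(models: list[Conformation], cutoff: float = 2.5,
                    selection: np.ndarray | None = None) -> list[Cluster]:
    """Greedy neighbour-count clustering at an RMSD ``cutoff`` (Å).

    The default 2.5 Å cutoff is the conformer-clustering setting of the
    cyclization protocol.
    """
    if cutoff <= 0:
        raise CyclopepError("RMSD cutoff must be positive")
    if len(models) == 0:
        raise CyclopepError("no models to cluster")
    mat = pairwise_rmsd_matrix(models, selection)
    return cluster_distance_matrix(mat, cutoff)


def cluster_distance_matrix(mat: np.ndarray, cutoff: float,
                            ids: list[int] | None = None) -> list[Cluster]:
    """Greedy clustering of a precomputed symmetric distance matrix.

    ``ids`` are stable model identities used for every tie-break (defaults
    to positional indices); with stable ids the partition is invariant to
    input order.  Members and centers are reported as positions in the
    input list.
    """
    n = mat.shape[0]
    ids = list(range(n)) if ids is None else list(ids)
    remaining = set(range(n))
    clusters: list[Cluster] = []
    within = mat <= cutoff
    while remaining:
        rem = sorted(remaining)
        # neighbour counts among remaining models (self included);
        # ties go to the lower model id
        counts = {i: int(sum(within[i, j] for j in rem)) for i in rem}
        best = max(rem, key=lambda i: (counts[i], -ids[i]))
        members = sorted((j for j in rem if within[best, j]),
                         key=lambda j: ids[j])
        center = _center_of(members, mat, ids)
        clusters.append(Cluster(members=members, center=center))
        remaining -= set(members)
    clusters.sort(key=lambda c: (-c.population, ids[c.center]))
    for rank, c in enumerate(clusters, start=1):
        c.rank = rank
    return clusters


def _center_of(members: list[int], mat: np.ndarray, ids: list[int]) -> int:
    if len(members) == 1:
        return members[0]
    sub = mat[np.ix_(members, members)]
    mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
    # ties broken by lower model id
    order = sorted(range(len(members)),
                   key=lambda k: (mean_rmsd[k], ids[members[k]]))
    return members[order[0]]


def select_representatives(clusters: list[Cluster], models: list[Conformation],
                           max_n: int = 10) -> list[Conformation]:
    """Centers of the ``max_n`` most populated clusters, in rank order.

    Fewer clusters simply yield fewer representatives — the protocol's
    behaviour when a run forms less than 10 clusters.
    """
    reps = []
    for c in sorted(clusters, key=lambda c: c.rank)[:max_n]:
        rep = models[c.center].copy()
        rep.labels["cluster_rank"] = c.rank
        rep.labels["cluster_population"] = c.population
        reps.append(rep)
    return reps


def cluster_report(clusters: list[Cluster]) -> str:
    """TSV cluster table: rank, population, center id, member ids."""
    lines = ["rank\tpopulation\tcenter\tmembers"]
    for c in sorted(clusters, key=lambda c: c.rank):
        lines.append(f"{c.rank}\t{c.population}\t{c.center}\t"
                     + ",".join(str(m) for m in c.members))
    return "\n".join(lines) + "\n"
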