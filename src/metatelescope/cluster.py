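"""OPTICS density clustering of homology-search matches.

Matches are compared by ``1 - fractional identity`` of their pairwise
global alignments; the OPTICS ordering/reachability is computed on that
precomputed metric and flat clusters are cut from the reachability
profile at a fixed threshold (DBSCAN-style extraction). Core distances
use the ``min_pts``-th nearest neighbour *including the point itself*.

Processing order is deterministic: unprocessed points are visited in
ascending id order, and seed-queue ties are broken by id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence as TSequence

import numpy as np

from .align import pairwise_align, fractional_identity
from .seqio import Sequence

INF = math.inf


@dataclass
class DistanceMatrix:
    ids: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")


@dataclass
class OpticsResult:
    ordering: List[str]
    reachability: List[float]
    core_dist: dict
    min_pts: int
    eps: float


@dataclass
class ClusterSet:
    clusters: List[List[str]]
    noise: List[str]


def distance_matrix(seqs: TSequence[Sequence], matrix="BLOSUM62") -> DistanceMatrix:
    """All-against-all alignment-identity distances, ``d = 1 - identity``."""
    seqs = list(seqs)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i].residues == seqs[j].residues:
                continue
            aln = pairwise_align(seqs[i], seqs[j], matrix)
            d[i, j] = d[j, i] = 1.0 - fractional_identity(aln)
    return DistanceMatrix([s.id for s in seqs], d)


def optics(dm: DistanceMatrix, min_pts: int = 5, eps: float = INF) -> OpticsResult:
    """OPTICS ordering and reachability on a precomputed metric.

    With fewer points than ``min_pts`` every core distance is infinite
    and all points are emitted in id order with infinite reachability.
    """
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if eps <= 0:
        raise ValueError("eps must be positive")
    ids = dm.ids
    n = len(ids)
    d = dm.d
    # core distance: min_pts-th nearest neighbour within eps, self included
    core = np.full(n, INF)
    for i in range(n):
        neigh = np.sort(d[i][d[i] <= eps])
        if len(neigh) >= min_pts:
            core[i] = neigh[min_pts - 1]
    id_order = sorted(range(n), key=lambda i: ids[i])
    processed = np.zeros(n, dtype=bool)
    reach = np.full(n, INF)
    ordering: List[int] = []
    out_reach: List[float] = []

    def update(p: int, seeds: dict) -> None:
        if core[p] == INF:
            return
        for q in range(n):
            if processed[q] or d[p, q] > eps:
                continue
            newr = max(core[p], d[p, q])
            if newr < reach[q]:
                reach[q] = newr
                seeds[q] = newr

    for start in id_order:
        if processed[start]:
            continue
        processed[start] = True
        ordering.append(start)
        out_reach.append(INF)
        seeds: dict = {}
        update(start, seeds)
        while seeds:
            q = min(seeds, key=lambda k: (seeds[k], ids[k]))
            del seeds[q]
            processed[q] = True
            ordering.append(q)
            out_reach.append(reach[q])
            update(q, seeds)
    return OpticsResult(
        ordering=[ids[i] for i in ordering],
        reachability=out_reach,
        core_dist={ids[i]: float(core[i]) for i in range(n)},
        min_pts=min_pts,
        eps=eps,
    )


def extract_clusters(
    res: OpticsResult, eps_prime: float = 0.6, min_cluster_size: int = 5
) -> ClusterSet:
    """Cut the reachability profile at ``eps_prime`` into flat clusters.

    A point with reachability above the cut starts a new cluster if it is
    itself core at ``eps_prime`` (it is the cluster's entry point),
    otherwise it is noise. Clusters smaller than ``min_cluster_size``
    are moved to noise.
    """
    if eps_prime > res.eps:
        raise ValueError("eps_prime must not exceed the OPTICS eps")
    clusters: List[List[str]] = []
    noise: List[str] = []
    current: List[str] | None = None
    for pid, r in zip(res.ordering, res.reachability):
        if r > eps_prime:
            if res.core_dist[pid] <= eps_prime:
                current = [pid]
                clusters.append(current)
            else:
                noise.append(pid)
                current = None
        else:
            if current is None:     # unreachable start, should not happen
                current = [pid]
                clusters.append(current)
            else:
                current.append(pid)
    kept: List[List[str]] = []
    for c in clusters:
        if len(c) >= min_cluster_size:
            kept.append(c)
        else:
            noise.extend(c)
    return ClusterSet(clusters=kept, noise=noise)


def cluster_table(cs: ClusterSet) -> str:
    lines = ["sequence_id\tcluster_id"]
    for k, c in enumerate(cs.clusters):
        for pid in c:
            lines.append(f"{pid}\t{k}")
    for pid in cs.noise:
        lines.append(f"{pid}\tnoise")
    return "\n".join(lines) + "\n"


def reachability_table(res: OpticsResult) -> str:
    lines = ["sequence_id\treachability"]
    for pid, r in zip(res.ordering, res.reachability):
        lines.append(f"{pid}\t{'inf' if r == INF else f'{r:.6f}'}")
    return "\n".join(lines) + "\n"
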