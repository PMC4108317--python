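"""Brute-force reference implementations for validation.

These are deliberately naive, unoptimised routines — exhaustive path
enumeration for profile-HMM scores, a literal transcription of the
OPTICS pseudocode, a plain DBSCAN, and a six-frame split-on-stop ORF
enumerator built on Biopython's translator. They share no code with the
production implementations and exist so the fast paths can be checked
against them on small inputs (in the test suite and the acceptance
script).
"""

from __future__ import annotations

import math
from typing import List, Set, Tuple

import numpy as np
from Bio.Seq import Seq

from .phmm import ProfileHMM

INF = math.inf


# ---------------------------------------------------------------------------
# exhaustive profile-HMM path enumeration
# ---------------------------------------------------------------------------


def _successors(hmm: ProfileHMM, state: Tuple[str, int]):
    """Yield (next_state, transition_prob); ('E', -1) is terminal."""
    kind, k = state
    M = hmm.M
    if kind == "M":           # k = 0 is Begin
        nxt = ("E", -1) if k == M else ("M", k + 1)
        yield nxt, hmm.tmm[k]
        yield ("I", k), hmm.tmi[k]
        if k < M:
            yield ("D", k + 1), hmm.tmd[k]
    elif kind == "I":
        nxt = ("E", -1) if k == M else ("M", k + 1)
        yield nxt, hmm.tim[k]
        yield ("I", k), hmm.tii[k]
    else:                     # D
        nxt = ("E", -1) if k == M else ("M", k + 1)
        yield nxt, hmm.tdm[k]
        if k < M:
            yield ("D", k + 1), hmm.tdd[k]


def enumerate_paths(hmm: ProfileHMM, residues: str):
    """All complete state paths emitting exactly ``residues``.

    Returns a list of (path, probability); path elements are strings
    like ``B``, ``M1``, ``I0``, ``D2``, ``E``.
    """
    idx = {c: i for i, c in enumerate(hmm.alphabet)}
    xs = [idx[c] for c in residues]
    L = len(xs)
    out: List[Tuple[List[str], float]] = []

    def walk(state, i, prob, path):
        if prob == 0.0:
            return
        for nxt, p in _successors(hmm, state):
            if p == 0.0:
                continue
            kind, k = nxt
            if kind == "E":
                if i == L:
                    out.append((path + ["E"], prob * p))
            elif kind == "M":
                if i < L:
                    walk(nxt, i + 1, prob * p * hmm.match_emis[k - 1, xs[i]],
                         path + [f"M{k}"])
            elif kind == "I":
                if i < L:
                    walk(nxt, i + 1, prob * p * hmm.ins_emis[k, xs[i]],
                         path + [f"I{k}"])
            else:
                walk(nxt, i, prob * p, path + [f"D{k}"])

    walk(("M", 0), 0, 1.0, ["B"])
    return out


def sequence_probability(hmm: ProfileHMM, residues: str) -> float:
    """P(w | model) by summation over every state path."""
    return sum(p for _, p in enumerate_paths(hmm, residues))


def brute_forward_bits(hmm: ProfileHMM, residues: str) -> float:
    idx = {c: i for i, c in enumerate(hmm.alphabet)}
    null = 1.0
    for c in residues:
        null *= hmm.background[idx[c]]
    return math.log2(sequence_probability(hmm, residues) / null)


def brute_viterbi_bits(hmm: ProfileHMM, residues: str) -> Tuple[float, List[str]]:
    idx = {c: i for i, c in enumerate(hmm.alphabet)}
    null = 1.0
    for c in residues:
        null *= hmm.background[idx[c]]
    paths = enumerate_paths(hmm, residues)
    best_p = max(p for _, p in paths)
    best = [path for path, p in paths if p == best_p]
    return math.log2(best_p / null), best


# ---------------------------------------------------------------------------
# six-frame ORF enumeration
# ---------------------------------------------------------------------------


def six_frame_orfs(
    contig_id: str, residues: str, min_aa: int, table_id: int = 11
) -> Set[Tuple[str, str, int, int, int, str]]:
    """Split-on-stop enumeration of all six frames via Biopython.

    Returns tuples (contig_id, strand, frame, start, end, protein) with
    forward-strand, 0-based half-open coordinates.
    """
    n = len(residues)
    found = set()
    for strand in "+-":
        s = residues if strand == "+" else str(Seq(residues).reverse_complement())
        for frame in range(3):
            n_codons = (n - frame) // 3
            if n_codons <= 0:
                continue
            aa = str(Seq(s[frame:frame + 3 * n_codons]).translate(table=table_id))
            c0 = 0
            while c0 < len(aa):
                c1 = c0
                while c1 < len(aa) and aa[c1] != "*":
                    c1 += 1
                if c1 - c0 >= min_aa:
                    lo = frame + 3 * c0
                    hi = frame + 3 * c1
                    if strand == "+":
                        start, end = lo, hi
                    else:
                        start, end = n - hi, n - lo
                    found.add((contig_id, strand, frame, start, end, aa[c0:c1]))
                c0 = c1 + 1
    return found


# ---------------------------------------------------------------------------
# literal OPTICS transcription and brute DBSCAN
# ---------------------------------------------------------------------------


def optics_reference(
    ids: List[str], d: np.ndarray, min_pts: int, eps: float = INF
) -> Tuple[List[str], List[float]]:
    """A line-by-line transcription of the OPTICS algorithm.

    ExpandClusterOrder with an explicit OrderSeeds list that is re-sorted
    on every pop; core distances include the point itself; unprocessed
    points are visited in ascending id order and seed ties break by id.
    """
    n = len(ids)
    order_index = sorted(range(n), key=lambda i: ids[i])
    processed = [False] * n
    reach: List[float] = [INF] * n
    core: List[float] = [INF] * n
    for p in range(n):
        neighbours = sorted(d[p][q] for q in range(n) if d[p][q] <= eps)
        if len(neighbours) >= min_pts:
            core[p] = neighbours[min_pts - 1]
    ordering: List[str] = []
    out_reach: List[float] = []
    seeds: List[int] = []

    def order_seeds_update(p: int) -> None:
        c_dist = core[p]
        if c_dist == INF:
            return
        for o in range(n):
            if processed[o] or d[p][o] > eps:
                continue
            new_r = max(c_dist, d[p][o])
            if new_r < reach[o]:
                reach[o] = new_r
                if o not in seeds:
                    seeds.append(o)

    for start in order_index:
        if processed[start]:
            continue
        processed[start] = True
        ordering.append(ids[start])
        out_reach.append(INF)
        seeds.clear()
        order_seeds_update(start)
        while seeds:
            seeds.sort(key=lambda o: (reach[o], ids[o]))
            current = seeds.pop(0)
            processed[current] = True
            ordering.append(ids[current])
            out_reach.append(reach[current])
            order_seeds_update(current)
    return ordering, out_reach


def dbscan_reference(
    ids: List[str], d: np.ndarray, eps: float, min_pts: int
) -> Tuple[List[Set[str]], Set[str], Set[str]]:
    """Plain DBSCAN on a precomputed metric.

    Returns (clusters-of-core-points, border ids, noise ids). Border
    points (non-core within eps of some core) are reported separately
    because their cluster assignment is order-dependent in DBSCAN.
    """
    n = len(ids)
    neigh = [set(q for q in range(n) if d[p][q] <= eps) for p in range(n)]
    is_core = [len(neigh[p]) >= min_pts for p in range(n)]
    seen = [False] * n
    clusters: List[Set[str]] = []
    for p in range(n):
        if not is_core[p] or seen[p]:
            continue
        comp = {p}
        stack = [p]
        seen[p] = True
        while stack:
            q = stack.pop()
            for r in neigh[q]:
                if is_core[r] and not seen[r]:
                    seen[r] = True
                    comp.add(r)
                    stack.append(r)
        clusters.append({ids[i] for i in comp})
    border: Set[str] = set()
    noise: Set[str] = set()
    for p in range(n):
        if is_core[p]:
            continue
        if any(is_core[q] for q in neigh[p]):
            border.add(ids[p])
        else:
            noise.add(ids[p])
    return clusters, border, noise
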