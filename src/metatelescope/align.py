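"""Pairwise and progressive multiple protein alignment.

Global (Needleman–Wunsch/Gotoh) alignment with affine gaps: a gap of
length ``k`` costs ``gap_open + k * gap_extend`` (both penalties are
negative numbers). Multiple alignment is progressive: a UPGMA guide tree
built on ``1 - fractional identity`` pairwise distances, with
profile–profile alignment at internal nodes. This is the package's
Clustal-equivalent stage; an externally computed alignment can be
imported with :func:`read_msa` instead.

Traceback ties are broken deterministically: diagonal (substitution)
first, then "up" (gap in the second sequence), then "left".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence as TSequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import Sequence, read_fasta, write_fasta

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0

_NEG = -1e30  # effectively -inf, safe for float arithmetic


def load_matrix(matrix) -> substitution_matrices.Array:
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def _score_lut(mat) -> Tuple[np.ndarray, dict]:
    """Dense lookup table over the matrix alphabet; unknown residues map to X."""
    alpha = mat.alphabet
    idx = {c: i for i, c in enumerate(alpha)}
    lut = np.asarray(mat, dtype=float)
    return lut, idx


def _encode(residues: str, idx: dict) -> np.ndarray:
    x = idx.get("X", 0)
    return np.fromiter((idx.get(c, x) for c in residues), dtype=np.intp, count=len(residues))


@dataclass
class PairwiseAlignment:
    row_a: str
    row_b: str
    score: float
    matrix_name: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        if any(a == "-" == b for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("column gapped in both rows")

    @property
    def n_cols(self) -> int:
        return len(self.row_a)


@dataclass
class Msa:
    """A multiple alignment: ordered ``(id, gapped row)`` pairs."""

    rows: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def degapped(self, i: int) -> str:
        return self.rows[i][1].replace("-", "")


def pairwise_align(
    a: Sequence,
    b: Sequence,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences under affine gaps."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    mat = load_matrix(matrix)
    lut, idx = _score_lut(mat)
    ea, eb = _encode(a.residues, idx), _encode(b.residues, idx)
    S = lut[np.ix_(ea, eb)]  # (n, m) substitution scores
    M, X, Y = _gotoh(S, gap_open, gap_extend)
    row_a, row_b = _traceback(a.residues, b.residues, S, M, X, Y, gap_open, gap_extend)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    name = matrix if isinstance(matrix, str) else "custom"
    return PairwiseAlignment(row_a, row_b, score, name, gap_open, gap_extend)


def _gotoh(S: np.ndarray, go: float, ge: float):
    """Row-vectorized affine-gap DP.

    M[i,j]: best ending in a substitution; X[i,j]: ending with a gap in
    the second sequence (consumes row i); Y[i,j]: gap in the first
    (consumes column j).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = go + ge * j
    i = np.arange(1, n + 1)
    X[1:, 0] = go + ge * i
    for r in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[r - 1], X[r - 1]), Y[r - 1])
        M[r, 1:] = S[r - 1] + best_prev[:-1]
        X[r, 1:] = np.maximum(M[r - 1, 1:] + go + ge, X[r - 1, 1:] + ge)
        X[r, 0] = go + ge * r
        # Y within the row: gap openings from M/X at any j' < j, extensions fold
        # into a running max of (z[j'] - ge*j').
        z = np.maximum(M[r], X[r])
        run = np.maximum.accumulate(z[:-1] - ge * np.arange(m))
        Y[r, 1:] = go + ge * j + run
    return M, X, Y


def _traceback(sa, sb, S, M, X, Y, go, ge):
    i, j = len(sa), len(sb)
    scores = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(scores))  # ties: M (diagonal) < X (up) < Y (left)
    ra: List[str] = []
    rb: List[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # substitution
            ra.append(sa[i - 1])
            rb.append(sb[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # gap in b, consume a
            ra.append(sa[i - 1])
            rb.append("-")
            if i == 1 and j == 0:
                state = 0
                i = 0
            elif M[i - 1, j] + go + ge >= X[i - 1, j] + ge - eps:
                state = 0
                i -= 1
            else:
                i -= 1
        else:  # gap in a, consume b
            ra.append("-")
            rb.append(sb[j - 1])
            cand = (M[i, j - 1] + go + ge, X[i, j - 1] + go + ge, Y[i, j - 1] + ge)
            state = int(np.argmax(cand))
            j -= 1
        if i == 0 and j == 0:
            break
    return "".join(reversed(ra)), "".join(reversed(rb))


def identity_similarity(
    aln: PairwiseAlignment, matrix=DEFAULT_MATRIX
) -> Tuple[float, float]:
    """Percent identity and percent similarity over all alignment columns.

    Identity counts columns with equal residues; similarity additionally
    counts residue pairs with a positive substitution score (the "+"
    convention). Gapped columns stay in the denominator.
    """
    mat = load_matrix(matrix)
    ident = simil = 0
    for x, y in zip(aln.row_a, aln.row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            simil += 1
        elif float(mat[x, y]) > 0:
            simil += 1
    n = aln.n_cols
    return 100.0 * ident / n, 100.0 * simil / n


def fractional_identity(aln: PairwiseAlignment) -> float:
    ident, _ = identity_similarity(aln)
    return ident / 100.0


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------


def _profile_freqs(rows: List[str], idx: dict) -> np.ndarray:
    """Per-column residue frequencies over the matrix alphabet.

    Gaps contribute no mass, so heavily gapped columns score near zero
    against everything.
    """
    K = len(idx)
    n_cols = len(rows[0])
    F = np.zeros((n_cols, K))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                F[c, idx.get(ch, idx.get("X", 0))] += 1.0
    return F / len(rows)


def _profile_align(rows_a: List[str], rows_b: List[str], lut, idx, go, ge):
    Fa = _profile_freqs(rows_a, idx)
    Fb = _profile_freqs(rows_b, idx)
    S = Fa @ lut @ Fb.T
    M, X, Y = _gotoh(S, go, ge)
    # reuse the pairwise traceback on pseudo-sequences of column indices
    pa = "".join(chr(33 + 0) for _ in rows_a[0])  # placeholders; only gaps matter
    pb = "".join(chr(33 + 0) for _ in rows_b[0])
    ta, tb = _traceback(pa, pb, S, M, X, Y, go, ge)
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ib = 0
    for ca, cb in zip(ta, tb):
        if ca != "-":
            for k, row in enumerate(rows_a):
                new_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                new_a[k] += "-"
        if cb != "-":
            for k, row in enumerate(rows_b):
                new_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                new_b[k] += "-"
    return new_a, new_b


def progressive_msa(
    seqs: TSequence[Sequence],
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Msa:
    """Progressive multiple alignment with a UPGMA guide tree.

    Deterministic for a fixed input order; the output row order equals
    the input order.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Msa([(seqs[0].id, seqs[0].residues)])
    mat = load_matrix(matrix)
    lut, idx = _score_lut(mat)
    n = len(seqs)
    if len({s.id for s in seqs}) != n:
        raise ValueError("duplicate sequence ids in MSA input")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(seqs[i], seqs[j], mat, gap_open, gap_extend)
            D[i, j] = D[j, i] = 1.0 - fractional_identity(aln)
    Z = linkage(squareform(D, checks=False), method="average")
    # nodes: 0..n-1 leaves, then n..2n-2 merges in Z order
    nodes: dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        ids_a, rows_a = nodes.pop(ia)
        ids_b, rows_b = nodes.pop(ib)
        na, nb = _profile_align(rows_a, rows_b, lut, idx, gap_open, gap_extend)
        nodes[n + k] = (ids_a + ids_b, na + nb)
    order, rows = nodes.popitem()[1]
    by_input = dict(zip(order, rows))
    return Msa([(seqs[i].id, by_input[i]) for i in range(n)])


def sum_of_pairs(msa: Msa, matrix=DEFAULT_MATRIX, gap_open=DEFAULT_GAP_OPEN,
                 gap_extend=DEFAULT_GAP_EXTEND) -> float:
    """Sum-of-pairs substitution score of an MSA (gap columns score the
    affine penalty per contiguous gap run within each row pair)."""
    mat = load_matrix(matrix)
    total = 0.0
    rows = [r for _, r in msa.rows]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            total += _pair_sp(rows[i], rows[j], mat, gap_open, gap_extend)
    return total


def _pair_sp(ra: str, rb: str, mat, go: float, ge: float) -> float:
    score = 0.0
    in_gap = False
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score += ge + (0.0 if in_gap else go)
            in_gap = True
        else:
            score += float(mat[x, y])
            in_gap = False
    return score


def read_msa(path: str | Path) -> Msa:
    """Import an aligned FASTA (gaps as ``-``), e.g. from a production aligner."""
    seqs = read_fasta(path, alphabet="protein")
    return Msa([(s.id, s.residues) for s in seqs])


def write_msa(msa: Msa, path: str | Path) -> None:
    write_fasta(
        [Sequence(i, row, alphabet="protein") for i, row in msa.rows], path
    )
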