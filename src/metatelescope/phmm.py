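"""Profile hidden Markov models: building, scoring, calibration, search.

The model is a Plan7-style linear profile: a Begin state, per-node
Match/Insert/Delete states, and an End state. Scoring is glocal — the
whole model against the whole target sequence — in log2-odds against an
i.i.d. background, computed entirely in log space (log-sum-exp for the
forward algorithm, max for Viterbi). Insert states emit the background
distribution, so insert columns are penalised only through transitions.

E-values come from an explicit Gumbel (extreme value) calibration: the
model is scored against random background sequences and a Gumbel is
fitted to the scores by maximum likelihood, mirroring the classic
empirical calibration of profile search tools.

Transition layout (node 0 is Begin; node M's match transition goes to End):

    tmm[k] : M_k -> M_{k+1}   (k = M: M_M -> End)
    tmi[k] : M_k -> I_k
    tmd[k] : M_k -> D_{k+1}   (tmd[M] = 0, no delete after the last node)
    tim[k] : I_k -> M_{k+1}   (k = M: I_M -> End)
    tii[k] : I_k -> I_k
    tdm[k] : D_k -> M_{k+1}   (k = M: D_M -> End; tdm[0] unused)
    tdd[k] : D_k -> D_{k+1}   (tdd[0] = tdd[M] = 0)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence as TSequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .align import Msa
from .seqio import Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Standard amino-acid background frequencies (BLOSUM62 marginals), in
# AMINO_ACIDS order.
BACKGROUND = np.array([
    0.0740, 0.0250, 0.0540, 0.0540, 0.0470, 0.0740, 0.0260, 0.0680,
    0.0580, 0.0990, 0.0250, 0.0450, 0.0390, 0.0340, 0.0520, 0.0570,
    0.0510, 0.0730, 0.0130, 0.0320,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

LN2 = math.log(2.0)


@dataclass
class ProfileHMM:
    """A calibratable linear profile HMM over a protein (or reduced) alphabet."""

    name: str
    match_emis: np.ndarray          # (M, K)
    ins_emis: np.ndarray            # (M+1, K)
    tmm: np.ndarray                 # (M+1,)
    tmi: np.ndarray
    tmd: np.ndarray
    tim: np.ndarray
    tii: np.ndarray
    tdm: np.ndarray
    tdd: np.ndarray
    background: np.ndarray          # (K,)
    alphabet: str = AMINO_ACIDS
    calib: Optional[Tuple[float, float]] = None   # (mu bits, lambda per bit)
    len_model: Optional[Tuple[Tuple[float, ...], Tuple[float, ...]]] = None
    """Expected background score as a function of target length.

    Glocal bit scores trend strongly with target length (every residue
    beyond the model length pays an insert transition, every missing one
    a delete), so the calibration estimates the conditional mean
    background score in length bins and fits the Gumbel to the
    residuals; E-values subtract the interpolated trend from the query
    score. Stored as ``(bin centres, bin means)``; ``None`` means no
    correction (fixed-length calibration)."""

    @property
    def M(self) -> int:
        return self.match_emis.shape[0]

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def validate(self, atol: float = 1e-9) -> None:
        M = self.M
        if M < 1:
            raise ValueError("model needs at least one match state")
        for rows in (self.match_emis, self.ins_emis):
            if not np.allclose(rows.sum(axis=1), 1.0, atol=atol):
                raise ValueError("emission rows must sum to 1")
            if np.any(rows <= 0):
                raise ValueError("emission probabilities must be positive")
        out_m = self.tmm + self.tmi + self.tmd
        if not np.allclose(out_m, 1.0, atol=atol):
            raise ValueError("match-state transitions must sum to 1")
        if not np.allclose(self.tim + self.tii, 1.0, atol=atol):
            raise ValueError("insert-state transitions must sum to 1")
        out_d = (self.tdm + self.tdd)[1:]
        if not np.allclose(out_d, 1.0, atol=atol):
            raise ValueError("delete-state transitions must sum to 1")
        if self.tmd[M] != 0 or self.tdd[M] != 0:
            raise ValueError("no delete state beyond the last node")
        if self.calib is not None and self.calib[1] <= 0:
            raise ValueError("calibration lambda must be positive")


@dataclass(frozen=True)
class Hit:
    """One above-threshold target of a profile search."""

    model: str
    target: str
    bit_score: float
    evalue: float
    target_len: int


@dataclass
class SearchParams:
    evalue_threshold: float = 1e-6
    db_size: Optional[int] = None   # default: number of sequences searched

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

_COND_CACHE: dict[str, np.ndarray] = {}


def conditional_matrix(alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Substitution probabilities P(b | a) derived from BLOSUM62:
    row-normalised ``background_b * 2^(S_ab / 2)``."""
    if alphabet not in _COND_CACHE:
        blosum = substitution_matrices.load("BLOSUM62")
        K = len(alphabet)
        C = np.zeros((K, K))
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                C[i, j] = BACKGROUND[j] * 2.0 ** (float(blosum[a, b]) / 2.0)
            C[i] /= C[i].sum()
        _COND_CACHE[alphabet] = C
    return _COND_CACHE[alphabet]


def henikoff_weights(rows: List[str]) -> np.ndarray:
    """Position-based sequence weights, normalised to sum to the row count.

    Each column distributes one unit of weight equally among its distinct
    residue types, and within a type equally among the sequences carrying
    it; gaps receive nothing.
    """
    n = len(rows)
    w = np.zeros(n)
    n_cols = len(rows[0])
    for c in range(n_cols):
        col = [r[c] for r in rows]
        residues = [x for x in col if x != "-"]
        if not residues:
            continue
        types: dict[str, int] = {}
        for x in residues:
            types[x] = types.get(x, 0) + 1
        r = len(types)
        for i, x in enumerate(col):
            if x != "-":
                w[i] += 1.0 / (r * types[x])
    if w.sum() == 0:
        w[:] = 1.0
    return w * n / w.sum()


def build_profile(
    msa: Msa,
    occupancy: float = 0.5,
    weighting: str = "henikoff",
    pseudocount: float = 1.0,
    name: str = "profile",
    alphabet: str = AMINO_ACIDS,
    background: Optional[np.ndarray] = None,
    prior: str = "laplace",
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Columns whose non-gap fraction is at least ``occupancy`` become match
    states. With the default flat prior, emissions are Laplace-smoothed
    weighted counts, ``(counts + pseudocount) / (total + K * pseudocount)``.
    ``prior="blosum"`` instead distributes the same pseudocount mass
    (``K * pseudocount``) over residues in proportion to the
    BLOSUM62-conditional substitution probabilities of the observed
    column composition, which markedly improves sensitivity to diverged
    homologs and is what the search pipeline uses. Transitions are
    estimated from the weighted match/insert/delete events of each row
    with a flat pseudocount. Insert states emit the background.
    """
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    rows = [r for _, r in msa.rows]
    n, n_cols = len(rows), msa.n_cols
    K = len(alphabet)
    aa_index = {c: i for i, c in enumerate(alphabet)}
    bg = BACKGROUND.copy() if background is None else np.asarray(background, float)

    nongap = np.array([sum(r[c] != "-" for r in rows) / n for c in range(n_cols)])
    is_match = nongap >= occupancy
    M = int(is_match.sum())
    if M == 0:
        raise ValueError("no match columns")

    if weighting == "henikoff":
        w = henikoff_weights(rows)
    elif weighting == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    counts = np.zeros((M, K))
    match_node = np.cumsum(is_match)  # column -> node index (1-based at match cols)
    for i, row in enumerate(rows):
        for c in range(n_cols):
            if is_match[c] and row[c] != "-":
                a = aa_index.get(row[c])
                if a is None:   # ambiguity (X): spread over the background
                    counts[match_node[c] - 1] += w[i] * bg
                else:
                    counts[match_node[c] - 1, a] += w[i]
    totals = counts.sum(axis=1, keepdims=True)
    if prior == "laplace":
        match_emis = (counts + pseudocount) / (totals + K * pseudocount)
    elif prior == "blosum":
        if alphabet != AMINO_ACIDS:
            raise ValueError("blosum prior requires the amino-acid alphabet")
        mix = (counts / totals) @ conditional_matrix(alphabet)
        match_emis = (counts + K * pseudocount * mix) / (totals + K * pseudocount)
    else:
        raise ValueError(f"unknown prior {prior!r}")

    # transition event counts
    cmm = np.zeros(M + 1)
    cmi = np.zeros(M + 1)
    cmd = np.zeros(M + 1)
    cim = np.zeros(M + 1)
    cii = np.zeros(M + 1)
    cdm = np.zeros(M + 1)
    cdd = np.zeros(M + 1)
    for i, row in enumerate(rows):
        state, node = "M", 0      # Begin behaves like M_0
        for c in range(n_cols):
            if is_match[c]:
                nxt = "M" if row[c] != "-" else "D"
                _count(state, nxt, node, w[i], cmm, cmi, cmd, cim, cii, cdm, cdd)
                state, node = nxt, node + 1
            elif row[c] != "-":
                _count(state, "I", node, w[i], cmm, cmi, cmd, cim, cii, cdm, cdd)
                state = "I"
        _count(state, "E", node, w[i], cmm, cmi, cmd, cim, cii, cdm, cdd)

    pc = pseudocount
    tmm = np.zeros(M + 1)
    tmi = np.zeros(M + 1)
    tmd = np.zeros(M + 1)
    tim = np.zeros(M + 1)
    tii = np.zeros(M + 1)
    tdm = np.zeros(M + 1)
    tdd = np.zeros(M + 1)
    for k in range(M + 1):
        legal_d = k < M     # M_k -> D_{k+1} exists only before the last node
        tot = cmm[k] + cmi[k] + cmd[k] + pc * (3 if legal_d else 2)
        tmm[k] = (cmm[k] + pc) / tot
        tmi[k] = (cmi[k] + pc) / tot
        tmd[k] = (cmd[k] + pc) / tot if legal_d else 0.0
        tot_i = cim[k] + cii[k] + 2 * pc
        tim[k] = (cim[k] + pc) / tot_i
        tii[k] = (cii[k] + pc) / tot_i
        if 1 <= k < M:
            tot_d = cdm[k] + cdd[k] + 2 * pc
            tdm[k] = (cdm[k] + pc) / tot_d
            tdd[k] = (cdd[k] + pc) / tot_d
    tdm[M] = 1.0

    ins_emis = np.tile(bg, (M + 1, 1))
    hmm = ProfileHMM(
        name=name, match_emis=match_emis, ins_emis=ins_emis,
        tmm=tmm, tmi=tmi, tmd=tmd, tim=tim, tii=tii, tdm=tdm, tdd=tdd,
        background=bg, alphabet=alphabet,
    )
    hmm.validate()
    return hmm


def _count(state, nxt, node, w, cmm, cmi, cmd, cim, cii, cdm, cdd):
    if state == "M":
        if nxt in ("M", "E"):
            cmm[node] += w
        elif nxt == "I":
            cmi[node] += w
        else:
            cmd[node] += w
    elif state == "I":
        if nxt in ("M", "E"):
            cim[node] += w
        elif nxt == "I":
            cii[node] += w
        else:
            # I -> D is not representable in this architecture; attribute the
            # event to I -> M -> ... by counting it as an exit to match.
            cim[node] += w
    else:  # D
        if nxt in ("M", "E"):
            cdm[node] += w
        elif nxt == "D":
            cdd[node] += w
        else:
            cdm[node] += w  # D -> I folded into the delete exit


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _encode(hmm: ProfileHMM, residues: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(hmm.alphabet)}
    K = hmm.K
    return np.fromiter(
        (idx.get(c, K) for c in residues), dtype=np.intp, count=len(residues)
    )


def _emission_odds(hmm: ProfileHMM):
    """Log emission odds with an extra column for ambiguity ('X' scores 0)."""
    lbg = _log(hmm.background)
    em = _log(hmm.match_emis) - lbg           # (M, K)
    ei = _log(hmm.ins_emis) - lbg             # (M+1, K)
    em = np.concatenate([em, np.zeros((hmm.M, 1))], axis=1)
    ei = np.concatenate([ei, np.zeros((hmm.M + 1, 1))], axis=1)
    return em, ei


def forward_scores(hmm: ProfileHMM, seqs: TSequence[Sequence]) -> np.ndarray:
    """Forward log2-odds bit scores for a batch of sequences.

    Sequences are grouped by length and each group is scored with one
    vectorised dynamic-programming sweep.
    """
    seqs = list(seqs)
    scores = np.empty(len(seqs))
    by_len: dict[int, List[int]] = {}
    for i, s in enumerate(seqs):
        if not s.residues:
            raise ValueError(f"empty sequence {s.id!r}")
        by_len.setdefault(len(s.residues), []).append(i)
    em, ei = _emission_odds(hmm)
    trans = _log_transitions(hmm)
    for L, idxs in by_len.items():
        X = np.stack([_encode(hmm, seqs[i].residues) for i in idxs])
        scores[np.asarray(idxs)] = _forward_batch(em, ei, trans, X) / LN2
    return scores


def forward_score(hmm: ProfileHMM, seq: Sequence) -> float:
    """log2( P(w | model) / P(w | background) ) via the forward algorithm."""
    return float(forward_scores(hmm, [seq])[0])


def _log_transitions(hmm: ProfileHMM):
    return tuple(
        _log(getattr(hmm, t)) for t in ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd")
    )


def _forward_batch(em, ei, trans, X) -> np.ndarray:
    """Forward log-odds (nats) for a (B, L) batch of encoded sequences."""
    ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd = trans
    M = em.shape[0]
    B, L = X.shape
    NEG = -np.inf
    vM = np.full((B, M + 1), NEG)
    vM[:, 0] = 0.0                      # Begin
    vI = np.full((B, M + 1), NEG)
    vD = _delete_row_sum(vM, ltmd, ltdd, M)
    for i in range(L):
        x = X[:, i]
        e_m = em[:, x].T                # (B, M)
        e_i = ei[:, x].T                # (B, M+1)
        prev = np.logaddexp(
            np.logaddexp(vM[:, :-1] + ltmm[:M], vI[:, :-1] + ltim[:M]),
            vD[:, :-1] + ltdm[:M],
        )
        nM = np.full((B, M + 1), NEG)
        nM[:, 1:] = e_m + prev
        vI = e_i + np.logaddexp(vM + ltmi, vI + ltii)
        vM = nM
        vD = _delete_row_sum(vM, ltmd, ltdd, M)
    return _lse3(vM[:, M] + ltmm[M], vI[:, M] + ltim[M], vD[:, M] + ltdm[M])


def _delete_row_sum(vM, ltmd, ltdd, M):
    """vD[k] = logsum over entry points M_j -> D_{j+1} -> ... -> D_k."""
    B = vM.shape[0]
    vD = np.full((B, M + 1), -np.inf)
    if M == 0:
        return vD
    C = np.concatenate([[0.0], np.cumsum(ltdd[1:M])])      # C[j] = sum ltdd[1..j]
    t = vM[:, :M] + ltmd[:M] - C
    acc = np.logaddexp.accumulate(t, axis=1)
    vD[:, 1:] = acc + C
    return vD


def _lse3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


def viterbi(hmm: ProfileHMM, seq: Sequence) -> Tuple[float, List[str]]:
    """Most probable state path and its log2-odds score.

    Ties are broken preferring Match, then Insert, then Delete
    predecessors, making the decoded path deterministic.
    """
    if not seq.residues:
        raise ValueError("empty sequence")
    em, ei = _emission_odds(hmm)
    ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd = _log_transitions(hmm)
    M = hmm.M
    x = _encode(hmm, seq.residues)
    L = len(x)
    NEG = -np.inf
    vM = np.full((L + 1, M + 1), NEG)
    vI = np.full((L + 1, M + 1), NEG)
    vD = np.full((L + 1, M + 1), NEG)
    pM = np.zeros((L + 1, M + 1), dtype=np.int8)   # 0=M, 1=I, 2=D predecessor
    pI = np.zeros((L + 1, M + 1), dtype=np.int8)
    pD = np.zeros((L + 1, M + 1), dtype=np.int8)
    vM[0, 0] = 0.0
    for k in range(1, M + 1):
        cands = (vM[0, k - 1] + ltmd[k - 1], vD[0, k - 1] + ltdd[k - 1])
        best = 0 if cands[0] >= cands[1] else 1
        vD[0, k] = cands[best]
        pD[0, k] = 0 if best == 0 else 2
    for i in range(1, L + 1):
        e_m = em[:, x[i - 1]]
        e_i = ei[:, x[i - 1]]
        for k in range(1, M + 1):
            cands = (
                vM[i - 1, k - 1] + ltmm[k - 1],
                vI[i - 1, k - 1] + ltim[k - 1],
                vD[i - 1, k - 1] + ltdm[k - 1],
            )
            b = _argmax_first(cands)
            vM[i, k] = e_m[k - 1] + cands[b]
            pM[i, k] = b
        for k in range(M + 1):
            cands = (vM[i - 1, k] + ltmi[k], vI[i - 1, k] + ltii[k])
            b = _argmax_first(cands)
            vI[i, k] = e_i[k] + cands[b]
            pI[i, k] = b
        for k in range(1, M + 1):
            cands = (vM[i, k - 1] + ltmd[k - 1], vD[i, k - 1] + ltdd[k - 1])
            b = _argmax_first(cands)
            vD[i, k] = cands[b]
            pD[i, k] = 0 if b == 0 else 2
    finals = (vM[L, M] + ltmm[M], vI[L, M] + ltim[M], vD[L, M] + ltdm[M])
    b = _argmax_first(finals)
    score = finals[b] / LN2
    # path reconstruction
    path = ["E"]
    i, k, state = L, M, b
    while not (state == 0 and k == 0):
        if state == 0:
            path.append(f"M{k}")
            prev = pM[i, k]
            i, k, state = i - 1, k - 1, prev
        elif state == 1:
            path.append(f"I{k}")
            prev = pI[i, k]
            i, state = i - 1, prev
        else:
            path.append(f"D{k}")
            prev = pD[i, k]
            k, state = k - 1, prev
    path.append("B")
    return float(score), path[::-1]


def _argmax_first(cands) -> int:
    best, bv = 0, cands[0]
    for j in range(1, len(cands)):
        if cands[j] > bv:
            best, bv = j, cands[j]
    return best


def viterbi_score(hmm: ProfileHMM, seq: Sequence) -> float:
    return viterbi(hmm, seq)[0]


# ---------------------------------------------------------------------------
# calibration and E-values
# ---------------------------------------------------------------------------


def sample_background(
    hmm: ProfileHMM, n: int, lengths: np.ndarray, rng: np.random.Generator
) -> List[Sequence]:
    ls = np.asarray(lengths)
    picked = rng.choice(ls, size=n) if ls.ndim else np.full(n, int(ls))
    alpha = np.array(list(hmm.alphabet))
    return [
        Sequence(f"bg{i}", "".join(rng.choice(alpha, size=int(l), p=hmm.background)))
        for i, l in enumerate(picked)
    ]


def _length_trend(
    lengths: np.ndarray, scores: np.ndarray, nbins: int = 12
) -> Tuple[np.ndarray, np.ndarray]:
    """Conditional mean background score per length bin (quantile bins,
    or exact lengths when few are distinct)."""
    uniq = np.unique(lengths)
    centers: List[float] = []
    means: List[float] = []
    if len(uniq) <= nbins:
        for u in uniq:
            m = lengths == u
            centers.append(float(u))
            means.append(float(scores[m].mean()))
    else:
        edges = np.quantile(lengths, np.linspace(0.0, 1.0, nbins + 1))
        for i in range(nbins):
            m = (lengths >= edges[i]) & (
                lengths <= edges[i + 1] if i == nbins - 1 else lengths < edges[i + 1]
            )
            if m.sum() >= 3:
                centers.append(float(lengths[m].mean()))
                means.append(float(scores[m].mean()))
    return np.asarray(centers), np.asarray(means)


def fit_gumbel(scores: np.ndarray) -> Tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda = 1/scale)."""
    scores = np.asarray(scores, float)
    if scores.std() < 1e-12:
        raise ValueError("degenerate score variance; cannot calibrate")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def fit_gumbel_tail(
    scores: np.ndarray, tail_frac: float = 0.10, min_tail: int = 50
) -> Tuple[float, float]:
    """Gumbel parameters fitted to the upper tail of the score sample.

    E-values live in the extreme right tail, where the EVD approximation
    actually applies; a full-sample fit lets the bulk of the distribution
    dictate lambda and grossly overestimates tail mass when the bulk is
    wider than the tail (as glocal forward scores are). Here lambda is
    the maximum-likelihood exponential rate of the exceedances over the
    ``1 - tail_frac`` quantile, re-expressed as a Gumbel ``(mu, lambda)``
    so that ``P(S > s) ~ exp(-lambda (s - mu))`` matches the observed
    exceedance fraction at the threshold.
    """
    scores = np.sort(np.asarray(scores, float))
    n = len(scores)
    if scores.std() < 1e-12:
        raise ValueError("degenerate score variance; cannot calibrate")
    k = min(n - 1, max(min_tail, int(round(n * tail_frac))))
    u = scores[-k - 1]
    exc = scores[-k:] - u
    mean_exc = float(exc.mean())
    if mean_exc <= 0:
        raise ValueError("degenerate score tail; cannot calibrate")
    lam = 1.0 / mean_exc
    frac = k / n
    mu = u + math.log(frac) / lam
    return float(mu), float(lam)


def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    len_dist: Optional[np.ndarray | int] = None,
    seed: int = 0,
) -> Tuple[float, float]:
    """Fit the Gumbel null of a model by scoring random background sequences.

    ``len_dist`` is an integer (fixed length), an array of lengths to
    resample (typically the target database's lengths), or None for the
    model length. The fitted ``(mu, lambda)`` is stored on the model.
    """
    if n_samples < 200:
        raise ValueError("n_samples must be >= 200 for a stable tail fit")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(hmm.M if len_dist is None else len_dist)
    seqs = sample_background(hmm, n_samples, lengths, rng)
    scores = forward_scores(hmm, seqs)
    drawn = np.array([len(s.residues) for s in seqs], dtype=float)
    if np.unique(drawn).size > 1:
        centers, means = _length_trend(drawn, scores)
        hmm.len_model = (tuple(centers), tuple(means))
        scores = scores - np.interp(drawn, centers, means)
    else:
        hmm.len_model = None
    mu, lam = fit_gumbel_tail(scores)
    hmm.calib = (mu, lam)
    return mu, lam


def evalue(
    hmm: ProfileHMM, bit_score: float, db_size: int,
    target_len: Optional[int] = None,
) -> float:
    """Expected chance hits at this score: ``N * P(S >= s)`` under the
    fitted Gumbel, after subtracting the length-expected background
    score when the model carries a length correction and the target
    length is known."""
    if hmm.calib is None:
        raise ValueError(f"model {hmm.name!r} is not calibrated")
    mu, lam = hmm.calib
    s = float(bit_score)
    if hmm.len_model is not None and target_len is not None:
        centers, means = hmm.len_model
        s -= float(np.interp(target_len, centers, means))
    with np.errstate(over="ignore"):
        pval = -np.expm1(-np.exp(-lam * (s - mu)))
    return float(db_size * pval)


def search(
    hmm: ProfileHMM, db: TSequence[Sequence], params: SearchParams | None = None
) -> List[Hit]:
    """Score every database sequence and return hits at the E-value
    threshold, sorted by ascending E-value (ties by target id)."""
    params = params or SearchParams()
    db = list(db)
    if not db:
        warnings.warn(f"empty database for model {hmm.name!r}", stacklevel=2)
        return []
    if hmm.calib is None:
        raise ValueError(f"model {hmm.name!r} is not calibrated")
    n = params.db_size if params.db_size is not None else len(db)
    scores = forward_scores(hmm, db)
    hits = []
    for s, sc in zip(db, scores):
        ev = evalue(hmm, sc, n, target_len=len(s.residues))
        if ev <= params.evalue_threshold:
            hits.append(Hit(hmm.name, s.id, float(sc), ev, len(s.residues)))
    hits.sort(key=lambda h: (h.evalue, h.target))
    return hits


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------


def save_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"NAME\t{hmm.name}\nALPH\t{hmm.alphabet}\nM\t{hmm.M}\n")
        if hmm.calib is not None:
            fh.write(f"CALIB\t{hmm.calib[0]!r}\t{hmm.calib[1]!r}\n")
        if hmm.len_model is not None:
            centers, means = hmm.len_model
            fh.write("LENMODEL\t" + ",".join(repr(float(c)) for c in centers)
                     + "\t" + ",".join(repr(float(m)) for m in means) + "\n")
        def table(tag, arr):
            fh.write(tag + "\n")
            for row in np.atleast_2d(arr):
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        table("BACKGROUND", hmm.background)
        table("MATCH_EMIS", hmm.match_emis)
        table("INS_EMIS", hmm.ins_emis)
        trans = np.stack([hmm.tmm, hmm.tmi, hmm.tmd, hmm.tim, hmm.tii, hmm.tdm, hmm.tdd])
        table("TRANSITIONS", trans.T)
        fh.write("//\n")


def load_hmm(path: str | Path) -> ProfileHMM:
    header: dict[str, str] = {}
    tables: dict[str, List[List[float]]] = {}
    current = None
    calib = None
    len_model = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//":
                continue
            parts = line.split("\t")
            if parts[0] in ("NAME", "ALPH", "M"):
                header[parts[0]] = parts[1]
                current = None
            elif parts[0] == "CALIB":
                calib = (float(parts[1]), float(parts[2]))
                current = None
            elif parts[0] == "LENMODEL":
                len_model = (
                    tuple(float(v) for v in parts[1].split(",")),
                    tuple(float(v) for v in parts[2].split(",")),
                )
                current = None
            elif parts[0] in ("BACKGROUND", "MATCH_EMIS", "INS_EMIS", "TRANSITIONS"):
                current = parts[0]
                tables[current] = []
            else:
                tables[current].append([float(v) for v in parts])
    trans = np.array(tables["TRANSITIONS"]).T
    hmm = ProfileHMM(
        name=header["NAME"],
        match_emis=np.array(tables["MATCH_EMIS"]),
        ins_emis=np.array(tables["INS_EMIS"]),
        tmm=trans[0], tmi=trans[1], tmd=trans[2], tim=trans[3],
        tii=trans[4], tdm=trans[5], tdd=trans[6],
        background=np.array(tables["BACKGROUND"][0]),
        alphabet=header["ALPH"],
        calib=calib,
        len_model=len_model,
    )
    return hmm


def hits_table(hits: Iterable[Hit]) -> str:
    lines = ["model\ttarget\tbit_score\tevalue\ttarget_len"]
    for h in hits:
        lines.append(f"{h.model}\t{h.target}\t{h.bit_score:.4f}\t{h.evalue:.6g}\t{h.target_len}")
    return "\n".join(lines) + "\n"
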