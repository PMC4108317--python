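"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from metatelescope.phmm import ProfileHMM


def random_profile(rng: np.random.Generator, max_m: int = 3,
                   alphabet: str = "ABCD") -> ProfileHMM:
    """A random, fully valid toy profile over a reduced alphabet."""
    M = int(rng.integers(1, max_m + 1))
    K = len(alphabet)

    def row(n: int) -> np.ndarray:
        r = rng.random(n) + 0.05
        return r / r.sum()

    me = np.stack([row(K) for _ in range(M)])
    ie = np.stack([row(K) for _ in range(M + 1)])
    tmm = np.empty(M + 1)
    tmi = np.empty(M + 1)
    tmd = np.empty(M + 1)
    for k in range(M + 1):
        legal_d = k < M
        r = row(3 if legal_d else 2)
        if legal_d:
            tmm[k], tmi[k], tmd[k] = r
        else:
            tmm[k], tmi[k] = r
            tmd[k] = 0.0
    tim = np.empty(M + 1)
    tii = np.empty(M + 1)
    for k in range(M + 1):
        tim[k], tii[k] = row(2)
    tdm = np.zeros(M + 1)
    tdd = np.zeros(M + 1)
    for k in range(1, M + 1):
        if k < M:
            tdm[k], tdd[k] = row(2)
        else:
            tdm[k] = 1.0
    hmm = ProfileHMM("toy", me, ie, tmm, tmi, tmd, tim, tii, tdm, tdd,
                     background=row(K), alphabet=alphabet)
    hmm.validate()
    return hmm


def single_path_model() -> ProfileHMM:
    """M=1 model that must emit 'A' (prob ~1) through B->M1->E,
    uniform background."""
    emis = np.full((1, 20), 1e-12)
    emis[0, 0] = 1.0 - 19e-12
    return ProfileHMM(
        "single", emis, np.tile(np.full(20, 0.05), (2, 1)),
        tmm=np.array([1.0, 1.0]), tmi=np.zeros(2), tmd=np.zeros(2),
        tim=np.array([1.0, 1.0]), tii=np.zeros(2),
        tdm=np.array([0.0, 1.0]), tdd=np.zeros(2),
        background=np.full(20, 0.05),
    )
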