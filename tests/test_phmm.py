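"""Profile HMM construction, scoring, calibration and search."""

import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from metatelescope import phmm
from metatelescope.align import Msa, progressive_msa
from metatelescope.phmm import (
    ProfileHMM, SearchParams, build_profile, calibrate, evalue, fit_gumbel,
    fit_gumbel_tail, forward_score, forward_scores, load_hmm, save_hmm,
    search, viterbi,
)
from metatelescope.reference import (
    brute_forward_bits, brute_viterbi_bits, sequence_probability,
)
from metatelescope.seqio import Sequence
from metatelescope.synthetic import FamilySpec, make_proteome, make_lineage, sample_family
from util import random_profile, single_path_model


class TestBuildProfile:
    def test_laplace_smoothed_counts(self):
        msa = Msa([("a", "ACD"), ("b", "ACD")])
        hmm = build_profile(msa, pseudocount=1.0)
        assert hmm.M == 3
        assert hmm.match_emis[0, 0] == pytest.approx(3 / 22)

    def test_sparse_column_becomes_insert(self):
        msa = Msa([("a", "AAC"), ("b", "A-C"), ("c", "A-C"), ("d", "A-C")])
        hmm = build_profile(msa, occupancy=0.5)
        assert hmm.M == 2      # middle column occupied by 1/4 < 0.5

    def test_no_match_columns_is_error(self):
        msa = Msa([("a", "A--"), ("b", "-A-"), ("c", "--A"), ("d", "---")])
        with pytest.raises(ValueError, match="no match columns"):
            build_profile(msa, occupancy=0.9)

    def test_rows_normalised_on_random_msa(self, rng):
        seqs, _ = sample_family(FamilySpec(M=40, n_seed=6, seed=3))
        hmm = build_profile(progressive_msa(seqs))
        hmm.validate()

    def test_blosum_prior_boosts_similar_residues(self):
        """The substitution-mixture prior moves pseudocount mass toward
        residues exchangeable with the observed ones."""
        msa = Msa([(f"s{i}", "III") for i in range(4)])
        flat = build_profile(msa)
        mix = build_profile(msa, prior="blosum")
        aa = phmm.AMINO_ACIDS
        assert np.allclose(mix.match_emis.sum(axis=1), 1.0)
        # leucine is exchangeable with isoleucine, tryptophan is not
        assert mix.match_emis[0, aa.index("L")] > flat.match_emis[0, aa.index("L")]
        assert mix.match_emis[0, aa.index("W")] < flat.match_emis[0, aa.index("W")]
        mix.validate()

    def test_identical_rows_emissions_approach_observed_residue(self):
        msa = Msa([("a", "ACD")] + [(f"b{i}", "ACD") for i in range(3)])
        sharp = build_profile(msa, pseudocount=1e-6)
        assert sharp.match_emis[0, 0] > 0.999


class TestScoring:
    def test_single_path_closed_form(self):
        hmm = single_path_model()
        s = forward_score(hmm, Sequence("x", "A"))
        assert s == pytest.approx(math.log2(20), abs=1e-6)
        v, path = viterbi(hmm, Sequence("x", "A"))
        assert v == pytest.approx(math.log2(20), abs=1e-6)
        assert path == ["B", "M1", "E"]

    def test_forward_and_viterbi_match_enumeration(self, rng):
        for _ in range(25):
            hmm = random_profile(rng)
            for L in range(1, 4):
                w = "".join(rng.choice(list(hmm.alphabet), size=L))
                f = forward_score(hmm, Sequence("s", w))
                assert f == pytest.approx(brute_forward_bits(hmm, w), rel=1e-9)
                v, path = viterbi(hmm, Sequence("s", w))
                bv, bpaths = brute_viterbi_bits(hmm, w)
                assert v == pytest.approx(bv, rel=1e-9)
                assert path in bpaths

    def test_forward_at_least_viterbi(self, rng):
        for _ in range(10):
            hmm = random_profile(rng, max_m=3)
            w = "".join(rng.choice(list(hmm.alphabet), size=rng.integers(1, 5)))
            assert forward_score(hmm, Sequence("s", w)) >= \
                viterbi(hmm, Sequence("s", w))[0] - 1e-12

    def test_tied_paths_break_match_before_insert(self):
        # M=1, symmetric transitions and uniform emissions: for a length-2
        # sequence the paths B,M1,I1,E and B,I0,M1,E have equal probability.
        K = 20
        u = np.full((1, K), 1 / K)
        ui = np.full((2, K), 1 / K)
        hmm = ProfileHMM(
            "tie", u, ui,
            tmm=np.array([1 / 3, 1 / 2]), tmi=np.array([1 / 3, 1 / 2]),
            tmd=np.array([1 / 3, 0.0]),
            tim=np.array([1 / 2, 1 / 2]), tii=np.array([1 / 2, 1 / 2]),
            tdm=np.array([0.0, 1.0]), tdd=np.zeros(2),
            background=np.full(K, 1 / K),
        )
        v, path = viterbi(hmm, Sequence("s", "AA"))
        bv, bpaths = brute_viterbi_bits(hmm, "AA")
        assert ["B", "M1", "I1", "E"] in bpaths and ["B", "I0", "M1", "E"] in bpaths
        assert v == pytest.approx(bv, rel=1e-9)
        # traceback prefers the Match predecessor at every step from the
        # end, so of the two tied paths the one ending ...M1,E is decoded
        assert path == ["B", "I0", "M1", "E"]

    def test_empty_sequence_rejected(self):
        hmm = single_path_model()
        with pytest.raises(ValueError):
            forward_score(hmm, Sequence("s", ""))

    def test_generative_model_normalised(self, rng):
        """Total probability over all emissions up to length L approaches 1."""
        hmm = random_profile(rng, max_m=2, alphabet="AB")
        # tame the insert loops so the length distribution has a short tail
        hmm.tii[:] = 0.3
        hmm.tim[:] = 0.7
        total = sequence_probability(hmm, "")   # all-delete paths
        for L in range(1, 13):
            for idx in range(2 ** L):
                w = "".join("AB"[(idx >> b) & 1] for b in range(L))
                total += sequence_probability(hmm, w)
        assert total <= 1.0 + 1e-9
        assert total > 0.98

    def test_ambiguity_scores_as_background(self):
        hmm = single_path_model()
        assert forward_score(hmm, Sequence("s", "X")) == pytest.approx(0.0, abs=1e-6)


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        lam_true = 0.7
        draws = gumbel_r.rvs(loc=0.0, scale=1 / lam_true, size=5000,
                             random_state=np.random.default_rng(8))
        for fitter in (fit_gumbel, fit_gumbel_tail):
            mu, lam = fitter(draws)
            assert abs(lam - lam_true) / lam_true < 0.10
            assert abs(mu) < 0.5

    def test_deterministic_given_seed(self):
        seqs, _ = sample_family(FamilySpec(M=30, n_seed=5, seed=1))
        hmm = build_profile(progressive_msa(seqs))
        c1 = calibrate(hmm, n_samples=300, seed=5)
        c2 = calibrate(hmm, n_samples=300, seed=5)
        assert c1 == c2

    def test_minimum_sample_size(self):
        hmm = single_path_model()
        with pytest.raises(ValueError):
            calibrate(hmm, n_samples=50)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.zeros(500))
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel_tail(np.zeros(500))

    def test_evalue_closed_forms(self):
        seqs, _ = sample_family(FamilySpec(M=30, n_seed=5, seed=2))
        hmm = build_profile(progressive_msa(seqs))
        calibrate(hmm, n_samples=400, len_dist=30, seed=0)   # fixed length
        assert hmm.len_model is None
        mu, lam = hmm.calib
        n = 1000
        assert evalue(hmm, mu, n) == pytest.approx(n * (1 - math.exp(-1)), rel=1e-9)
        assert evalue(hmm, mu + 500, n) == pytest.approx(0.0, abs=1e-12)
        # monotone decreasing and linear in db size
        s = np.linspace(mu - 5, mu + 20, 30)
        es = [evalue(hmm, x, n) for x in s]
        assert all(a >= b for a, b in zip(es, es[1:]))
        assert evalue(hmm, mu + 3, 2 * n) == pytest.approx(
            2 * evalue(hmm, mu + 3, n), rel=1e-9)

    def test_uncalibrated_model_rejected(self):
        hmm = single_path_model()
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(hmm, 1.0, 100)


@pytest.fixture(scope="module")
def family_setup():
    seqs, lineage = make_lineage(FamilySpec(M=60, n_seed=8, seed=11))
    hmm = build_profile(progressive_msa(seqs), name="fam")
    rng = np.random.default_rng(4)
    from metatelescope.synthetic import evolve, random_protein
    members = [
        Sequence(f"m{i}", evolve(lineage.seed_ancestor, 0.25, 0.01, rng))
        for i in range(50)
    ]
    decoys = [
        Sequence(f"d{i}", random_protein(int(rng.integers(40, 100)), rng))
        for i in range(500)
    ]
    db = members + decoys
    calibrate(hmm, n_samples=500,
              len_dist=np.array([len(s.residues) for s in db]), seed=9)
    return hmm, members, decoys


class TestSearch:
    def test_family_separates_from_decoys(self, family_setup):
        """Implanted family members all outscore every decoy (AUC 1)."""
        hmm, members, decoys = family_setup
        ms = forward_scores(hmm, members)
        ds = forward_scores(hmm, decoys)
        assert ms.min() > ds.max()

    def test_threshold_and_ordering(self, family_setup):
        hmm, members, decoys = family_setup
        db = members + decoys
        hits = search(hmm, db, SearchParams(evalue_threshold=1e-6))
        assert hits, "family members should be significant"
        assert all(h.evalue <= 1e-6 for h in hits)
        assert {h.target for h in hits} <= {m.id for m in members}
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)

    def test_empty_db_warns(self, family_setup):
        hmm, _, _ = family_setup
        with pytest.warns(UserWarning):
            assert search(hmm, []) == []

    def test_agrees_with_reference_search_tool(self, family_setup):
        """Independent cross-check: an established profile-search stack
        built from the same alignment detects the same labelled set."""
        pyhmmer = pytest.importorskip("pyhmmer")
        seqs, lineage = make_lineage(FamilySpec(M=60, n_seed=8, seed=11))
        msa = progressive_msa(seqs)
        abc = pyhmmer.easel.Alphabet.amino()
        dmsa = pyhmmer.easel.TextMSA(
            name=b"fam",
            sequences=[pyhmmer.easel.TextSequence(name=i.encode(), sequence=r)
                       for i, r in msa.rows]).digitize(abc)
        bg = pyhmmer.plan7.Background(abc)
        hmm_p, _, _ = pyhmmer.plan7.Builder(abc).build_msa(dmsa, bg)
        hmm, members, decoys = family_setup
        db = members + decoys
        dseqs = pyhmmer.easel.DigitalSequenceBlock(abc, [
            pyhmmer.easel.TextSequence(name=s.id.encode(),
                                       sequence=s.residues).digitize(abc)
            for s in db])
        pipe = pyhmmer.plan7.Pipeline(abc, background=bg, E=1e-3)
        ph_hits = {h.name if isinstance(h.name, str) else h.name.decode()
                   for h in pipe.search_hmm(hmm_p, dseqs)
                   if h.evalue <= 1e-3}
        ours = {h.target for h in search(hmm, db, SearchParams(1e-6))}
        assert ph_hits == {m.id for m in members}
        assert ours == ph_hits


def test_model_round_trip(tmp_path, rng):
    seqs, _ = sample_family(FamilySpec(M=25, n_seed=5, seed=6))
    hmm = build_profile(progressive_msa(seqs), name="rt")
    calibrate(hmm, n_samples=300,
              len_dist=np.array([20, 25, 30, 40]), seed=1)
    p = tmp_path / "m.hmm"
    save_hmm(hmm, p)
    back = load_hmm(p)
    assert back.name == hmm.name and back.alphabet == hmm.alphabet
    np.testing.assert_array_equal(back.match_emis, hmm.match_emis)
    np.testing.assert_array_equal(back.tmm, hmm.tmm)
    assert back.calib == hmm.calib
    assert back.len_model == hmm.len_model
    w = Sequence("w", "".join(rng.choice(list(phmm.AMINO_ACIDS), size=30)))
    assert forward_score(back, w) == pytest.approx(forward_score(hmm, w))
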