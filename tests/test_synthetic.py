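"""Ground-truth generators: determinism, divergence statistics, labels."""

import numpy as np
import pytest

from metatelescope.reference import six_frame_orfs
from metatelescope.seqio import Sequence, extract_orfs
from metatelescope.synthetic import (
    FamilySpec, conditional_matrix, evolve, make_benchmark, make_lineage,
    make_metagenome, make_proteome, random_protein, sample_family,
)
from metatelescope.align import pairwise_align, fractional_identity

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSampleFamily:
    def test_zero_divergence_identical_descendants(self):
        seqs, _ = sample_family(
            FamilySpec(M=50, n_seed=4, divergence=0.0, indel_rate=0.0, seed=1))
        assert len({s.residues for s in seqs}) == 1

    def test_same_seed_identical_output(self):
        a, _ = sample_family(FamilySpec(seed=9))
        b, _ = sample_family(FamilySpec(seed=9))
        assert [(s.id, s.residues) for s in a] == [(s.id, s.residues) for s in b]

    def test_generator_hmm_valid(self):
        _, hmm = sample_family(FamilySpec(M=30, seed=2))
        hmm.validate()

    def test_pairwise_identity_matches_analytic_expectation(self):
        """Two branches at divergence d: a site matches if neither mutated,
        or both mutated to the same replacement."""
        d = 0.2
        n = 1000
        rng = np.random.default_rng(77)
        ancestor = random_protein(n, rng)
        x = evolve(ancestor, d, 0.0, rng)
        y = evolve(ancestor, d, 0.0, rng)
        observed = sum(a == b for a, b in zip(x, y)) / n

        C = conditional_matrix()
        idx = {c: i for i, c in enumerate(AA)}
        p_site = []
        for ch in ancestor:
            a = idx[ch]
            cond = C[a].copy()
            cond[a] = 0.0
            cond /= cond.sum()
            q_coincide = float((cond ** 2).sum())
            p_site.append((1 - d) ** 2 + d ** 2 * q_coincide)
        p_site = np.array(p_site)
        mean = p_site.mean()
        sigma = np.sqrt((p_site * (1 - p_site)).sum()) / n
        assert abs(observed - mean) < 3 * sigma

    def test_divergence_bounds_validated(self):
        with pytest.raises(ValueError):
            FamilySpec(divergence=1.0)
        with pytest.raises(ValueError):
            FamilySpec(n_seed=1)


class TestMetagenome:
    def test_no_implants_only_decoys(self):
        contigs, labels = make_metagenome({}, n_decoy_contigs=5, seed=0)
        assert len(contigs) == 5
        assert set(labels.labels.values()) == {"decoy"}

    def test_label_complete(self):
        fam = [Sequence(f"p{i}", random_protein(60, np.random.default_rng(i)))
               for i in range(3)]
        contigs, labels = make_metagenome({"f": fam}, n_decoy_contigs=4, seed=1)
        assert {c.id for c in contigs} == set(labels.labels)

    def test_implants_recoverable_as_orfs(self):
        rng = np.random.default_rng(5)
        fam = [Sequence(f"p{i}", random_protein(60, rng)) for i in range(6)]
        contigs, labels = make_metagenome(
            {"f": fam}, n_decoy_contigs=0, implant_divergence=0.0, seed=2)
        for contig, prot in zip(contigs, fam):
            orfs = extract_orfs(contig, min_aa=10)
            assert any(prot.residues in o.protein.residues for o in orfs), \
                f"implant {prot.id} not recoverable from {contig.id}"

    def test_strand_balance(self):
        rng = np.random.default_rng(6)
        fam = [Sequence(f"p{i}", random_protein(40, rng)) for i in range(300)]
        contigs, _ = make_metagenome({"f": fam}, n_decoy_contigs=0,
                                     implant_divergence=0.0, seed=3)
        n_fwd = 0
        for contig, prot in zip(contigs, fam):
            hits = [o for o in extract_orfs(contig, min_aa=10)
                    if prot.residues in o.protein.residues]
            assert hits
            n_fwd += hits[0].strand == "+"
        frac = n_fwd / len(fam)
        sigma = 0.5 / np.sqrt(len(fam))
        assert abs(frac - 0.5) < 4 * sigma

    def test_same_seed_identical_bytes(self):
        fam = [Sequence("p", random_protein(30, np.random.default_rng(0)))]
        c1, _ = make_metagenome({"f": fam}, 3, 0.1, seed=7)
        c2, _ = make_metagenome({"f": fam}, 3, 0.1, seed=7)
        assert [(c.id, c.residues) for c in c1] == [(c.id, c.residues) for c in c2]


class TestProteomeAndChain:
    def test_no_remotes_requested(self):
        _, lineage = make_lineage(FamilySpec(M=40, seed=4))
        _, labels = make_proteome([lineage], n_remote=0, n_decoy=10, seed=1)
        assert not labels.ids("remote_homolog")

    def test_label_complete_and_deterministic(self):
        _, lineage = make_lineage(FamilySpec(M=40, seed=4))
        p1, l1 = make_proteome([lineage], seed=5)
        p2, _ = make_proteome([lineage], seed=5)
        assert {s.id for s in p1} == set(l1.labels)
        assert [(s.id, s.residues) for s in p1] == [(s.id, s.residues) for s in p2]

    def test_transitive_chain_identities(self):
        """Link identities sit near 45-50%; the composed seed-to-remote
        identity lands in the twilight zone (~20-25%)."""
        seeds, lineage = make_lineage(FamilySpec(M=120, seed=4))
        prot, labels = make_proteome([lineage], n_close=2, n_remote=3,
                                     n_decoy=0, seed=6)
        inter = Sequence("i", lineage.intermediate_ancestor)
        remotes = [s for s in prot if labels[s.id] == "remote_homolog"]

        def fi(a, b):
            return fractional_identity(pairwise_align(a, b))

        link1 = fi(seeds[0], inter)
        link2 = np.mean([fi(inter, r) for r in remotes])
        composed = np.mean([fi(seeds[0], r) for r in remotes])
        assert 0.35 < link1 < 0.60
        assert 0.35 < link2 < 0.60
        assert 0.12 < composed < 0.33
        assert composed < min(link1, link2) - 0.1


def test_benchmark_labels_partition_everything():
    b = make_benchmark(3, spec=FamilySpec(M=40, seed=3), n_decoy_contigs=3,
                       n_decoy_proteins=10)
    assert {c.id for c in b.contigs} == set(b.metagenome_labels.labels)
    assert {s.id for s in b.proteome} == set(b.proteome_labels.labels)
    assert b.metagenome_labels.of_orf("fam3_implant0_10_100_+_1") == "close_homolog"
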