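"""Synthetic families, metagenomes and proteomes with known ground truth.

The generators emulate the data the two-projection search operates on: a
conserved protein family sampled around a common ancestor, nucleotide
contigs carrying reverse-translated divergent homologs among random
decoy contigs, and proteomes containing close homologs, remote homologs
and unrelated decoys.

Substitutions draw the replacement residue from BLOSUM62-conditional
probabilities (excluding the original residue), so sequence similarity
decays the way real family divergence does and ``divergence`` is the
expected fraction of changed sites. The central construction is the
*transitive chain*: remote homologs descend from an intermediate
ancestor that itself descends from the seed ancestor, so remote
sequences are detectable through the metagenome intermediates but sit
near the twilight zone relative to the seeds.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .phmm import AMINO_ACIDS, BACKGROUND, ProfileHMM, conditional_matrix
from .seqio import Sequence

LABELS = ("seed_family", "close_homolog", "remote_homolog", "decoy")


@dataclass
class FamilySpec:
    """Parameters of one simulated protein family."""

    M: int = 120                 # ancestor length (aa)
    n_seed: int = 8              # descendants sampled around the ancestor
    divergence: float = 0.15     # expected fraction of substituted sites per branch
    indel_rate: float = 0.01     # per-site insertion/deletion probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if self.n_seed < 2:
            raise ValueError("n_seed must be >= 2")


@dataclass
class TruthLabels:
    """Ground-truth label for every generated sequence id."""

    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __getitem__(self, key: str) -> str:
        return self.labels[key]

    def of_orf(self, orf_name: str) -> str:
        """Label of an ORF by its parent contig (ORF ids are
        ``contig_start_end_strand_frame``)."""
        return self.labels[orf_name.rsplit("_", 4)[0]]

    def ids(self, label: str) -> List[str]:
        return [k for k, v in self.labels.items() if v == label]

    def to_table(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.labels.items()]
        return "\n".join(lines) + "\n"


def _cond() -> np.ndarray:
    return conditional_matrix()


_AA_IDX = {c: i for i, c in enumerate(AMINO_ACIDS)}
_AA_ARR = np.array(list(AMINO_ACIDS))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA_ARR, size=length, p=BACKGROUND))


def evolve(
    residues: str,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """One descendant: per-site substitution (replacement drawn from the
    BLOSUM62-conditional distribution, never the original residue) plus
    geometric-length insertions and single-site deletions."""
    C = _cond()
    out: List[str] = []
    for ch in residues:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:          # deletion
                continue
            for _ in range(int(rng.geometric(0.5))):   # insertion before site
                out.append(str(rng.choice(_AA_ARR, p=BACKGROUND)))
        if divergence > 0 and rng.random() < divergence:
            a = _AA_IDX[ch]
            p = C[a].copy()
            p[a] = 0.0
            p /= p.sum()
            out.append(str(rng.choice(_AA_ARR, p=p)))
        else:
            out.append(ch)
    return "".join(out)


def _generator_hmm(ancestor: str, divergence: float, indel_rate: float,
                   name: str) -> ProfileHMM:
    """The generative profile the family was drawn from: per-site
    emission is a (1-d) point mass on the ancestral residue mixed with
    the conditional substitution distribution."""
    C = _cond()
    M = len(ancestor)
    K = len(AMINO_ACIDS)
    emis = np.empty((M, K))
    for k, ch in enumerate(ancestor):
        a = _AA_IDX[ch]
        p = C[a].copy()
        p[a] = 0.0
        p /= p.sum()
        row = divergence * p
        row[a] += 1.0 - divergence
        emis[k] = row
    emis = (emis + 1e-4) / (1.0 + K * 1e-4)   # keep every probability positive
    r = max(indel_rate, 1e-3)
    tmm = np.full(M + 1, 1.0 - r)
    tmi = np.full(M + 1, r / 2)
    tmd = np.full(M + 1, r / 2)
    tmd[M] = 0.0
    tmm[M] = 1.0 - tmi[M]
    tim = np.full(M + 1, 0.5)
    tii = np.full(M + 1, 0.5)
    tdm = np.full(M + 1, 0.9)
    tdd = np.full(M + 1, 0.1)
    tdd[M] = 0.0
    tdm[M] = 1.0
    tdd[0] = 0.0
    tdm[0] = 0.0
    hmm = ProfileHMM(
        name=name, match_emis=emis, ins_emis=np.tile(BACKGROUND, (M + 1, 1)),
        tmm=tmm, tmi=tmi, tmd=tmd, tim=tim, tii=tii, tdm=tdm, tdd=tdd,
        background=BACKGROUND.copy(),
    )
    return hmm


def sample_family(spec: FamilySpec) -> Tuple[List[Sequence], ProfileHMM]:
    """Draw an ancestor and evolve ``n_seed`` descendants from it."""
    rng = np.random.default_rng(spec.seed)
    ancestor = random_protein(spec.M, rng)
    seqs = [
        Sequence(f"fam{spec.seed}_s{i}",
                 evolve(ancestor, spec.divergence, spec.indel_rate, rng))
        for i in range(spec.n_seed)
    ]
    gen = _generator_hmm(ancestor, spec.divergence, spec.indel_rate,
                         name=f"fam{spec.seed}_generator")
    return seqs, gen


@dataclass
class Lineage:
    """A transitive homology chain: seed ancestor -> intermediate -> remote."""

    name: str
    seed_ancestor: str
    intermediate_ancestor: str
    remote_ancestor: str


def make_lineage(
    spec: FamilySpec, chain_divergence: float = 0.50, chain_indel_rate: float = 0.02
) -> Tuple[List[Sequence], Lineage]:
    """Sample a seed family plus the intermediate/remote chain ancestors.

    Each chain link applies ``chain_divergence`` substitutions, so the
    remote ancestor sits roughly at the product of the per-link
    identities from the seeds — reachable from the intermediates but not
    (by design) from the seeds directly.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = random_protein(spec.M, rng)
    seqs = [
        Sequence(f"fam{spec.seed}_s{i}",
                 evolve(ancestor, spec.divergence, spec.indel_rate, rng))
        for i in range(spec.n_seed)
    ]
    inter = evolve(ancestor, chain_divergence, chain_indel_rate, rng)
    remote = evolve(inter, chain_divergence, chain_indel_rate, rng)
    return seqs, Lineage(f"fam{spec.seed}", ancestor, inter, remote)


# ---------------------------------------------------------------------------
# nucleotide layer
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))


def _codons_by_aa(table_id: int = 11) -> Dict[str, List[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


def reverse_translate(protein: str, rng: np.random.Generator,
                      table_id: int = 11) -> str:
    """Random synonymous codons for each residue."""
    by_aa = _codons_by_aa(table_id)
    return "".join(str(rng.choice(by_aa[aa])) for aa in protein)


def random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NT, size=length))


def make_metagenome(
    families: Dict[str, List[Sequence]],
    n_decoy_contigs: int = 40,
    implant_divergence: float = 0.12,
    seed: int = 0,
    decoy_len: Tuple[int, int] = (750, 1050),
    flank_len: Tuple[int, int] = (30, 120),
    table_id: int = 11,
) -> Tuple[List[Sequence], TruthLabels]:
    """Contigs with reverse-translated homologs implanted among decoys.

    ``families`` maps a family name to the proteins to implant (one
    contig each); every implant is first mutated by
    ``implant_divergence``, then reverse-translated and framed by stop
    codons so the stop-to-stop ORF extractor recovers exactly the
    implanted protein. Strand is random. Labels are per contig id:
    implant contigs are ``close_homolog`` (homologous to the implanted
    family), decoys are ``decoy``.
    """
    rng = np.random.default_rng(seed)
    contigs: List[Sequence] = []
    labels: Dict[str, str] = {}
    for fam, proteins in sorted(families.items()):
        for i, prot in enumerate(proteins):
            mutated = evolve(prot.residues, implant_divergence, 0.0, rng)
            cds = reverse_translate(mutated, rng, table_id)
            left = random_nt(int(rng.integers(*flank_len)), rng)
            right = random_nt(int(rng.integers(*flank_len)), rng)
            nt = left + "TAA" + cds + "TGA" + right
            if rng.random() < 0.5:
                nt = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            cid = f"{fam}_implant{i}"
            contigs.append(Sequence(cid, nt, alphabet="nucleotide"))
            labels[cid] = "close_homolog"
    for i in range(n_decoy_contigs):
        cid = f"decoy_contig{i}"
        contigs.append(Sequence(cid, random_nt(int(rng.integers(*decoy_len)), rng),
                                alphabet="nucleotide"))
        labels[cid] = "decoy"
    return contigs, TruthLabels(labels)


def make_proteome(
    lineages: TSequence[Lineage],
    n_close: int = 3,
    n_remote: int = 4,
    n_decoy: int = 300,
    divergences: Optional[Dict[str, float]] = None,
    seed: int = 0,
    decoy_len: Tuple[int, int] = (60, 250),
) -> Tuple[List[Sequence], TruthLabels]:
    """A proteome of close homologs, chain-remote homologs and decoys.

    Close homologs descend from each lineage's seed ancestor; remote
    homologs descend from its remote ancestor (two chain links away from
    the seeds); decoys are i.i.d. background proteins.
    """
    div = {"close": 0.10, "remote": 0.12}
    if divergences:
        div.update(divergences)
    rng = np.random.default_rng(seed)
    seqs: List[Sequence] = []
    labels: Dict[str, str] = {}
    for lin in lineages:
        for i in range(n_close):
            sid = f"{lin.name}_close{i}"
            seqs.append(Sequence(
                sid, evolve(lin.seed_ancestor, div["close"], 0.01, rng)))
            labels[sid] = "close_homolog"
        for i in range(n_remote):
            sid = f"{lin.name}_remote{i}"
            seqs.append(Sequence(
                sid, evolve(lin.remote_ancestor, div["remote"], 0.01, rng)))
            labels[sid] = "remote_homolog"
    for i in range(n_decoy):
        sid = f"decoy{i}"
        seqs.append(Sequence(sid, random_protein(int(rng.integers(*decoy_len)), rng)))
        labels[sid] = "decoy"
    return seqs, TruthLabels(labels)


@dataclass
class Benchmark:
    """One fully linked synthetic study: seeds, metagenome, proteome, truth."""

    seed_family: List[Sequence]
    lineage: Lineage
    contigs: List[Sequence]
    metagenome_labels: TruthLabels
    proteome: List[Sequence]
    proteome_labels: TruthLabels


def make_benchmark(
    seed: int,
    spec: Optional[FamilySpec] = None,
    n_intermediates: int = 12,
    n_decoy_contigs: int = 40,
    n_close: int = 3,
    n_remote: int = 4,
    n_decoy_proteins: int = 300,
    chain_divergence: float = 0.50,
) -> Benchmark:
    """The transitive-chain study used for sensitivity evaluation.

    The metagenome carries ``n_intermediates`` homologs of the
    intermediate ancestor; the proteome carries close homologs of the
    seed ancestor and remote homologs of the remote ancestor.
    """
    spec = spec or FamilySpec(seed=seed)
    if spec.seed != seed:
        spec = FamilySpec(spec.M, spec.n_seed, spec.divergence, spec.indel_rate, seed)
    seeds, lineage = make_lineage(spec, chain_divergence)
    rng = np.random.default_rng(seed + 1)
    intermediates = [
        Sequence(f"{lineage.name}_inter{i}",
                 evolve(lineage.intermediate_ancestor, 0.12, 0.01, rng))
        for i in range(n_intermediates)
    ]
    contigs, meta_labels = make_metagenome(
        {lineage.name: intermediates},
        n_decoy_contigs=n_decoy_contigs,
        implant_divergence=0.0,       # divergence already applied above
        seed=seed + 2,
    )
    proteome, prot_labels = make_proteome(
        [lineage], n_close=n_close, n_remote=n_remote,
        n_decoy=n_decoy_proteins, seed=seed + 3,
    )
    return Benchmark(seeds, lineage, contigs, meta_labels, proteome, prot_labels)
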