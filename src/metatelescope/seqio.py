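"""Sequence I/O and six-frame ORF extraction.

FASTA reading/writing is delegated to Biopython; ORF extraction follows the
stop-to-stop convention (maximal open stretches between stop codons or
sequence ends in each of the six reading frames), the behaviour of classic
``getorf``-style tools, rather than ATG-to-stop gene calling.

Coordinates are 0-based, half-open, and always reported on the forward
strand, for both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Alphabet = Literal["nucleotide", "protein"]

NT_SYMBOLS = frozenset("ACGTN")
AA_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Sequence:
    """A named residue string over a declared alphabet."""

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id contains whitespace: {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        """Raise if residues fall outside the alphabet plus its ambiguity code."""
        allowed = NT_SYMBOLS if self.alphabet == "nucleotide" else AA_SYMBOLS
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"{self.id}: residues outside {self.alphabet} alphabet: {sorted(bad)}"
            )
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")


@dataclass
class Orf:
    """An open reading frame located on the forward strand of its contig.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``frame`` is the 0/1/2 offset on the strand the ORF was read from.
    """

    contig_id: str
    strand: Literal["+", "-"]
    frame: int
    start: int
    end: int
    protein: Sequence = field(repr=False)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not divisible by 3")
        if len(self.protein.residues) != (self.end - self.start) // 3:
            raise ValueError("protein length inconsistent with ORF span")
        if "*" in self.protein.residues:
            raise ValueError("ORF protein contains a stop symbol")

    @property
    def name(self) -> str:
        return f"{self.contig_id}_{self.start}_{self.end}_{self.strand}_{self.frame}"


def read_fasta(path: str | Path, alphabet: Alphabet = "protein") -> List[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Residues are upper-cased and a single terminal ``*`` is stripped.
    Duplicate record ids are a hard error; an empty file yields an empty
    list with a warning.
    """
    out: List[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(Sequence(rec.id, residues, alphabet=alphabet, description=desc))
    if not out:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-record FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


_CODON_CACHE: dict[int, dict[str, str]] = {}


def translate(nt: Sequence | str, table_id: int = 11) -> str:
    """Translate a nucleotide sequence; stops rendered as ``*``.

    Codons containing ``N`` translate to ``X`` unless every resolution of
    the ambiguity yields the same amino acid. Length must be a multiple
    of 3.
    """
    residues = nt.residues if isinstance(nt, Sequence) else nt
    if len(residues) % 3 != 0:
        raise ValueError("nucleotide length not divisible by 3")
    if table_id not in (1, 11):
        raise ValueError(f"unsupported translation table {table_id}")
    if table_id not in _CODON_CACHE:
        _CODON_CACHE[table_id] = _codon_map(table_id)
    cmap = _CODON_CACHE[table_id]
    out = []
    for i in range(0, len(residues), 3):
        codon = residues[i:i + 3]
        aa = cmap.get(codon)
        if aa is None:
            aa = _translate_ambiguous(codon, cmap)
        out.append(aa)
    return "".join(out)


def _translate_ambiguous(codon: str, cmap: dict[str, str]) -> str:
    options = {""}
    for base in codon:
        expand = "ACGT" if base == "N" else base
        if base not in "ACGTN":
            return "X"
        options = {pre + b for pre in options for b in expand}
    aas = {cmap[c] for c in options}
    return aas.pop() if len(aas) == 1 else "X"


def extract_orfs(
    contig: Sequence, min_aa: int = 30, table_id: int = 11
) -> List[Orf]:
    """Extract stop-to-stop ORFs from all six frames of a contig.

    Returns ORFs whose translated length is at least ``min_aa``, sorted by
    (start, strand, frame). Reverse-strand ORFs carry forward-strand
    coordinates.
    """
    if contig.alphabet != "nucleotide":
        raise ValueError("extract_orfs expects a nucleotide contig")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(contig.residues)
    orfs: List[Orf] = []
    for strand in "+-":
        seq = contig.residues if strand == "+" else reverse_complement(contig.residues)
        for frame in range(3):
            usable = (n - frame) // 3 * 3
            if usable <= 0:
                continue
            protein = translate(seq[frame:frame + usable], table_id)
            # split into maximal stop-free stretches
            c0 = 0
            for chunk in protein.split("*"):
                c1 = c0 + len(chunk)
                if len(chunk) >= min_aa:
                    s = frame + 3 * c0          # on the read strand
                    e = frame + 3 * c1
                    if strand == "+":
                        start, end = s, e
                    else:
                        start, end = n - e, n - s
                    orf_seq = Sequence(
                        f"{contig.id}_{start}_{end}_{strand}_{frame}",
                        chunk,
                        alphabet="protein",
                    )
                    orfs.append(Orf(contig.id, strand, frame, start, end, orf_seq))
                c0 = c1 + 1
    orfs.sort(key=lambda o: (o.start, o.strand, o.frame))
    return orfs


def orfs_to_fasta(orfs: Iterable[Orf], path: str | Path) -> None:
    write_fasta((o.protein for o in orfs), path)


def orf_table(orfs: Iterable[Orf]) -> str:
    """Render ORFs as a 6-column tab-separated table (with header)."""
    lines = ["contig_id\tstrand\tframe\tstart\tend\tprotein"]
    for o in orfs:
        lines.append(
            f"{o.contig_id}\t{o.strand}\t{o.frame}\t{o.start}\t{o.end}\t{o.protein.residues}"
        )
    return "\n".join(lines) + "\n"
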