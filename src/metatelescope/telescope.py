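"""The two-projection ("telescopic") homology search.

The *original projection* searches the seed-family profile directly
against model-organism proteomes. The telescope instead projects twice:

* Projection 1 — the same seed profile is searched against ORFs
  extracted from metagenome contigs; the above-threshold ORFs are the
  "metagenome matches".
* Projection 2 — the matches are clustered (OPTICS on alignment
  distances), each sufficiently large cluster is aligned and turned into
  a new profile, and the new profiles are searched against the same
  proteomes. The union of their above-threshold targets per organism is
  the "telescopic hits".

Targets present among the telescopic hits but absent from the original
hits are the "new telescopic hits" — the remote homologs the seed
profile alone cannot reach but its metagenome intermediates can.

Every profile is calibrated against the length distribution of the
database it is about to search, with seeds derived deterministically
from the run seed.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence as TSequence, Set, Tuple

import numpy as np
import yaml

from . import align, cluster, phmm, seqio
from .cluster import ClusterSet
from .phmm import Hit, ProfileHMM, SearchParams
from .seqio import Sequence


@dataclass
class ClusterParams:
    min_pts: int = 5
    eps: float = math.inf
    eps_prime: float = 0.6
    min_cluster_size: int = 5


@dataclass
class TelescopeConfig:
    """Inputs and parameters of one telescope run."""

    seed_family: Path
    metagenomes: List[Path]
    proteomes: List[Tuple[str, Path]]          # (organism name, FASTA path)
    family_name: str = "family"
    evalue_threshold: float = 1e-6
    orf_min_aa: int = 30
    table_id: int = 11
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    calib_n: int = 1000
    seed: int = 0
    pool_metagenomes: bool = True
    annotations: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.metagenomes:
            raise ValueError("at least one metagenome is required")
        if not self.proteomes:
            raise ValueError("at least one proteome is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TelescopeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        cp = ClusterParams(**raw.get("cluster", {}))
        eps = cp.eps
        cp.eps = math.inf if eps in ("inf", None) else float(eps)
        return cls(
            seed_family=base / raw["seed_family"],
            metagenomes=[base / p for p in raw["metagenomes"]],
            proteomes=[(o, base / p) for o, p in raw["proteomes"].items()],
            family_name=raw.get("family_name", "family"),
            evalue_threshold=float(raw.get("evalue_threshold", 1e-6)),
            orf_min_aa=int(raw.get("orf_min_aa", 30)),
            table_id=int(raw.get("table_id", 11)),
            cluster_params=cp,
            calib_n=int(raw.get("calib_n", 1000)),
            seed=int(raw.get("seed", 0)),
            pool_metagenomes=bool(raw.get("pool_metagenomes", True)),
            annotations=(base / raw["annotations"]) if raw.get("annotations") else None,
        )


@dataclass
class TelescopeResult:
    family: str
    original_hits: Dict[str, List[Hit]]        # organism -> hits
    telescopic_hits: Dict[str, List[Hit]]
    new_telescopic: Dict[str, Set[str]]        # organism -> new target ids
    metagenome_matches: List[Hit]
    match_seqs: List[Sequence]
    clusters: Optional[ClusterSet]
    new_hmms: List[ProfileHMM]
    seed_hmm: ProfileHMM


def _derived_seed(base: int, *indices: int) -> int:
    s = np.random.SeedSequence([base, *indices])
    return int(s.generate_state(1)[0] % (2**31))


def _calibrated_search(
    hmm: ProfileHMM,
    db: TSequence[Sequence],
    params: SearchParams,
    calib_n: int,
    calib_seed: int,
) -> List[Hit]:
    if not db:
        return []
    lengths = np.array([len(s.residues) for s in db])
    phmm.calibrate(hmm, n_samples=calib_n, len_dist=lengths, seed=calib_seed)
    return phmm.search(hmm, db, params)


def original_projection(
    hmm: ProfileHMM, proteome: TSequence[Sequence], params: SearchParams
) -> List[Hit]:
    """Direct search of the (calibrated) seed profile against one proteome."""
    proteome = list(proteome)
    if not proteome:
        warnings.warn("empty proteome", stacklevel=2)
        return []
    return phmm.search(hmm, proteome, params)


def projection_1(
    hmm: ProfileHMM,
    metagenome_contigs: TSequence[Sequence],
    orf_min_aa: int,
    params: SearchParams,
    table_id: int = 11,
) -> Tuple[List[Hit], List[Sequence]]:
    """Search the seed profile against six-frame ORFs of the contigs.

    Returns the metagenome matches and the full ORF protein database
    (match sequences are looked up in it for clustering).
    """
    orfs: List[seqio.Orf] = []
    for contig in metagenome_contigs:
        orfs.extend(seqio.extract_orfs(contig, min_aa=orf_min_aa, table_id=table_id))
    if not orfs:
        warnings.warn("no ORFs above the length floor", stacklevel=2)
        return [], []
    db = [o.protein for o in orfs]
    hits = phmm.search(hmm, db, params)
    return hits, db


def projection_2(
    matches: List[Hit],
    match_seqs: TSequence[Sequence],
    cluster_params: ClusterParams,
    proteomes: TSequence[Tuple[str, TSequence[Sequence]]],
    params: SearchParams,
    calib_n: int = 1000,
    seed: int = 0,
    name_prefix: str = "telescope",
) -> Tuple[Optional[ClusterSet], List[ProfileHMM], Dict[str, List[Hit]]]:
    """Cluster the metagenome matches, build one new profile per cluster,
    and search every proteome with each of them.

    Telescopic hits per organism are the union over cluster profiles; a
    target hit by several profiles keeps its best (lowest) E-value.
    """
    if not matches:
        raise ValueError("no metagenome matches to project from")
    by_id = {s.id: s for s in match_seqs}
    seqs = [by_id[h.target] for h in matches]
    dm = cluster.distance_matrix(seqs)
    res = cluster.optics(dm, min_pts=cluster_params.min_pts, eps=cluster_params.eps)
    cs = cluster.extract_clusters(
        res, eps_prime=cluster_params.eps_prime,
        min_cluster_size=cluster_params.min_cluster_size,
    )
    new_hmms: List[ProfileHMM] = []
    telescopic: Dict[str, Dict[str, Hit]] = {org: {} for org, _ in proteomes}
    if not cs.clusters:
        warnings.warn("telescope degenerate: no cluster reaches the size floor",
                      stacklevel=2)
        return cs, [], {org: [] for org, _ in proteomes}
    for ci, members in enumerate(cs.clusters):
        cluster_seqs = [by_id[m] for m in members]
        msa = align.progressive_msa(cluster_seqs)
        hmm = phmm.build_profile(msa, name=f"{name_prefix}_cluster{ci}",
                                 prior="blosum")
        new_hmms.append(hmm)
        for pi, (org, proteome) in enumerate(proteomes):
            hits = _calibrated_search(
                hmm, proteome, params, calib_n,
                _derived_seed(seed, 2, ci, pi),
            )
            pool = telescopic[org]
            for h in hits:
                if h.target not in pool or h.evalue < pool[h.target].evalue:
                    pool[h.target] = h
    out = {
        org: sorted(pool.values(), key=lambda h: (h.evalue, h.target))
        for org, pool in telescopic.items()
    }
    return cs, new_hmms, out


def compare_hits(original: Iterable[Hit], telescopic: Iterable[Hit]) -> Set[str]:
    """Target ids present among telescopic hits but not original hits."""
    orig = {h.target for h in original}
    return {h.target for h in telescopic} - orig


def summarize_terms(
    hit_ids: Iterable[str], annotation_table: Mapping[str, List[str]]
) -> Counter:
    """Count annotation terms over a hit set; ids missing from the table
    count under ``unannotated``."""
    counts: Counter = Counter()
    for hid in hit_ids:
        terms = annotation_table.get(hid)
        if not terms:
            counts["unannotated"] += 1
        else:
            counts.update(terms)
    return counts


def term_summary(
    result: "TelescopeResult", annotation_table: Mapping[str, List[str]]
) -> Dict[str, object]:
    """Term distributions for the original, telescopic and new-telescopic
    hit sets (pooled over organisms), plus the terms that appear only
    among the new telescopic hits."""
    orig_ids = {h.target for hits in result.original_hits.values() for h in hits}
    tele_ids = {h.target for hits in result.telescopic_hits.values() for h in hits}
    new_ids = set().union(*result.new_telescopic.values()) if result.new_telescopic else set()
    orig_c = summarize_terms(orig_ids, annotation_table)
    tele_c = summarize_terms(tele_ids, annotation_table)
    new_c = summarize_terms(new_ids, annotation_table)
    new_only = {t for t in new_c if t != "unannotated" and t not in orig_c}
    return {
        "original": orig_c,
        "telescopic": tele_c,
        "new_telescopic": new_c,
        "new_only_terms": new_only,
    }


def read_annotations(path: str | Path) -> Dict[str, List[str]]:
    """Tab-separated annotation table: ``id<TAB>term`` (one per line) or
    ``id<TAB>term1;term2;...``."""
    table: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, terms = line.split("\t", 1)
            table.setdefault(sid, []).extend(
                t for t in terms.replace(";", "\t").split("\t") if t
            )
    return table


def run_telescope_data(
    seed_family: TSequence[Sequence],
    metagenomes: TSequence[TSequence[Sequence]],
    proteomes: TSequence[Tuple[str, TSequence[Sequence]]],
    family_name: str = "family",
    params: Optional[SearchParams] = None,
    orf_min_aa: int = 30,
    table_id: int = 11,
    cluster_params: Optional[ClusterParams] = None,
    calib_n: int = 1000,
    seed: int = 0,
    pool_metagenomes: bool = True,
    seed_aligned: Optional[align.Msa] = None,
) -> TelescopeResult:
    """Run the full telescope on in-memory sequence collections."""
    params = params or SearchParams()
    cluster_params = cluster_params or ClusterParams()
    msa = seed_aligned or align.progressive_msa(seed_family)
    seed_hmm = phmm.build_profile(msa, name=family_name, prior="blosum")

    original: Dict[str, List[Hit]] = {}
    for pi, (org, proteome) in enumerate(proteomes):
        original[org] = _calibrated_search(
            seed_hmm, proteome, params, calib_n, _derived_seed(seed, 0, pi)
        )

    matches: List[Hit] = []
    match_db: List[Sequence] = []
    groups = [list(c for m in metagenomes for c in m)] if pool_metagenomes else [
        list(m) for m in metagenomes
    ]
    for gi, contigs in enumerate(groups):
        orfs: List[seqio.Orf] = []
        for contig in contigs:
            orfs.extend(seqio.extract_orfs(contig, min_aa=orf_min_aa,
                                           table_id=table_id))
        if not orfs:
            warnings.warn("no ORFs above the length floor", stacklevel=2)
            continue
        db = [o.protein for o in orfs]
        lengths = np.array([len(s.residues) for s in db])
        phmm.calibrate(seed_hmm, n_samples=calib_n, len_dist=lengths,
                       seed=_derived_seed(seed, 1, gi))
        matches.extend(phmm.search(seed_hmm, db, params))
        match_db.extend(db)

    if matches:
        clusters, new_hmms, telescopic = projection_2(
            matches, match_db, cluster_params, proteomes, params,
            calib_n=calib_n, seed=seed, name_prefix=family_name,
        )
    else:
        warnings.warn("telescope degenerate: no metagenome matches", stacklevel=2)
        clusters, new_hmms = None, []
        telescopic = {org: [] for org, _ in proteomes}

    match_ids = {h.target for h in matches}
    new_tel = {
        org: compare_hits(original[org], telescopic[org]) for org, _ in proteomes
    }
    return TelescopeResult(
        family=family_name,
        original_hits=original,
        telescopic_hits=telescopic,
        new_telescopic=new_tel,
        metagenome_matches=matches,
        match_seqs=[s for s in match_db if s.id in match_ids],
        clusters=clusters,
        new_hmms=new_hmms,
        seed_hmm=seed_hmm,
    )


def run_telescope(config: TelescopeConfig) -> TelescopeResult:
    """Run the full telescope from a configuration of file paths."""
    seed_seqs = seqio.read_fasta(config.seed_family, alphabet="protein")
    seed_msa = None
    if any("-" in s.residues for s in seed_seqs):
        seed_msa = align.Msa([(s.id, s.residues) for s in seed_seqs])
        seed_seqs = [Sequence(s.id, s.residues.replace("-", "")) for s in seed_seqs]
    metagenomes = [
        seqio.read_fasta(p, alphabet="nucleotide") for p in config.metagenomes
    ]
    proteomes = [
        (org, seqio.read_fasta(p, alphabet="protein"))
        for org, p in config.proteomes
    ]
    return run_telescope_data(
        seed_seqs, metagenomes, proteomes,
        family_name=config.family_name,
        params=SearchParams(evalue_threshold=config.evalue_threshold),
        orf_min_aa=config.orf_min_aa,
        table_id=config.table_id,
        cluster_params=config.cluster_params,
        calib_n=config.calib_n,
        seed=config.seed,
        pool_metagenomes=config.pool_metagenomes,
        seed_aligned=seed_msa,
    )
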