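"""Seeded transitive-chain benchmarks for the telescope's sensitivity claim.

Each replicate builds one synthetic study (seed family, metagenome with
implanted intermediate homologs, proteome with close/remote homologs
and decoys), runs the full two-projection pipeline, and measures hit
counts and labelled recall for both projections. The replicate sizes
are deliberately compact — one family, one proteome, a few hundred
decoys — so that a multi-replicate evaluation completes in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set

from .synthetic import Benchmark, make_benchmark
from .telescope import TelescopeResult, run_telescope_data

ORGANISM = "org1"


@dataclass
class ReplicateOutcome:
    seed: int
    n_original: int
    n_telescopic: int
    n_new_telescopic: int
    close_ids: Set[str]
    remote_ids: Set[str]
    original_targets: Set[str]
    telescopic_targets: Set[str]

    @property
    def remote_recall_original(self) -> float:
        if not self.remote_ids:
            return float("nan")
        return len(self.remote_ids & self.original_targets) / len(self.remote_ids)

    @property
    def remote_recall_telescopic(self) -> float:
        if not self.remote_ids:
            return float("nan")
        return len(self.remote_ids & self.telescopic_targets) / len(self.remote_ids)

    @property
    def close_in_both(self) -> bool:
        """Every labelled close homolog appears in both hit sets."""
        return (self.close_ids <= self.original_targets
                and self.close_ids <= self.telescopic_targets)

    @property
    def monotone(self) -> bool:
        return self.n_telescopic >= self.n_original


def run_replicate(seed: int, calib_n: int = 1000, **bench_kwargs) -> ReplicateOutcome:
    bench: Benchmark = make_benchmark(seed, **bench_kwargs)
    result: TelescopeResult = run_telescope_data(
        bench.seed_family,
        [bench.contigs],
        [(ORGANISM, bench.proteome)],
        family_name=bench.lineage.name,
        calib_n=calib_n,
        seed=seed,
    )
    labels = bench.proteome_labels
    return ReplicateOutcome(
        seed=seed,
        n_original=len(result.original_hits[ORGANISM]),
        n_telescopic=len(result.telescopic_hits[ORGANISM]),
        n_new_telescopic=len(result.new_telescopic[ORGANISM]),
        close_ids=set(labels.ids("close_homolog")),
        remote_ids=set(labels.ids("remote_homolog")),
        original_targets={h.target for h in result.original_hits[ORGANISM]},
        telescopic_targets={h.target for h in result.telescopic_hits[ORGANISM]},
    )


def run_benchmark(base_seed: int, n_replicates: int = 20,
                  **bench_kwargs) -> List[ReplicateOutcome]:
    return [
        run_replicate(base_seed + 1000 * i, **bench_kwargs)
        for i in range(n_replicates)
    ]


def summarize(outcomes: List[ReplicateOutcome]) -> Dict[str, float]:
    n = len(outcomes)
    with_remote = [o for o in outcomes if o.remote_ids]
    gains = [
        o for o in with_remote
        if o.remote_recall_telescopic > o.remote_recall_original
    ]
    return {
        "n_replicates": n,
        "monotone_fraction": sum(o.monotone for o in outcomes) / n,
        "bona_fide_fraction": sum(o.close_in_both for o in outcomes) / n,
        "recall_gain_fraction": len(gains) / len(with_remote) if with_remote else float("nan"),
        "mean_remote_recall_original": (
            sum(o.remote_recall_original for o in with_remote) / len(with_remote)
            if with_remote else float("nan")),
        "mean_remote_recall_telescopic": (
            sum(o.remote_recall_telescopic for o in with_remote) / len(with_remote)
            if with_remote else float("nan")),
        "mean_n_original": sum(o.n_original for o in outcomes) / n,
        "mean_n_telescopic": sum(o.n_telescopic for o in outcomes) / n,
        "mean_n_new_telescopic": sum(o.n_new_telescopic for o in outcomes) / n,
    }
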