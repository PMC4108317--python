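"""Run manifests and the final comparison report."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from . import __version__
from .telescope import TelescopeResult, term_summary


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-identically (modulo
    timestamps)."""

    version: str = __version__
    config_hash: str = ""
    parameters: Dict[str, object] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def add_file(self, role: str, path: str | Path) -> None:
        self.checksums[role] = sha256_file(path)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "parameters": self.parameters,
            "seeds": self.seeds,
            "checksums": self.checksums,
            "timestamp": self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def counts_frame(result: TelescopeResult) -> pd.DataFrame:
    """Per family x organism hit counts for the two projections."""
    rows = []
    for org in result.original_hits:
        n_orig = len(result.original_hits[org])
        n_tel = len(result.telescopic_hits.get(org, []))
        n_new = len(result.new_telescopic.get(org, set()))
        rows.append({
            "family": result.family,
            "organism": org,
            "n_original": n_orig,
            "n_telescopic": n_tel,
            "n_new_telescopic": n_new,
        })
    return pd.DataFrame(rows)


def render_report(
    result: TelescopeResult,
    annotations: Optional[Mapping[str, list]] = None,
    outdir: str | Path = ".",
) -> Dict[str, Path]:
    """Write the machine- and human-readable summary of one run.

    Produces ``counts.tsv`` (hit counts per organism), ``report.json``
    (counts plus hit lists), and, when an annotation table is given,
    ``terms.tsv`` with the term distribution of each hit set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    counts = counts_frame(result)
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index=False)

    payload = {
        "family": result.family,
        "counts": counts.to_dict(orient="records"),
        "original_hits": {
            org: [h.target for h in hits] for org, hits in result.original_hits.items()
        },
        "telescopic_hits": {
            org: [h.target for h in hits] for org, hits in result.telescopic_hits.items()
        },
        "new_telescopic": {
            org: sorted(ids) for org, ids in result.new_telescopic.items()
        },
        "n_metagenome_matches": len(result.metagenome_matches),
        "n_clusters": len(result.clusters.clusters) if result.clusters else 0,
    }
    if annotations is not None:
        summary = term_summary(result, annotations)
        rows = []
        for which in ("original", "telescopic", "new_telescopic"):
            for term, n in sorted(summary[which].items()):
                rows.append({"hit_set": which, "term": term, "count": n})
        terms = pd.DataFrame(rows, columns=["hit_set", "term", "count"])
        paths["terms"] = outdir / "terms.tsv"
        terms.to_csv(paths["terms"], sep="\t", index=False)
        payload["new_only_terms"] = sorted(summary["new_only_terms"])

    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
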