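"""End-to-end orchestration: extract -> cluster -> consensus -> quantify.

The in-memory :func:`analyze_reads` is the library entry point used by tests
and simulations; :func:`run_pipeline` wraps it with file I/O, a run manifest
(every parameter echoed, read-accounting totals) and per-stage TSV outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import io as fastq_io
from .cluster import BarcodeCluster, cluster_barcodes, tally_barcodes
from .consensus import ConsensusRead, build_consensus
from .panel import Panel, read_panel
from .preprocess import ReadAccounting, SequencedRead, TaggedRead, process_reads
from .quantify import molecule_table


@dataclass
class RunConfig:
    """Parameters of one pipeline run; everything lands in the manifest."""

    panel_path: str
    r1_path: str
    out_dir: str
    r2_path: Optional[str] = None
    seed: int = 17
    max_error_rate: float = 0.1
    min_overlap: int = 3
    max_primer_mismatches: int = 1
    slack: int = 2
    ratio: float = 6.0
    max_dist: int = 1
    offlen_dist: int = 2
    q_cap: int = 60
    majority_floor: float = 0.5


@dataclass
class AnalysisResult:
    """In-memory result of the extract -> cluster -> consensus chain."""

    tagged: list[TaggedRead]
    accounting: ReadAccounting
    clusters: dict[str, list[BarcodeCluster]]  # amplicon_id -> clusters
    consensus: dict[str, list[ConsensusRead]]  # amplicon_id -> consensus reads

    def counts_table(self) -> pd.DataFrame:
        """Per-amplicon molecule (barcode cluster) and read counts."""
        rows = []
        for amp_id in sorted(self.clusters):
            cl = self.clusters[amp_id]
            rows.append(
                (amp_id, "run", len(cl), sum(c.total_reads for c in cl))
            )
        return molecule_table(rows)


def analyze_reads(
    reads: Iterable[SequencedRead],
    panel: Panel,
    config: Optional[RunConfig] = None,
) -> AnalysisResult:
    """Run extraction, clustering and consensus building on a read stream."""
    cfg = config or RunConfig(panel_path="", r1_path="", out_dir="")
    tagged, acct = process_reads(
        reads,
        panel,
        max_error_rate=cfg.max_error_rate,
        min_overlap=cfg.min_overlap,
        max_primer_mismatches=cfg.max_primer_mismatches,
        slack=cfg.slack,
    )
    by_amp: dict[str, list[TaggedRead]] = {}
    for t in tagged:
        by_amp.setdefault(t.amplicon_id, []).append(t)

    clusters: dict[str, list[BarcodeCluster]] = {}
    consensus: dict[str, list[ConsensusRead]] = {}
    for amp_id, amp_reads in sorted(by_amp.items()):
        expected = panel.get(amp_id).expected_barcode_length
        tallies = tally_barcodes(amp_reads, expected)
        amp_clusters = cluster_barcodes(
            tallies, ratio=cfg.ratio, max_dist=cfg.max_dist, offlen_dist=cfg.offlen_dist
        )
        clusters[amp_id] = amp_clusters
        reads_by_barcode: dict[str, list[TaggedRead]] = {}
        for t in amp_reads:
            reads_by_barcode.setdefault(t.barcode, []).append(t)
        cons = []
        for cl in amp_clusters:
            cluster_reads = [
                r for m in cl.members for r in reads_by_barcode[m.barcode]
            ]
            cons.append(
                build_consensus(
                    cluster_reads,
                    canonical_barcode=cl.canonical_barcode,
                    q_cap=cfg.q_cap,
                    majority_floor=cfg.majority_floor,
                )
            )
        consensus[amp_id] = cons
    return AnalysisResult(tagged=tagged, accounting=acct, clusters=clusters,
                          consensus=consensus)


def _write_outputs(result: AnalysisResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (t.read.read_id, t.amplicon_id, t.barcode, t.primer_offset)
            for t in result.tagged
        ],
        columns=["read_id", "amplicon_id", "barcode", "primer_offset"],
    ).to_csv(out / "tagged.tsv", sep="\t", index=False)

    cluster_rows = []
    for amp_id, cls in sorted(result.clusters.items()):
        for c in cls:
            for m in c.members:
                cluster_rows.append(
                    (amp_id, c.canonical_barcode, m.barcode, m.read_count, c.total_reads)
                )
    pd.DataFrame(
        cluster_rows,
        columns=["amplicon_id", "canonical_barcode", "member_barcode",
                 "member_reads", "cluster_total_reads"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    cons_reads = []
    for amp_id, cons in sorted(result.consensus.items()):
        for c in cons:
            cons_reads.append(
                SequencedRead(
                    read_id=f"{amp_id}:{c.canonical_barcode}:{c.supporting_reads}",
                    sequence=c.sequence,
                    qualities=c.qualities,
                )
            )
    fastq_io.write_fastq(cons_reads, out / "consensus.fastq")
    result.counts_table().to_csv(out / "counts.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline run; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    panel = read_panel(config.panel_path)
    reads = fastq_io.read_fastq(config.r1_path)
    result = analyze_reads(reads, panel, config)
    _write_outputs(result, out)
    manifest = {
        "parameters": asdict(config),
        "reads": result.accounting.as_dict(),
        "amplicons": {
            amp_id: {"clusters": len(cls), "reads": sum(c.total_reads for c in cls)}
            for amp_id, cls in sorted(result.clusters.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
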