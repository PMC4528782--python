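"""Consensus read construction from barcode clusters.

All reads sharing one barcode cluster derive from a single original molecule,
so their disagreements are PCR/sequencing errors (or, rarely, a mis-merged
barcode).  Each column is collapsed using both abundance and base quality:
the per-base score is the sum of the phred qualities supporting that base,
the consensus base is the argmax, and the consensus quality is the winner's
score minus the combined score of all other bases, capped at 60 and floored
at 2.  Ties, or a winner supported by no more than half the covering reads,
yield an ``N`` at quality 2 — low per-cluster coverage otherwise inflates
false calls downstream.

Reads within one amplicon share a fixed layout (primer followed by insert),
so columns are primer-anchored rather than realigned per read.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .preprocess import TaggedRead

DELETION = "-"
QUAL_FLOOR = 2


@dataclass
class ColumnPileup:
    """Observations at one 0-based position within the amplicon layout."""

    position: int
    observations: list[tuple[str, int]]  # (base in {A,C,G,T,-}, phred)

    def __post_init__(self):
        if not self.observations:
            raise ValueError("a pileup column needs at least one observation")


@dataclass
class ConsensusRead:
    """One error-suppressed read per barcode cluster."""

    amplicon_id: str
    canonical_barcode: str
    sequence: str
    qualities: list[int]
    supporting_reads: int
    per_position_depth: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.supporting_reads < 1:
            raise ValueError("supporting_reads must be >= 1")


def _call_column(observations: Sequence[tuple[str, int]], q_cap: int,
                 majority_floor: float) -> tuple[str, int]:
    scores: dict[str, int] = {}
    counts: dict[str, int] = {}
    for base, q in observations:
        scores[base] = scores.get(base, 0) + q
        counts[base] = counts.get(base, 0) + 1
    top = max(scores.values())
    winners = [b for b, s in scores.items() if s == top]
    if len(winners) > 1:
        return "N", QUAL_FLOOR
    winner = winners[0]
    if counts[winner] / len(observations) <= majority_floor:
        return "N", QUAL_FLOOR
    qual = top - (sum(scores.values()) - top)
    return winner, max(QUAL_FLOOR, min(q_cap, qual))


def consensus_from_pileups(
    pileups: Sequence[ColumnPileup],
    amplicon_id: str,
    canonical_barcode: str,
    supporting_reads: int,
    q_cap: int = 60,
    majority_floor: float = 0.5,
) -> ConsensusRead:
    """Column-wise consensus over explicit pileups.  Deletion observations
    (``-``) compete like bases; a column won by a deletion is omitted from the
    output sequence."""
    seq: list[str] = []
    quals: list[int] = []
    depth: list[int] = []
    for col in sorted(pileups, key=lambda c: c.position):
        base, q = _call_column(col.observations, q_cap, majority_floor)
        if base == DELETION:
            continue
        seq.append(base)
        quals.append(q)
        depth.append(len(col.observations))
    return ConsensusRead(
        amplicon_id=amplicon_id,
        canonical_barcode=canonical_barcode,
        sequence="".join(seq),
        qualities=quals,
        supporting_reads=supporting_reads,
        per_position_depth=depth,
    )


def build_consensus(
    reads: Sequence[TaggedRead],
    canonical_barcode: Optional[str] = None,
    q_cap: int = 60,
    majority_floor: float = 0.5,
) -> ConsensusRead:
    """Collapse one cluster's reads into a consensus read.

    Reads are anchored at the primer start (position 0 of the consensus is the
    first primer base); shorter reads simply stop contributing.  A single-read
    cluster passes through with its original bases and qualities.
    """
    if not reads:
        raise ValueError("cannot build a consensus from an empty cluster")
    amp_ids = {r.amplicon_id for r in reads}
    if len(amp_ids) > 1:
        raise ValueError(f"cluster spans multiple amplicons: {sorted(amp_ids)}")
    amplicon_id = reads[0].amplicon_id
    if canonical_barcode is None:
        canonical_barcode = reads[0].barcode

    if len(reads) == 1:
        r = reads[0]
        return ConsensusRead(
            amplicon_id=amplicon_id,
            canonical_barcode=canonical_barcode,
            sequence=r.payload_sequence,
            qualities=list(r.payload_qualities),
            supporting_reads=1,
            per_position_depth=[1] * len(r.payload_sequence),
        )

    length = max(len(r.payload_sequence) for r in reads)
    seq: list[str] = []
    quals: list[int] = []
    depth: list[int] = []
    payloads = [(r.payload_sequence, r.payload_qualities) for r in reads]
    for j in range(length):
        obs = [(s[j], q[j]) for s, q in payloads if j < len(s)]
        base, q = _call_column(obs, q_cap, majority_floor)
        seq.append(base)
        quals.append(q)
        depth.append(len(obs))
    return ConsensusRead(
        amplicon_id=amplicon_id,
        canonical_barcode=canonical_barcode,
        sequence="".join(seq),
        qualities=quals,
        supporting_reads=len(reads),
        per_position_depth=depth,
    )


@dataclass
class DepthStats:
    """Per-base depth summary over the target."""

    mean_consensus_depth: float
    median_consensus_depth: float
    mean_raw_to_consensus_ratio: float
    median_raw_to_consensus_ratio: float
    bases_covered: int
    coverage_gaps: int


def consensus_depth_stats(
    consensus_reads: Iterable[ConsensusRead],
    target_lengths: Optional[dict[str, int]] = None,
) -> Optional[DepthStats]:
    """Summarize consensus depth and the raw/consensus read ratio per base.

    Each consensus read covers positions [0, len) of its amplicon's layout;
    raw depth at a base is the sum of supporting reads covering it.  Bases
    with zero consensus depth are coverage gaps and excluded from the ratio.
    Returns None on empty input.
    """
    reads = list(consensus_reads)
    if not reads:
        return None
    lengths: dict[str, int] = dict(target_lengths or {})
    for r in reads:
        lengths[r.amplicon_id] = max(lengths.get(r.amplicon_id, 0), len(r.sequence))
    cons_depth: dict[tuple[str, int], int] = {}
    raw_depth: dict[tuple[str, int], int] = {}
    for r in reads:
        for pos in range(len(r.sequence)):
            key = (r.amplicon_id, pos)
            cons_depth[key] = cons_depth.get(key, 0) + 1
            raw_depth[key] = raw_depth.get(key, 0) + r.supporting_reads
    all_bases = [(a, p) for a, L in lengths.items() for p in range(L)]
    covered = [k for k in all_bases if cons_depth.get(k, 0) > 0]
    gaps = len(all_bases) - len(covered)
    depths = [cons_depth[k] for k in covered]
    ratios = [raw_depth[k] / cons_depth[k] for k in covered]
    return DepthStats(
        mean_consensus_depth=statistics.fmean(depths),
        median_consensus_depth=statistics.median(depths),
        mean_raw_to_consensus_ratio=statistics.fmean(ratios),
        median_raw_to_consensus_ratio=statistics.median(ratios),
        bases_covered=len(covered),
        coverage_gaps=gaps,
    )
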