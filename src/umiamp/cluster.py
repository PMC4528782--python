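"""Error-tolerant clustering of molecular barcodes within one amplicon.

A PCR or sequencing error inside the UMI region creates a "mutant" barcode
that would otherwise be counted as an extra molecule.  Because an error-free
barcode is expected in substantially more reads than any single erroneous
version of it, barcodes within edit distance 1 are merged when the putative
ancestor has at least 6x the reads of the candidate.  Two exceptions allow
more aggressive clustering: barcodes seen in a single read join any cluster
within distance 1 regardless of the read-count ratio, and barcodes that are
not of the expected UMI length join within distance 2 with the ratio likewise
waived (length-changing errors imply an indel already).

The procedure is a deterministic greedy pass over barcodes in decreasing
read-count order; candidates are compared against cluster *canonical*
barcodes only (the highest-count member, treated as the error-free ancestor),
which bounds chain merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib


@dataclass(frozen=True)
class BarcodeTally:
    """One unique barcode and the number of reads containing it."""

    barcode: str
    read_count: int
    is_expected_length: bool = True

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class BarcodeCluster:
    """Barcodes attributed to one original molecular tag."""

    canonical_barcode: str
    members: list[BarcodeTally] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(m.read_count for m in self.members)

    @property
    def canonical_reads(self) -> int:
        return self.members[0].read_count


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions + indels)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def cluster_barcodes(
    tallies: Iterable[BarcodeTally],
    expected_length: Optional[int] = None,
    ratio: float = 6.0,
    max_dist: int = 1,
    offlen_dist: Optional[int] = None,
) -> list[BarcodeCluster]:
    """Cluster one amplicon's barcode tallies into putative molecules.

    Barcodes are visited in order of (read_count descending, barcode
    ascending).  Each barcode joins the existing cluster with the largest
    canonical read count for which the edit distance to the canonical barcode
    is <= ``max_dist`` and the canonical read count is >= ``ratio`` times its
    own (6.0x exactly qualifies); otherwise it founds a new cluster.
    Single-read barcodes and off-length barcodes use the waived-ratio
    exceptions described in the module docstring.

    If ``expected_length`` is given, each tally's ``is_expected_length`` flag
    is recomputed from its barcode length.  Output clusters are sorted by
    (total_reads descending, canonical barcode ascending).
    """
    if offlen_dist is None:
        offlen_dist = max_dist + 1
    items = list(tallies)
    if expected_length is not None:
        items = [
            BarcodeTally(t.barcode, t.read_count, len(t.barcode) == expected_length)
            for t in items
        ]
    items.sort(key=lambda t: (-t.read_count, t.barcode))

    clusters: list[BarcodeCluster] = []
    for t in items:
        if not t.is_expected_length:
            allowed, need_ratio = offlen_dist, False
        elif t.read_count == 1:
            allowed, need_ratio = max_dist, False
        else:
            allowed, need_ratio = max_dist, True
        best = None
        for c in clusters:
            if need_ratio and c.canonical_reads < ratio * t.read_count:
                continue
            if levenshtein(t.barcode, c.canonical_barcode) > allowed:
                continue
            key = (-c.canonical_reads, c.canonical_barcode)
            if best is None or key < best[0]:
                best = (key, c)
        if best is not None:
            best[1].members.append(t)
        else:
            clusters.append(BarcodeCluster(t.barcode, [t]))
    clusters.sort(key=lambda c: (-c.total_reads, c.canonical_barcode))
    return clusters


def collision_probability(n_molecules: int, barcode_length: int) -> float:
    """Birthday approximation of the probability that any two of
    ``n_molecules`` molecules receive the same random barcode.

    Returns ``1 - exp(-n(n-1) / (2 * 4^L))``.  This underestimates the exact
    probability slightly for tiny barcode spaces (e.g. L=1) but is accurate in
    the operating regime, where 4^L vastly exceeds the molecule count.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if not 6 <= barcode_length <= 12:
        raise ValueError("barcode_length must be in [6, 12]")
    return _collision_probability_unchecked(n_molecules, barcode_length)


def _collision_probability_unchecked(n: int, length: int) -> float:
    if n < 2:
        return 0.0
    return 1.0 - math.exp(-n * (n - 1) / (2.0 * 4.0**length))


def tally_barcodes(tagged_reads, expected_length: int) -> list[BarcodeTally]:
    """Aggregate tagged reads (one amplicon) into barcode tallies."""
    counts: dict[str, int] = {}
    for t in tagged_reads:
        counts[t.barcode] = counts.get(t.barcode, 0) + 1
    return [
        BarcodeTally(bc, n, len(bc) == expected_length)
        for bc, n in sorted(counts.items())
    ]
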