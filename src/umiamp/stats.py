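"""Sampling statistics for molecule-counted variant detection.

Once reads are collapsed to molecules, variant detection is a sampling
problem: among n sampled molecules, the number carrying a variant at allele
fraction f is Binomial(n, f), and a caller that requires at least k variant
molecules detects the variant with probability P(X >= k).  These calculators
give the detection power, the molecule count required for a target power, and
the DNA input implied by a capture efficiency (~3,300 haploid genome copies
per 10 ng of human genomic DNA).  Accuracy metrics (sensitivity against a
truth set, false positives per base of evaluated region) and a naive
molecule-level allele counter close the loop for simulation tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import binom

from .consensus import ConsensusRead

#: haploid genome copies in 10 ng of human genomic DNA
COPIES_PER_10NG = 3300.0


@dataclass(frozen=True)
class PowerQuery:
    """Detection-power question: n sampled molecules, variant allele fraction,
    and the minimum number of variant molecules the caller must see."""

    n_molecules: int
    allele_fraction: float
    min_variant_copies: int = 2

    def __post_init__(self):
        if self.n_molecules < 1 or self.min_variant_copies < 1:
            raise ValueError("n_molecules and min_variant_copies must be positive")
        if not 0 < self.allele_fraction <= 1:
            raise ValueError("allele_fraction must be in (0, 1]")


def detection_probability(query: PowerQuery) -> float:
    """P(X >= min_variant_copies) for X ~ Binomial(n_molecules,
    allele_fraction), by exact tail summation."""
    return float(
        binom.sf(query.min_variant_copies - 1, query.n_molecules, query.allele_fraction)
    )


def required_molecules(
    target_prob: float, allele_fraction: float, min_variant_copies: int = 2
) -> int:
    """Smallest n with detection power >= ``target_prob``.

    The power is non-decreasing in n, so bisection on the exact binomial tail
    finds the argmin.
    """
    if not 0 < target_prob < 1:
        raise ValueError("target_prob must be in (0, 1)")

    def power(n: int) -> float:
        return detection_probability(PowerQuery(n, allele_fraction, min_variant_copies))

    hi = max(min_variant_copies, 1)
    while power(hi) < target_prob:
        hi *= 2
    lo = min_variant_copies
    while lo < hi:
        mid = (lo + hi) // 2
        if power(mid) >= target_prob:
            hi = mid
        else:
            lo = mid + 1
    return lo


def required_input_ng(
    n_molecules: int,
    capture_efficiency: float,
    copies_per_10ng: float = COPIES_PER_10NG,
) -> float:
    """Nanograms of genomic DNA needed to sample ``n_molecules`` at the given
    capture efficiency (fraction of input molecules that become barcoded
    consensus reads)."""
    if not 0 < capture_efficiency <= 1:
        raise ValueError("capture_efficiency must be in (0, 1]")
    return 10.0 * n_molecules / (capture_efficiency * copies_per_10ng)


@dataclass
class AccuracyResult:
    """Variant-calling accuracy against a truth set over an evaluated region."""

    tp: int
    fp: int
    truth_total: int
    region_bases: int

    @property
    def sensitivity(self) -> float:
        return self.tp / self.truth_total if self.truth_total else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / self.region_bases

    @property
    def sensitivity_percent(self) -> float:
        """Sensitivity in percent, one decimal (report convention)."""
        return round(100.0 * self.sensitivity, 1)

    def __str__(self):
        return (
            f"sensitivity {self.sensitivity_percent}% ({self.tp}/{self.truth_total}), "
            f"{self.fp} FP over {self.region_bases} bases (FPR {self.fpr:.2e})"
        )


def accuracy_metrics(
    called: Iterable, truth: Iterable, region_bases: int
) -> AccuracyResult:
    """Sensitivity = |called ∩ truth| / |truth|; FPR = |called \\ truth| /
    region_bases.  Inputs are treated as sets of (site, alt) identifiers;
    duplicates are ignored and order is irrelevant."""
    if region_bases <= 0:
        raise ValueError("region_bases must be positive")
    called_set = set(called)
    truth_set = set(truth)
    tp = len(called_set & truth_set)
    fp = len(called_set - truth_set)
    return AccuracyResult(tp=tp, fp=fp, truth_total=len(truth_set), region_bases=region_bases)


def molecule_allele_counter(
    consensus_reads: Sequence[ConsensusRead],
    reference: str,
    min_variant_molecules: int = 2,
    min_fraction: float = 0.005,
    positions: Optional[Iterable[int]] = None,
) -> set[tuple[int, str]]:
    """Naive molecule-level allele caller over primer-anchored consensus reads.

    At each position, consensus molecules supporting each non-reference base
    are counted (``N`` bases are excluded from both numerator and
    denominator); a variant (position, alt) is called when the count reaches
    ``min_variant_molecules`` and its fraction of non-N molecules reaches
    ``min_fraction``.  ``reference`` is the expected sequence in the same
    coordinate frame as the consensus reads; ``positions`` restricts the scan.
    """
    sites = range(len(reference)) if positions is None else positions
    calls: set[tuple[int, str]] = set()
    for pos in sites:
        ref_base = reference[pos]
        counts: dict[str, int] = {}
        depth = 0
        for r in consensus_reads:
            if pos >= len(r.sequence):
                continue
            b = r.sequence[pos]
            if b == "N":
                continue
            depth += 1
            if b != ref_base:
                counts[b] = counts.get(b, 0) + 1
        if depth == 0:
            continue
        for alt, n in counts.items():
            if n >= min_variant_molecules and n / depth >= min_fraction:
                calls.add((pos, alt))
    return calls
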