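"""Universal-tag trimming and per-read barcode extraction.

Reads produced by the barcoded-amplicon protocol have the layout

    5' universal tag | UMI (6-12 nt) | target-specific primer | insert 3'

Trimming removes the universal tag from the 5' end (and the reverse
complement of a tag that read-through reaches at the 3' end); extraction then
locates the target-specific primer of one of the panel's amplicons near its
expected offset and takes everything upstream of the primer as the molecular
barcode.  Reads matching no primer within tolerance are off-target; barcodes
whose length deviates from the expected UMI length are kept but routed to a
separate off-length stream for the clustering stage's special handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib

from .panel import Amplicon, Panel, revcomp


@dataclass
class SequencedRead:
    """A read with per-base phred qualities (offset-33 on disk)."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: Optional["SequencedRead"] = None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.sequence)} bases vs "
                f"{len(self.qualities)} qualities"
            )
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"read {self.read_id}: phred values outside [0, 60]")

    def __len__(self):
        return len(self.sequence)


@dataclass
class TrimResult:
    """Outcome of universal-tag trimming for one read."""

    read: SequencedRead
    trimmed5: bool
    trimmed3: bool

    @property
    def untrimmed(self) -> bool:
        """Neither end matched the universal tag."""
        return not (self.trimmed5 or self.trimmed3)


@dataclass
class TaggedRead:
    """A trimmed read with its amplicon assignment and extracted barcode.

    ``primer_offset`` is the 0-based position in the trimmed read where the
    target-specific primer begins; the barcode is everything before it.
    """

    read: SequencedRead
    amplicon_id: str
    barcode: str
    barcode_qualities: list[int]
    primer_offset: int
    is_expected_length: bool = True

    def __post_init__(self):
        if self.barcode != self.read.sequence[: self.primer_offset]:
            raise ValueError("barcode must equal trimmed read prefix before primer")

    @property
    def payload_sequence(self) -> str:
        """Primer + insert portion (everything after the barcode)."""
        return self.read.sequence[self.primer_offset:]

    @property
    def payload_qualities(self) -> list[int]:
        return self.read.qualities[self.primer_offset:]


@dataclass
class ReadAccounting:
    """Per-run read bookkeeping; categories are mutually exclusive and sum to
    the number of input reads."""

    total: int = 0
    tagged: int = 0
    off_length: int = 0
    off_target: int = 0
    untrimmed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "tagged": self.tagged,
            "off_length": self.off_length,
            "off_target": self.off_target,
            "untrimmed": self.untrimmed,
        }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_5p_match(seq: str, tag: str, max_error_rate: float, min_overlap: int):
    """Best 5' occurrence of ``tag`` (full, with errors, or a partial suffix of
    the tag overlapping the read start).  Returns (trim_end, errors, length) or
    None."""
    candidates = []
    max_err_full = int(max_error_rate * len(tag))
    window = seq[: len(tag) + max_err_full + 2]
    if window:
        res = edlib.align(tag, window, mode="HW", task="locations", k=max_err_full)
        if res["editDistance"] != -1:
            start, end = res["locations"][0]
            candidates.append((end + 1, res["editDistance"], len(tag)))
    # partial overlap: a suffix of the tag hanging over the read start
    for ov in range(len(tag) - 1, min_overlap - 1, -1):
        if ov > len(seq):
            continue
        errs = _hamming(tag[-ov:], seq[:ov])
        if errs <= int(max_error_rate * ov):
            candidates.append((ov, errs, ov))
    if not candidates:
        return None
    # fewest errors per matched base, then longest match
    return min(candidates, key=lambda c: (c[1] / c[2], -c[2]))


def _best_3p_match(seq: str, rc_tag: str, max_error_rate: float, min_overlap: int):
    """Best 3' occurrence of the reverse-complemented tag.  Returns
    (trim_start, errors, length) or None."""
    candidates = []
    max_err_full = int(max_error_rate * len(rc_tag))
    w = len(rc_tag) + max_err_full + 2
    offset = max(0, len(seq) - w)
    window = seq[offset:]
    if window:
        res = edlib.align(rc_tag, window, mode="HW", task="locations", k=max_err_full)
        if res["editDistance"] != -1:
            start, end = res["locations"][0]
            candidates.append((offset + (start or 0), res["editDistance"], len(rc_tag)))
    # partial overlap: a prefix of rc(tag) at the read's 3' end
    for ov in range(len(rc_tag) - 1, min_overlap - 1, -1):
        if ov > len(seq):
            continue
        errs = _hamming(rc_tag[:ov], seq[-ov:])
        if errs <= int(max_error_rate * ov):
            candidates.append((len(seq) - ov, errs, ov))
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c[1] / c[2], -c[2]))


def trim_universal(
    read: SequencedRead,
    tag5: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> TrimResult:
    """Remove the universal tag from the 5' end and its reverse complement
    from the 3' end, allowing mismatches/indels up to ``max_error_rate`` of the
    matched length and partial end overlaps of at least ``min_overlap`` bases.
    Qualities are trimmed in lockstep; bases that are kept are never altered.
    """
    if not tag5:
        raise ValueError("tag5 must be non-empty")
    if len(read) == 0:
        return TrimResult(read, trimmed5=False, trimmed3=False)
    seq = read.sequence
    hit5 = _best_5p_match(seq, tag5, max_error_rate, min_overlap)
    start = hit5[0] if hit5 else 0
    hit3 = _best_3p_match(seq[start:], revcomp(tag5), max_error_rate, min_overlap)
    end = start + hit3[0] if hit3 else len(seq)
    trimmed = SequencedRead(
        read_id=read.read_id,
        sequence=seq[start:end],
        qualities=read.qualities[start:end],
        mate=read.mate,
    )
    return TrimResult(trimmed, trimmed5=hit5 is not None, trimmed3=hit3 is not None)


def assign_and_extract(
    read: SequencedRead,
    panel: Panel,
    max_primer_mismatches: int = 1,
    slack: int = 2,
) -> Optional[TaggedRead]:
    """Assign a trimmed read to an amplicon and extract its barcode.

    Each amplicon's barcoded-primer sequence is searched at offsets within
    ``slack`` of the expected barcode length, allowing up to
    ``max_primer_mismatches`` substitutions and no indels (an indel inside the
    primer shifts the barcode boundary unreliably, so such reads fall through
    to off-target).  The unique best hit — fewest mismatches, then smallest
    offset — assigns the amplicon; ties across amplicons and reads with no hit
    return None (off-target).
    """
    seq = read.sequence
    best_per_amp: list[tuple[int, int, Amplicon]] = []
    for amp in panel:
        primer = amp.bc_primer.sequence
        exp = amp.expected_barcode_length
        best = None
        for off in range(max(0, exp - slack), exp + slack + 1):
            window = seq[off : off + len(primer)]
            if len(window) < len(primer):
                break
            mm = _hamming(window, primer)
            if mm <= max_primer_mismatches and (best is None or mm < best[0]):
                best = (mm, off)
                if mm == 0:
                    break
        if best is not None:
            best_per_amp.append((best[0], best[1], amp))
    if not best_per_amp:
        return None
    best_per_amp.sort(key=lambda t: (t[0], t[1]))
    if len(best_per_amp) > 1 and best_per_amp[0][0] == best_per_amp[1][0]:
        return None  # ambiguous across amplicons
    mm, off, amp = best_per_amp[0]
    return TaggedRead(
        read=read,
        amplicon_id=amp.amplicon_id,
        barcode=seq[:off],
        barcode_qualities=read.qualities[:off],
        primer_offset=off,
        is_expected_length=(off == amp.expected_barcode_length),
    )


def extract_from_alignment(aln, panel: Panel, slack: int = 2) -> Optional[TaggedRead]:
    """Barcode extraction from an externally aligned read (pysam record).

    The amplicon whose primer-start reference coordinate matches the read's
    alignment start within ``slack`` bases is assigned; the barcode is the
    query bases preceding the inferred primer start (typically the aligner's
    5' soft clip).  Reads mapping to no panel interval return None.
    """
    if aln.is_unmapped or aln.reference_name is None:
        raise ValueError(
            f"read {aln.query_name} has no mapping; use assign_and_extract instead"
        )
    for amp in panel:
        ri = amp.reference_interval
        if ri is None or ri.chrom != aln.reference_name:
            continue
        if abs(aln.reference_start - ri.start) > slack:
            continue
        primer_start_in_read = aln.query_alignment_start - (aln.reference_start - ri.start)
        if primer_start_in_read < 0:
            continue
        seq = aln.query_sequence
        quals = list(aln.query_qualities) if aln.query_qualities is not None else [30] * len(seq)
        read = SequencedRead(aln.query_name, seq, quals)
        return TaggedRead(
            read=read,
            amplicon_id=amp.amplicon_id,
            barcode=seq[:primer_start_in_read],
            barcode_qualities=quals[:primer_start_in_read],
            primer_offset=primer_start_in_read,
            is_expected_length=(primer_start_in_read == amp.expected_barcode_length),
        )
    return None


def process_reads(
    reads: Iterable[SequencedRead],
    panel: Panel,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    max_primer_mismatches: int = 1,
    slack: int = 2,
) -> tuple[list[TaggedRead], ReadAccounting]:
    """Trim + extract a read stream; returns tagged reads (expected-length and
    off-length alike) and the read accounting."""
    acct = ReadAccounting()
    tagged: list[TaggedRead] = []
    tag5 = panel.universal_tag_bc
    for read in reads:
        acct.total += 1
        if tag5:
            tr = trim_universal(read, tag5, max_error_rate, min_overlap)
            if tr.untrimmed:
                acct.untrimmed += 1
                continue
            read = tr.read
        t = assign_and_extract(read, panel, max_primer_mismatches, slack)
        if t is None:
            acct.off_target += 1
        elif t.is_expected_length:
            acct.tagged += 1
            tagged.append(t)
        else:
            acct.off_length += 1
            tagged.append(t)
    return tagged, acct
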