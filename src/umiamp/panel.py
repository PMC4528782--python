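"""Amplicon panel model and primer cross-dimer screening.

A panel is a set of amplicons, each amplified by a pair of target-specific
primers.  One primer of each pair (the *BC primer*) carries a random molecular
barcode (UMI) between its 5' universal tag and its 3' target-specific
sequence; the other (the *non-BC primer*) carries only the second universal
tag.  Because hundreds of primers are pooled in one reaction, any pair of
target-specific sequences whose 3' ends are mutually complementary risks
primer-dimer amplification; the screen implemented here rejects a primer pair
when 11 or more contiguous bases at one primer's 3' end form a perfect
reverse-complement match anywhere in the other primer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

#: columns a panel TSV must provide
REQUIRED_COLUMNS = ("amplicon_id", "bc_primer_seq", "nonbc_primer_seq", "barcode_length")
#: optional columns (reference coordinates and simulation insert)
OPTIONAL_COLUMNS = (
    "universal_tag_bc",
    "universal_tag_nonbc",
    "chrom",
    "start",
    "end",
    "strand",
    "insert_seq",
)


class PanelFormatError(ValueError):
    """Panel file is malformed (missing column, bad value, duplicate id)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    if not seq:
        raise PanelFormatError(f"{what}: sequence is empty")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PanelFormatError(
            f"{what}: non-ACGT character(s) {sorted(bad)!r} in sequence {seq!r}"
        )
    return seq


@dataclass(frozen=True)
class Primer:
    """A target-specific primer (5'->3', plain ACGT only).

    ``role`` distinguishes the barcoded primer (carries the UMI between its
    universal tag and target-specific sequence) from the non-barcoded one.
    Degenerate IUPAC codes are rejected: panels here use plain DNA.
    """

    primer_id: str
    sequence: str
    role: str  # "barcoded" | "non_barcoded"
    universal_tag: str = ""

    def __post_init__(self):
        _check_dna(self.sequence, f"primer {self.primer_id}")
        if self.universal_tag:
            _check_dna(self.universal_tag, f"primer {self.primer_id} universal tag")
        if self.role not in ("barcoded", "non_barcoded"):
            raise ValueError(f"primer {self.primer_id}: bad role {self.role!r}")


@dataclass(frozen=True)
class ReferenceInterval:
    """0-based half-open genomic interval of the amplified insert."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class Amplicon:
    """One amplicon: its primer pair, expected UMI length and optional
    reference interval / insert sequence (the latter used for simulation)."""

    amplicon_id: str
    bc_primer: Primer
    nonbc_primer: Primer
    expected_barcode_length: int = 10
    reference_interval: Optional[ReferenceInterval] = None
    insert_sequence: Optional[str] = None

    def __post_init__(self):
        if not 6 <= self.expected_barcode_length <= 12:
            raise ValueError(
                f"amplicon {self.amplicon_id}: barcode length "
                f"{self.expected_barcode_length} outside [6, 12]"
            )
        if self.insert_sequence is not None:
            _check_dna(self.insert_sequence, f"amplicon {self.amplicon_id} insert")


@dataclass
class Panel:
    """An ordered collection of amplicons sharing two universal tags."""

    amplicons: list[Amplicon] = field(default_factory=list)
    universal_tag_bc: str = ""
    universal_tag_nonbc: str = ""

    def __post_init__(self):
        ids = [a.amplicon_id for a in self.amplicons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelFormatError(f"duplicate amplicon_id(s): {sorted(dupes)}")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self):
        return len(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)


def read_panel(path: str | Path) -> Panel:
    """Read a tab-separated panel definition file.

    Required columns: ``amplicon_id``, ``bc_primer_seq``, ``nonbc_primer_seq``,
    ``barcode_length``.  Optional: universal tags, ``chrom``/``start``/``end``/
    ``strand`` (0-based half-open) and ``insert_seq``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"panel file {path}: missing required column {col!r}")
    tag_bc = ""
    tag_nonbc = ""
    amplicons = []
    for i, row in df.iterrows():
        amp_id = str(row["amplicon_id"])
        tag_bc = str(row.get("universal_tag_bc", "") or tag_bc or "")
        tag_nonbc = str(row.get("universal_tag_nonbc", "") or tag_nonbc or "")
        try:
            bc = Primer(f"{amp_id}_bc", str(row["bc_primer_seq"]), "barcoded", tag_bc)
            nonbc = Primer(
                f"{amp_id}_nonbc", str(row["nonbc_primer_seq"]), "non_barcoded", tag_nonbc
            )
        except PanelFormatError as e:
            raise PanelFormatError(f"panel row {i} ({amp_id}): {e}") from e
        interval = None
        if "chrom" in df.columns and pd.notna(row.get("chrom")):
            interval = ReferenceInterval(
                str(row["chrom"]), int(row["start"]), int(row["end"]),
                str(row.get("strand", "+") or "+"),
            )
        insert = None
        if "insert_seq" in df.columns and pd.notna(row.get("insert_seq")):
            insert = str(row["insert_seq"])
        amplicons.append(
            Amplicon(
                amplicon_id=amp_id,
                bc_primer=bc,
                nonbc_primer=nonbc,
                expected_barcode_length=int(row["barcode_length"]),
                reference_interval=interval,
                insert_sequence=insert,
            )
        )
    return Panel(amplicons, universal_tag_bc=tag_bc, universal_tag_nonbc=tag_nonbc)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to its TSV representation."""
    rows = []
    for a in panel:
        row = {
            "amplicon_id": a.amplicon_id,
            "bc_primer_seq": a.bc_primer.sequence,
            "nonbc_primer_seq": a.nonbc_primer.sequence,
            "universal_tag_bc": panel.universal_tag_bc,
            "universal_tag_nonbc": panel.universal_tag_nonbc,
            "barcode_length": a.expected_barcode_length,
        }
        if a.reference_interval is not None:
            ri = a.reference_interval
            row.update(chrom=ri.chrom, start=ri.start, end=ri.end, strand=ri.strand)
        if a.insert_sequence is not None:
            row["insert_seq"] = a.insert_sequence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def cross_dimer_conflict(
    candidate: Primer | str,
    existing: Primer | str,
    k: int = 11,
    allow_short: bool = False,
) -> bool:
    """Test a primer pair for 3' cross-dimer risk.

    True iff the reverse complement of one primer's 3'-terminal ``k``-mer
    occurs as an exact substring anywhere in the other primer (checked in both
    directions, since extension can proceed off either 3' end).  The default
    k=11 encodes the rule that a match of more than ten complementary bases is
    rejected.

    Sequences shorter than ``k`` raise unless ``allow_short`` is set, in which
    case k is reduced to the shorter sequence length.
    """
    a = candidate.sequence if isinstance(candidate, Primer) else candidate
    b = existing.sequence if isinstance(existing, Primer) else existing
    shortest = min(len(a), len(b))
    if shortest < k:
        if not allow_short:
            raise ValueError(
                f"sequence shorter than k={k}; pass allow_short=True to reduce k"
            )
        k = shortest
    return revcomp(a[-k:]) in b or revcomp(b[-k:]) in a


def screen_panel(panel: Panel, k: int = 11) -> list[tuple[str, str]]:
    """All unordered primer-id pairs in the panel with 3' cross-dimer risk.

    Every target-specific primer sequence in the panel (barcoded and
    non-barcoded alike) is screened against every other; an empty result means
    the panel passes.  Output is sorted and independent of panel order.
    """
    primers = []
    for a in panel:
        primers.append(a.bc_primer)
        primers.append(a.nonbc_primer)
    conflicts = set()
    for p, q in itertools.combinations(primers, 2):
        if cross_dimer_conflict(p, q, k=k, allow_short=True):
            conflicts.add(tuple(sorted((p.primer_id, q.primer_id))))
    return sorted(conflicts)
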