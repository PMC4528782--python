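"""FASTQ input/output helpers (phred+33, optional gzip)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import SequencedRead


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Iterate reads from a FASTQ (or gzipped FASTQ) file."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield SequencedRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[SequencedRead], path: str | Path,
                comments: dict[str, str] | None = None) -> int:
    """Write reads to FASTQ; ``comments`` maps read_id to a description
    string appended after the id (e.g. ``UMI:<seq> AMP:<id>``). Returns the
    number of reads written."""
    n = 0
    with _open_text(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            if comments and r.read_id in comments:
                rec.description = comments[r.read_id]
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
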