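"""Raw-read quality control, poly(T) trimming and alignment ingestion.

The stage order is quality filter -> leading-T trim -> minimum-length
rule, and a read-accounting ledger is kept at every step so that
``n_raw == n_dropped_quality + n_dropped_short + n_unmapped + n_termini``
always holds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .models import RawRead

log = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 10
DEFAULT_MAX_LOW_FRACTION = 0.5
DEFAULT_MIN_LENGTH = 16


def quality_filter(
    read: RawRead,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    max_low_fraction: float = DEFAULT_MAX_LOW_FRACTION,
) -> bool:
    """Keep a read unless *more than* ``max_low_fraction`` of its bases
    fall below ``q_threshold``.

    The comparison is strictly greater: a read with exactly half its
    bases low-quality is kept under the defaults.
    """
    if len(read) == 0:
        warnings.warn(f"empty read {read.id!r} dropped", stacklevel=2)
        return False
    n_low = sum(1 for q in read.quality if q < q_threshold)
    return not (n_low / len(read) > max_low_fraction)


def trim_leading_t(
    read: RawRead, min_length: int = DEFAULT_MIN_LENGTH
) -> RawRead | None:
    """Strip the longest leading poly(T) prefix (the reverse-complemented
    poly(A) tail) and drop the read if fewer than ``min_length`` bases
    remain. Returns the trimmed read, or None when dropped."""
    n = 0
    seq = read.sequence
    while n < len(seq) and seq[n] in "Tt":
        n += 1
    if len(seq) - n < min_length:
        return None
    return RawRead(id=read.id, sequence=seq[n:], quality=read.quality[n:])


@dataclass
class ProcessingStats:
    """Read-accounting ledger for one library."""

    library: str = ""
    n_raw: int = 0
    n_dropped_quality: int = 0
    n_dropped_short: int = 0
    n_unmapped: int = 0
    n_secondary_ignored: int = 0
    n_termini: int = 0

    def assert_conserved(self) -> None:
        total = (
            self.n_dropped_quality + self.n_dropped_short + self.n_unmapped + self.n_termini
        )
        if total != self.n_raw:
            raise AssertionError(
                f"{self.library}: read accounting broken: raw={self.n_raw} != "
                f"quality({self.n_dropped_quality}) + short({self.n_dropped_short}) "
                f"+ unmapped({self.n_unmapped}) + termini({self.n_termini})"
            )


def process_fastq(
    fastq_path: str | Path,
    out_path: str | Path | None = None,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    max_low_fraction: float = DEFAULT_MAX_LOW_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
    library: str | None = None,
) -> tuple[dict[str, RawRead], ProcessingStats]:
    """Run quality filter + trim + length rule over a FASTQ file.

    Returns the surviving trimmed reads keyed by id, plus the ledger.
    Optionally writes the trimmed reads back out as FASTQ.
    """
    library = library or Path(fastq_path).stem
    stats = ProcessingStats(library=library)
    kept: dict[str, RawRead] = {}
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        stats.n_raw += 1
        read = RawRead(
            id=rec.id,
            sequence=str(rec.seq),
            quality=list(rec.letter_annotations["phred_quality"]),
        )
        if not quality_filter(read, q_threshold, max_low_fraction):
            stats.n_dropped_quality += 1
            continue
        trimmed = trim_leading_t(read, min_length)
        if trimmed is None:
            stats.n_dropped_short += 1
            continue
        kept[trimmed.id] = trimmed
    if out_path is not None:
        with open(out_path, "w") as fh:
            for read in kept.values():
                qual = "".join(chr(q + 33) for q in read.quality)
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
    return kept, stats


# ---------------------------------------------------------------------------
# alignment ingestion
# ---------------------------------------------------------------------------


def _terminus_from_span(
    start: int, end: int, aln_strand: str, orientation: str
) -> tuple[int, str]:
    """Map an alignment span to (terminus position, transcript strand).

    Under the default ``antisense`` orientation the read (which begins at
    the poly(A) tail) maps antisense to its transcript: a minus-strand
    alignment implies a plus-strand transcript whose last transcribed
    base is the alignment's end-most coordinate, and vice versa. The
    ``sense`` orientation inverts the bookkeeping.
    """
    if orientation == "antisense":
        if aln_strand == "-":
            return end - 1, "+"
        return start, "-"
    if aln_strand == "+":
        return end - 1, "+"
    return start, "-"


def ingest_alignments(
    alignments: str | Path,
    reads: dict[str, RawRead] | None = None,
    *,
    library: str = "",
    orientation: str = "antisense",
    min_mapq: int = 0,
    reference_lengths: dict[str, int] | None = None,
    stats: ProcessingStats | None = None,
) -> pd.DataFrame:
    """Turn per-read alignments (BED6 or SAM/BAM) into a terminus table.

    Returns a DataFrame with columns read_id, chrom, position, strand,
    library, where ``position`` is the genomic coordinate of the
    terminus-adjacent base on the transcriptional ``strand``.

    When ``reads`` is given, alignment records must reference known read
    ids, and reads without any alignment are counted as unmapped in
    ``stats``. Secondary/supplementary/unmapped records are ignored and
    counted.
    """
    if orientation not in ("antisense", "sense"):
        raise ValueError(f"unknown read orientation {orientation!r}")
    stats = stats if stats is not None else ProcessingStats(library=library)
    path = Path(alignments)
    rows: list[tuple[str, str, int, str, str]] = []
    seen: set[str] = set()

    def emit(name: str, chrom: str, start: int, end: int, aln_strand: str) -> None:
        if reads is not None and name not in reads:
            raise KeyError(f"alignment references unknown read id {name!r}")
        if reference_lengths is not None:
            if chrom not in reference_lengths or end > reference_lengths[chrom] or start < 0:
                raise ValueError(
                    f"alignment of {name!r} outside reference: {chrom}:{start}-{end}"
                )
        pos, strand = _terminus_from_span(start, end, aln_strand, orientation)
        rows.append((name, chrom, pos, strand, library))
        seen.add(name)

    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        for rec in bed.itertuples():
            emit(rec.name, rec.chrom, int(rec.start), int(rec.end), rec.strand)
    else:
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    stats.n_secondary_ignored += 1
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                emit(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )

    if reads is not None:
        missing = set(reads) - seen
        stats.n_unmapped += len(missing)
        if missing:
            log.info("%s: %d trimmed reads had no alignment", library, len(missing))
    stats.n_termini += len(rows)
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "position", "strand", "library"]
    )
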