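"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RawRead:
    """One unprocessed sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EndRead:
    """A trimmed read anchored to the genomic position of its terminus.

    ``position`` is the 0-based coordinate of the terminus-adjacent base
    (the last transcribed base for 3'-end libraries); ``strand`` is the
    transcriptional strand implied by the library chemistry.
    """

    id: str
    sequence: str
    library: str
    chrom: str
    position: int
    strand: str


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each a sorted list of exons.

    Exons are (start, end) 0-based half-open tuples, non-overlapping and
    sorted in genomic order within each transcript.
    """

    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(e[0] for exons in self.transcripts.values() for e in exons)

    @property
    def end(self) -> int:
        return max(e[1] for exons in self.transcripts.values() for e in exons)

    def three_prime_ends(self) -> list[int]:
        """Transcript 3' end coordinates (position of the last transcribed
        base, 0-based) for every transcript."""
        out = []
        for exons in self.transcripts.values():
            if self.strand == "+":
                out.append(exons[-1][1] - 1)
            else:
                out.append(exons[0][0])
        return out

    def introns(self, transcript: str) -> list[tuple[int, int]]:
        exons = self.transcripts[transcript]
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


#: Within-gene class codes: c exon-confined, e exon-to-intron extended
#: (>=10 bp penetration), i intronic, o exonic with extension, p within
#: 2 kb downstream of a transcript, x antisense-exonic, u unassigned.
CLASS_CODES = ("c", "e", "i", "o", "p", "x", "u")

#: Conventional sites derive from exons or just downstream; the
#: non-conventional group covers intron-involved and antisense sites.
CONVENTIONAL_CODES = frozenset("cop")
NON_CONVENTIONAL_CODES = frozenset("eix")

DE_CATEGORIES = ("gained", "lost", "up", "down", "ns")
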