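"""Site annotation: gene assignment with within-gene class codes,
downstream A-rich-stretch (ARS) classification, and upstream polyA-signal
scanning.

Class codes (re-implemented from their definitions; an external
comparison tool is not invoked):

``c``
    cluster span confined within an exon of a same-strand gene
``e``
    span overlaps an exon and extends at least 10 bp into an adjacent
    intron
``i``
    span completed within an intron
``o``
    span overlaps exons otherwise (e.g. extends beyond the terminal exon,
    or crosses a junction with <10 bp of intron)
``p``
    span within 2 kb downstream of a transcript 3' end, outside the gene
``x``
    span overlaps an exon of an opposite-strand gene and no same-strand
    assignment exists
``u``
    unassigned / intergenic

Precedence is c > e > i > o within a gene, same-strand assignment over
downstream (p) over antisense (x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

from .models import (
    CONVENTIONAL_CODES,
    GeneModel,
    NON_CONVENTIONAL_CODES,
)

log = logging.getLogger(__name__)

DEFAULT_DOWNSTREAM_LEN = 30
DEFAULT_UPSTREAM_LEN = 100
DEFAULT_MIN_INTRON_PENETRATION = 10
DEFAULT_MAX_DOWNSTREAM_DISTANCE = 2000

#: Default polyA-signal hexamers: the canonical AAUAAA family. The study
#: design this package follows scans a larger externally published list;
#: supply it via ``load_signal_list`` for replication.
DEFAULT_SIGNALS = ("AATAAA", "ATTAAA")


# ---------------------------------------------------------------------------
# reference loading
# ---------------------------------------------------------------------------


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (requires a ``gene_biotype`` or
    ``biotype`` attribute on gene features)."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (
            g.attributes.get("gene_biotype") or g.attributes.get("biotype") or ["unknown"]
        )[0]
        symbol = (g.attributes.get("Name") or [g.id])[0]
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            if exons:
                transcripts[t.id] = exons
        if not transcripts:
            # gene without transcript children: treat its span as one exon
            transcripts[f"{g.id}.t1"] = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id.removeprefix("gene:"),
                symbol=symbol,
                biotype=biotype,
                chrom=g.seqid,
                strand=g.strand,
                transcripts=transcripts,
            )
        )
    return genes


def load_signal_list(path: str | Path) -> list[str]:
    """One hexamer per line; U is normalised to T, blanks and '#'
    comments ignored."""
    signals = []
    for line in Path(path).read_text().splitlines():
        s = line.split("#")[0].strip().upper().replace("U", "T")
        if s:
            signals.append(s)
    return signals


# ---------------------------------------------------------------------------
# gene index + class codes
# ---------------------------------------------------------------------------


@dataclass
class GeneIndex:
    """Interval index over gene spans, padded by the downstream (p-class)
    search distance."""

    genes: list[GeneModel]
    max_downstream: int = DEFAULT_MAX_DOWNSTREAM_DISTANCE
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for i, g in enumerate(self.genes):
            pad_lo = self.max_downstream if g.strand == "-" else 0
            pad_hi = self.max_downstream if g.strand == "+" else 0
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start - pad_lo, g.end + pad_hi, i)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree.overlap(start, end), key=lambda iv: iv.data)]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _classify_within_gene(
    span: tuple[int, int], gene: GeneModel, min_penetration: int
) -> str | None:
    """Best class among the gene's transcripts (c > e > i > o), or None
    when the span does not touch any transcript."""
    s, e = span
    best: str | None = None
    order = {"c": 0, "e": 1, "i": 2, "o": 3}
    for tid, exons in gene.transcripts.items():
        t0, t1 = exons[0][0], exons[-1][1]
        if _overlap(s, e, t0, t1) == 0:
            continue
        exonic = any(x0 <= s and e <= x1 for x0, x1 in exons)
        if exonic:
            code = "c"
        else:
            introns = gene.introns(tid)
            if any(i0 <= s and e <= i1 for i0, i1 in introns):
                code = "i"
            elif any(_overlap(s, e, x0, x1) > 0 for x0, x1 in exons):
                pen = max(
                    (_overlap(s, e, i0, i1) for i0, i1 in introns), default=0
                )
                code = "e" if pen >= min_penetration else "o"
            else:
                # touches the padded transcript span only (shouldn't occur
                # for unpadded spans): treat as outside
                continue
        if best is None or order[code] < order[best]:
            best = code
    return best


def _exonic_overlap(span: tuple[int, int], gene: GeneModel) -> int:
    s, e = span
    return max(
        sum(_overlap(s, e, x0, x1) for x0, x1 in exons)
        for exons in gene.transcripts.values()
    )


def _downstream_distance(span: tuple[int, int], gene: GeneModel) -> int | None:
    """Distance (1-based, bp) from the nearest transcript 3' end to the
    span's proximal edge, when the span lies strictly downstream."""
    s, e = span
    dists = []
    for exons in gene.transcripts.values():
        if gene.strand == "+":
            t_end = exons[-1][1]  # half-open end
            d = s - t_end + 1
        else:
            t_start = exons[0][0]
            d = t_start - (e - 1)
        if d >= 1:
            dists.append(d)
    return min(dists) if dists else None


def classify_site(
    chrom: str,
    span_start: int,
    span_end: int,
    strand: str,
    index: GeneIndex,
    *,
    position: int | None = None,
    min_penetration: int = DEFAULT_MIN_INTRON_PENETRATION,
    max_downstream: int = DEFAULT_MAX_DOWNSTREAM_DISTANCE,
) -> tuple[GeneModel | None, str]:
    """Assign a site (cluster span, inclusive coordinates) to a gene and
    class code. Returns (gene or None, code)."""
    s, e = span_start, span_end + 1  # to half-open
    position = position if position is not None else span_start
    candidates = index.overlapping(chrom, s, e)

    same = [
        g
        for g in candidates
        if g.strand == strand and _overlap(s, e, g.start, g.end) > 0
    ]
    if same:
        if len(same) > 1:
            same.sort(
                key=lambda g: (
                    -_exonic_overlap((s, e), g),
                    min(abs(position - t3) for t3 in g.three_prime_ends()),
                )
            )
            log.info(
                "site %s:%d-%d overlaps %d same-strand genes; assigned to %s",
                chrom,
                s,
                e,
                len(same),
                same[0].gene_id,
            )
        gene = same[0]
        code = _classify_within_gene((s, e), gene, min_penetration)
        if code is not None:
            return gene, code
        # overlaps the gene span but no transcript (rare): fall through

    downstream = [
        (d, g)
        for g in candidates
        if g.strand == strand
        and (d := _downstream_distance((s, e), g)) is not None
        and d <= max_downstream
        and _overlap(s, e, g.start, g.end) == 0
    ]
    if downstream:
        downstream.sort(key=lambda t: t[0])
        return downstream[0][1], "p"

    anti = [
        g
        for g in candidates
        if g.strand != strand and _exonic_overlap((s, e), g) > 0
    ]
    if anti:
        anti.sort(key=lambda g: -_exonic_overlap((s, e), g))
        return anti[0], "x"

    return None, "u"


# ---------------------------------------------------------------------------
# ARS rule + signal scan
# ---------------------------------------------------------------------------


def is_a_rich(
    seq: str, min_run: int = 7, window: int = 10, window_count: int = 8
) -> bool:
    """True iff the sequence contains >= ``min_run`` consecutive A, or
    any ``window``-bp window holding >= ``window_count`` A."""
    s = seq.upper()
    run = best = 0
    for ch in s:
        run = run + 1 if ch == "A" else 0
        if run > best:
            best = run
    if best >= min_run:
        return True
    w = min(window, len(s))
    count = s[:w].count("A")
    if count >= window_count:
        return True
    for i in range(w, len(s)):
        count += (s[i] == "A") - (s[i - w] == "A")
        if count >= window_count:
            return True
    return False


def downstream_sequence(
    genome: dict[str, str], chrom: str, position: int, strand: str, length: int
) -> str:
    """Transcript-strand sequence of ``length`` bases immediately
    downstream of the site position (truncated at chromosome ends)."""
    seq = genome[chrom]
    if strand == "+":
        out = seq[position + 1 : position + 1 + length]
    else:
        out = reverse_complement(seq[max(position - length, 0) : position])
    if len(out) < length:
        log.warning(
            "site %s:%d%s: only %d bp available downstream", chrom, position, strand, len(out)
        )
    return out


def classify_ars(
    genome: dict[str, str],
    chrom: str,
    position: int,
    strand: str,
    downstream_len: int = DEFAULT_DOWNSTREAM_LEN,
) -> bool:
    """ARS (True) vs NARS (False) for the region downstream of a site,
    read on the transcript strand — the adenines that mislead oligo(dT)
    priming are those of the continuing sense sequence."""
    return is_a_rich(
        downstream_sequence(genome, chrom, position, strand, downstream_len)
    )


def scan_signals(
    genome: dict[str, str],
    chrom: str,
    position: int,
    strand: str,
    signals: list[str] | tuple[str, ...] = DEFAULT_SIGNALS,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
) -> list[tuple[str, int]]:
    """All occurrences of the listed hexamers whose 3'-most base lies
    within ``upstream_len`` bp upstream of the site, on the transcript
    strand. Offsets are negative (-1 = immediately 5' of the site),
    measured to the signal's 3'-most base; overlapping matches are all
    reported, sorted closest-first."""
    if not signals:
        raise ValueError("signal list is empty")
    sigs = [s.upper().replace("U", "T") for s in signals]
    k = max(len(s) for s in sigs)
    seq = genome[chrom]
    # extend 5' so a motif *ending* at -upstream_len is still found
    if strand == "+":
        lo = max(position - upstream_len - (k - 1), 0)
        window = seq[lo:position]
    else:
        hi = min(position + 1 + upstream_len + (k - 1), len(seq))
        window = reverse_complement(seq[position + 1 : hi])
    w = len(window)
    hits: list[tuple[str, int]] = []
    for sig in sigs:
        start = window.find(sig)
        while start != -1:
            offset = -(w - (start + len(sig)) + 1)
            if -upstream_len <= offset <= -1:
                hits.append((sig, offset))
            start = window.find(sig, start + 1)
    return sorted(hits, key=lambda h: (-h[1], h[0]))


# ---------------------------------------------------------------------------
# site-table annotation + biotype summaries
# ---------------------------------------------------------------------------


def conventionality(code: str) -> str | None:
    if code in CONVENTIONAL_CODES:
        return "conventional"
    if code in NON_CONVENTIONAL_CODES:
        return "non_conventional"
    return None


def annotate_sites(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    genome: dict[str, str],
    signals: list[str] | tuple[str, ...] = DEFAULT_SIGNALS,
    *,
    downstream_len: int = DEFAULT_DOWNSTREAM_LEN,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
    min_penetration: int = DEFAULT_MIN_INTRON_PENETRATION,
    max_downstream: int = DEFAULT_MAX_DOWNSTREAM_DISTANCE,
) -> pd.DataFrame:
    """Annotate a called-site table with gene assignment, class code,
    ARS status and polyA-signal hits.

    Returns one row per site: site_id, gene_id, symbol, biotype,
    class_code, conventionality, distal, ars, n_signal_hits,
    best_signal, best_offset, signal_hits (semicolon-joined).
    """
    index = GeneIndex(genes, max_downstream=max_downstream)
    rows = []
    for site in sites.itertuples():
        gene, code = classify_site(
            site.chrom,
            int(site.span_start),
            int(site.span_end),
            site.strand,
            index,
            position=int(site.position),
            min_penetration=min_penetration,
            max_downstream=max_downstream,
        )
        ars = classify_ars(
            genome, site.chrom, int(site.position), site.strand, downstream_len
        )
        hits = scan_signals(
            genome, site.chrom, int(site.position), site.strand, signals, upstream_len
        )
        rows.append(
            {
                "site_id": site.site_id,
                "gene_id": gene.gene_id if gene else None,
                "symbol": gene.symbol if gene else None,
                "biotype": gene.biotype if gene else None,
                "class_code": code,
                "conventionality": conventionality(code),
                # distal = terminal-exon/downstream derived view of the
                # conventional codes; an approximation of TTS-centred
                # annotation categories
                "distal": code in ("c", "o", "p"),
                "ars": ars,
                "n_signal_hits": len(hits),
                "best_signal": hits[0][0] if hits else None,
                "best_offset": hits[0][1] if hits else None,
                "signal_hits": ";".join(f"{s}@{o}" for s, o in hits),
            }
        )
    return pd.DataFrame(rows)


def summarize_by_biotype(annotated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-biotype summaries over gene-assigned sites (class codes other
    than u): sites per gene, class-code composition, ARS:NARS
    composition, and the conventional vs non-conventional split."""
    assigned = annotated[annotated["gene_id"].notna()].copy()

    per_gene = (
        assigned.groupby(["biotype", "gene_id"]).size().rename("n_sites").reset_index()
    )
    sites_per_gene = (
        per_gene.groupby("biotype")
        .agg(
            n_genes=("gene_id", "nunique"),
            mean_sites_per_gene=("n_sites", "mean"),
            frac_multi_site=("n_sites", lambda s: float((s > 1).mean())),
        )
        .reset_index()
    )

    class_codes = (
        assigned.groupby(["biotype", "class_code"])
        .size()
        .unstack(fill_value=0)
        .pipe(lambda df: df.div(df.sum(axis=1), axis=0))
        .reset_index()
    )

    ars = (
        assigned.groupby(["biotype", "ars"])
        .size()
        .unstack(fill_value=0)
        .rename(columns={True: "ARS", False: "NARS"})
        .pipe(lambda df: df.div(df.sum(axis=1), axis=0))
        .reset_index()
    )

    conv = (
        assigned[assigned["conventionality"].notna()]
        .groupby(["biotype", "conventionality"])
        .size()
        .unstack(fill_value=0)
        .pipe(lambda df: df.div(df.sum(axis=1), axis=0))
        .reset_index()
    )

    return {
        "sites_per_gene": sites_per_gene,
        "class_code_composition": class_codes,
        "ars_composition": ars,
        "conventionality": conv,
    }
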