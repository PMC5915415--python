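"""Synthetic WTTS-seq study generator.

Builds a toy genome with gene models and a known polyA-site architecture,
then emits strand-specific 3'-end reads for a two-condition (KO vs WT)
replicated design. Every read carries a leading poly(T) stretch — the
reverse-complemented poly(A) tail captured by the chemistry — followed by
the reverse complement of the genomic sequence upstream of the (jittered)
cleavage position. Truth tables and truth alignments (BED6) make every
downstream stage testable without an aligner.

The generator plants, per site: a polyA-signal hexamer 15-30 bp upstream
on the transcript strand, a fixed non-A terminus-adjacent base (so that
leading-T trimming cannot eat into genomic sequence at zero jitter), and
— for internal-priming artifact sites only — a 10-base adenine stretch
immediately downstream, the footprint oligo(dT) mis-priming leaves on the
genome.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import reverse_complement

from .models import GeneModel

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "miRNA", "small_RNA")


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    The replicate design (2 KO vs 2 WT), per-library depth of ~100 reads
    per site, NB dispersion 0.05 and a 15-30 bp signal offset window are
    the study conditions emulated; everything is reproducible from
    ``seed`` alone.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 60
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.60,
            "lncRNA": 0.15,
            "pseudogene": 0.10,
            "miRNA": 0.075,
            "small_RNA": 0.075,
        }
    )
    sites_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.35, 3: 0.25}
    )
    signal_alphabet: dict[str, float] = field(
        default_factory=lambda: {
            "AATAAA": 0.70,
            "ATTAAA": 0.15,
            "TATAAA": 0.075,
            "AAGAAA": 0.075,
        }
    )
    signal_offset_range: tuple[int, int] = (15, 30)
    ars_artifact_rate: float = 0.05
    jitter_sd: float = 2.0
    tail_p: float = 0.35
    read_length: int = 40
    n_replicates_per_condition: int = 2
    mean_depth_per_site: float = 100.0
    nb_dispersion: float = 0.05
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    exclusive_fraction: float = 0.5

    def validate(self) -> None:
        if abs(sum(self.biotype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_proportions must sum to 1")
        if unknown := set(self.biotype_proportions) - set(BIOTYPES):
            raise ValueError(f"unknown biotypes: {sorted(unknown)}")
        if abs(sum(self.sites_per_gene_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("sites_per_gene_distribution must sum to 1")
        if abs(sum(self.signal_alphabet.values()) - 1.0) > 1e-9:
            raise ValueError("signal_alphabet probabilities must sum to 1")
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_genes",
            "read_length",
            "n_replicates_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ars_artifact_rate", "de_fraction", "exclusive_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.tail_p <= 1.0:
            raise ValueError("tail_p must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        lo, hi = self.signal_offset_range
        if not (6 <= lo <= hi):
            raise ValueError("signal_offset_range must satisfy 6 <= lo <= hi")
        for hexamer in self.signal_alphabet:
            if len(hexamer) != 6 or set(hexamer.upper()) - set("ACGTU"):
                raise ValueError(f"bad signal hexamer {hexamer!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "signal_offset_range" in raw:
            raw["signal_offset_range"] = tuple(raw["signal_offset_range"])
        if "sites_per_gene_distribution" in raw:
            raw["sites_per_gene_distribution"] = {
                int(k): v for k, v in raw["sites_per_gene_distribution"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["signal_offset_range"] = list(self.signal_offset_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    """In-memory result of :func:`simulate_genome`."""

    config: SimConfig
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame  # one row per planted site

    @property
    def libraries(self) -> list[str]:
        n = self.config.n_replicates_per_condition
        return [f"KO_{i + 1}" for i in range(n)] + [f"WT_{i + 1}" for i in range(n)]

    def conditions(self) -> dict[str, str]:
        return {lib: lib.split("_")[0] for lib in self.libraries}


# ---------------------------------------------------------------------------
# genome + site architecture
# ---------------------------------------------------------------------------

_GENE_STRUCTURE = {
    # biotype -> (n_exons, exon length range, intron length range)
    "protein_coding": (3, (300, 600), (250, 600)),
    "lncRNA": (2, (200, 500), (200, 500)),
    "pseudogene": (1, (500, 900), None),
    "miRNA": (1, (80, 120), None),
    "small_RNA": (1, (80, 150), None),
}
_EDGE_MARGIN = 2_500  # room for downstream p-sites and upstream scan windows


def _draw_gene(
    rng: np.random.Generator, gene_id: str, biotype: str, chrom: str, start: int
) -> GeneModel:
    n_exons, exon_rng, intron_rng = _GENE_STRUCTURE[biotype]
    strand = rng.choice(["+", "-"])
    exons: list[tuple[int, int]] = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(intron_rng[0], intron_rng[1] + 1))
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        transcripts={f"{gene_id}.t1": exons},
    )


def _max_gene_length() -> int:
    return max(
        n * er[1] + (n - 1) * (ir[1] if ir else 0)
        for n, er, ir in _GENE_STRUCTURE.values()
    )


def _plant(seq: bytearray, pos: int, fragment: str) -> None:
    if pos < 0 or pos + len(fragment) > len(seq):
        return
    seq[pos : pos + len(fragment)] = fragment.encode()


def _site_positions_for_gene(gene: GeneModel) -> list[tuple[int, str]]:
    """Candidate (position, class_code) plants, distal first.

    Distal site sits inside the terminal exon 10 bp from the transcript
    3' end (class c); further sites go to the middle of the first intron
    (class i) where one exists, then 500 / 1000 bp downstream (class p).
    """
    exons = next(iter(gene.transcripts.values()))
    out: list[tuple[int, str]] = []
    if gene.strand == "+":
        terminal = exons[-1]
        out.append((terminal[1] - 10, "c"))
        if len(exons) > 1:
            i0, i1 = exons[0][1], exons[1][0]
            out.append(((i0 + i1) // 2, "i"))
        out.append((gene.end + 499, "p"))
        out.append((gene.end + 999, "p"))
    else:
        terminal = exons[0]
        out.append((terminal[0] + 9, "c"))
        if len(exons) > 1:
            i0, i1 = exons[0][1], exons[1][0]
            out.append(((i0 + i1) // 2, "i"))
        out.append((gene.start - 500, "p"))
        out.append((gene.start - 1000, "p"))
    return out


_ARS_RUN = 7
_ARS_WINDOW = 10
_ARS_WINDOW_COUNT = 8


def _is_a_rich(seq: str) -> bool:
    # mirror of annotation.classify_ars, kept local so the generator can
    # scrub accidental A-rich stretches downstream of genuine sites
    s = seq.upper()
    run = best = 0
    for ch in s:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    if best >= _ARS_RUN:
        return True
    w = min(_ARS_WINDOW, len(s))
    for i in range(len(s) - w + 1):
        if s[i : i + w].count("A") >= _ARS_WINDOW_COUNT:
            return True
    return False


def simulate_genome(config: SimConfig) -> SimulatedStudy:
    """Generate chromosome sequences, gene models and the site truth table.

    Raises ``ValueError`` when the chromosomes are too short to hold the
    requested number of genes with their flanking margins.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes_per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    slot = config.chrom_length // genes_per_chrom
    needed = _max_gene_length() + 2 * _EDGE_MARGIN
    if slot < needed:
        raise ValueError(
            f"chromosome too short for requested gene count: slot {slot} bp "
            f"< {needed} bp needed per gene (grow chrom_length or shrink n_genes)"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        c: bytearray(
            rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length)
            .tobytes()
        )
        for c in chrom_names
    }

    biotype_names = list(config.biotype_proportions)
    biotype_p = np.array([config.biotype_proportions[b] for b in biotype_names])
    site_ks = np.array(sorted(config.sites_per_gene_distribution))
    site_kp = np.array(
        [config.sites_per_gene_distribution[int(k)] for k in site_ks], dtype=float
    )
    signal_names = [s.upper().replace("U", "T") for s in config.signal_alphabet]
    signal_p = np.array(list(config.signal_alphabet.values()))

    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chromosomes]
        slot_idx = g // config.n_chromosomes
        biotype = str(rng.choice(biotype_names, p=biotype_p))
        glen_max = _max_gene_length()
        lo = slot_idx * slot + _EDGE_MARGIN
        room = max(slot - glen_max - 2 * _EDGE_MARGIN, 1)
        start = lo + int(rng.integers(0, room))
        genes.append(_draw_gene(rng, f"G{g + 1:04d}", biotype, chrom, start))

    # guarantee at least one antisense-overlapping gene pair: re-strand the
    # second gene and shift it so its span overlaps the first gene's tail
    if config.n_genes >= 2:
        a, b = genes[0], genes[1]
        shift = (a.end - 200) - b.start
        b.strand = "+" if a.strand == "-" else "-"
        b.chrom = a.chrom
        b.transcripts = {
            t: [(s + shift, e + shift) for s, e in ex]
            for t, ex in b.transcripts.items()
        }

    truth_rows: list[dict] = []

    def plant_site(
        gene: GeneModel,
        pos: int,
        strand: str,
        class_code: str,
        *,
        artifact: bool = False,
        with_signal: bool = True,
    ) -> None:
        chrom = gene.chrom
        seq = seqs[chrom]
        if strand == "+":
            _plant(seq, pos, "C")
        else:
            _plant(seq, pos, "G")
        signal, offset = None, None
        if with_signal:
            signal = str(rng.choice(signal_names, p=signal_p))
            offset = int(
                rng.integers(
                    config.signal_offset_range[0], config.signal_offset_range[1] + 1
                )
            )
            if strand == "+":
                _plant(seq, pos - offset - 5, signal)
            else:
                _plant(seq, pos + offset, reverse_complement(signal))
        if artifact:
            if strand == "+":
                _plant(seq, pos + 1, "A" * 10)
            else:
                _plant(seq, pos - 10, "T" * 10)
        truth_rows.append(
            {
                "site_id": f"S{len(truth_rows) + 1:05d}",
                "gene_id": gene.gene_id,
                "chrom": chrom,
                "position": pos,
                "strand": strand,
                "class_code": class_code,
                "is_artifact": artifact,
                "ars": artifact,
                "signal": signal,
                "signal_offset": offset,
            }
        )

    for gene in genes:
        k = int(rng.choice(site_ks, p=site_kp))
        candidates = _site_positions_for_gene(gene)
        k = min(k, len(candidates))
        for pos, code in candidates[:k]:
            plant_site(gene, pos, gene.strand, code)

    # one antisense-exonic (class x) site: opposite strand inside a wide
    # exon of a gene that overlaps nothing on that strand
    if config.n_genes >= 3:
        host = next(
            (
                g
                for g in genes[2:]
                if next(iter(g.transcripts.values()))[0][1]
                - next(iter(g.transcripts.values()))[0][0]
                >= 300
            ),
            None,
        )
        if host is not None:
            exon = next(iter(host.transcripts.values()))[0]
            xpos = (exon[0] + exon[1]) // 2
            xstrand = "+" if host.strand == "-" else "-"
            plant_site(host, xpos, xstrand, "x")

    n_true = len(truth_rows)
    if config.ars_artifact_rate > 0:
        n_art = max(1, round(config.ars_artifact_rate * n_true))
        # drop artifacts into gene bodies, 150 bp from the distal site so
        # clusters stay separable; skip genes too short to hold them
        planted_art = 0
        for gene in genes[3:] + genes[:3]:
            if planted_art >= n_art:
                break
            exons = next(iter(gene.transcripts.values()))
            if gene.strand == "+":
                pos = exons[-1][1] - 10 - 150
            else:
                pos = exons[0][0] + 9 + 150
            if not (gene.start <= pos < gene.end):
                continue
            if any(x0 <= pos < x1 for x0, x1 in exons):
                code = "c"
            else:
                code = "i"
            plant_site(gene, pos, gene.strand, code, artifact=True, with_signal=False)
            planted_art += 1

    truth = pd.DataFrame(truth_rows)

    # scrub accidental A-rich stretches downstream of genuine sites so the
    # planted truth ARS labels are exact
    for row in truth.itertuples():
        if row.is_artifact:
            continue
        seq = seqs[row.chrom]
        for _ in range(40):
            if row.strand == "+":
                window = seq[row.position + 1 : row.position + 31].decode()
            else:
                window = reverse_complement(
                    seq[max(row.position - 30, 0) : row.position].decode()
                )
            if not _is_a_rich(window):
                break
            idx = window.upper().index("A" * 2) if "AA" in window.upper() else window.upper().index("A")
            repl = "C" if row.strand == "+" else "G"
            if row.strand == "+":
                seq[row.position + 1 + idx] = ord(repl)
            else:
                seq[row.position - 1 - idx] = ord(repl)

    # assign differential truth over non-artifact sites
    truth["category"] = "ns"
    truth["log2fc"] = 0.0
    eligible = truth.index[~truth.is_artifact].to_numpy()
    n_de = round(config.de_fraction * len(eligible))
    de_idx = rng.permutation(eligible)[:n_de]
    n_excl = round(config.exclusive_fraction * n_de)
    gained = de_idx[: n_excl // 2]
    lost = de_idx[n_excl // 2 : n_excl]
    rest = de_idx[n_excl:]
    up = rest[: len(rest) // 2 + len(rest) % 2]
    down = rest[len(rest) // 2 + len(rest) % 2 :]
    truth.loc[gained, "category"] = "gained"
    truth.loc[lost, "category"] = "lost"
    truth.loc[up, ["category", "log2fc"]] = ["up", config.de_log2fc]
    truth.loc[down, ["category", "log2fc"]] = ["down", -config.de_log2fc]

    # expected per-library depth by condition
    m = config.mean_depth_per_site
    half = 2.0 ** (config.de_log2fc / 2.0)
    mean_ko = np.full(len(truth), m)
    mean_wt = np.full(len(truth), m)
    cat = truth.category.to_numpy()
    mean_ko[cat == "up"] = m * half
    mean_wt[cat == "up"] = m / half
    mean_ko[cat == "down"] = m / half
    mean_wt[cat == "down"] = m * half
    mean_wt[cat == "gained"] = 0.0
    mean_ko[cat == "lost"] = 0.0
    if config.ars_artifact_rate > 0:
        art = truth.is_artifact.to_numpy()
        total_true = m * (~art).sum()
        rate = config.ars_artifact_rate
        per_art = rate / (1.0 - rate) * total_true / max(art.sum(), 1)
        mean_ko[art] = per_art
        mean_wt[art] = per_art
    truth["mean_ko"] = mean_ko
    truth["mean_wt"] = mean_wt

    chromosomes = {c: bytes(s).decode() for c, s in seqs.items()}
    return SimulatedStudy(config=config, chromosomes=chromosomes, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    """Per-library reads plus truth alignments."""

    #: library -> list of (read_id, sequence, quality string)
    reads: dict[str, list[tuple[str, str, str]]]
    #: BED6 truth alignments: chrom, start, end, read_id, score, strand
    truth_bed: pd.DataFrame
    #: per-site per-library counts actually drawn
    counts: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def simulate_reads(config: SimConfig, study: SimulatedStudy) -> SimulatedReads:
    """Emit FASTQ-ready reads and truth alignments for every library.

    Read = poly(T) prefix (geometric length >= 1) + reverse complement of
    the transcript-strand genomic sequence ending at the jittered cleavage
    position. The truth BED records each read's genomic alignment span on
    the *alignment* strand (antisense to the transcript).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    L = config.read_length
    reads: dict[str, list[tuple[str, str, str]]] = {}
    bed_rows: list[tuple] = []
    count_rows: dict[str, dict[str, int]] = {}

    for lib in study.libraries:
        condition = lib.split("_")[0]
        lib_reads: list[tuple[str, str, str]] = []
        for row in study.truth.itertuples():
            mean = row.mean_ko if condition == "KO" else row.mean_wt
            n_reads = _nb_draw(rng, mean, config.nb_dispersion)
            count_rows.setdefault(row.site_id, {})[lib] = n_reads
            if n_reads == 0:
                continue
            chrom_seq = study.chromosomes[row.chrom]
            clen = len(chrom_seq)
            if config.jitter_sd > 0:
                jitter = np.rint(
                    rng.normal(0.0, config.jitter_sd, size=n_reads)
                ).astype(int)
            else:
                jitter = np.zeros(n_reads, dtype=int)
            tails = rng.geometric(config.tail_p, size=n_reads)
            for i in range(n_reads):
                pos = int(np.clip(row.position + jitter[i], L, clen - L - 1))
                if row.strand == "+":
                    genomic = chrom_seq[pos - L + 1 : pos + 1]
                    insert = reverse_complement(genomic)
                    aln = (row.chrom, pos - L + 1, pos + 1, "-")
                else:
                    insert = chrom_seq[pos : pos + L]
                    aln = (row.chrom, pos, pos + L, "+")
                seq = "T" * int(tails[i]) + insert
                q = rng.integers(25, 39, size=len(seq))
                read_id = f"{lib}:{row.site_id}:{i}"
                lib_reads.append((read_id, seq, "".join(chr(x + 33) for x in q)))
                bed_rows.append((aln[0], aln[1], aln[2], read_id, 60, aln[3], lib))
        reads[lib] = lib_reads

    truth_bed = pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "name", "score", "strand", "library"]
    )
    counts = (
        pd.DataFrame.from_dict(count_rows, orient="index")
        .reindex(study.truth.site_id)
        .fillna(0)
        .astype(int)
    )
    counts.index.name = "site_id"
    return SimulatedReads(reads=reads, truth_bed=truth_bed, counts=counts)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_genome_fasta(study: SimulatedStudy, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in study.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tapsflow-sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID=gene:{g.gene_id};Name={g.symbol};"
                f"gene_biotype={g.biotype}\n"
            )
            for tid, exons in g.transcripts.items():
                t0 = min(e[0] for e in exons)
                t1 = max(e[1] for e in exons)
                fh.write(
                    f"{g.chrom}\tapsflow-sim\ttranscript\t{t0 + 1}\t{t1}\t.\t"
                    f"{g.strand}\t.\tID=transcript:{tid};Parent=gene:{g.gene_id}\n"
                )
                for j, (s, e) in enumerate(exons):
                    fh.write(
                        f"{g.chrom}\tapsflow-sim\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID=exon:{tid}.{j + 1};Parent=transcript:{tid}\n"
                    )


def write_truth_table(study: SimulatedStudy, path: str | Path) -> None:
    study.truth.to_csv(path, sep="\t", index=False)


def write_fastq(reads: SimulatedReads, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib, records in reads.reads.items():
        p = outdir / f"{lib}.fastq"
        with open(p, "w") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        paths[lib] = p
    return paths


def write_truth_bed(reads: SimulatedReads, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib, sub in reads.truth_bed.groupby("library", sort=False):
        p = outdir / f"{lib}.bed"
        sub[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            p, sep="\t", header=False, index=False
        )
        paths[lib] = p
    return paths
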