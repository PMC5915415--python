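"""End-to-end orchestration: qc -> trim -> ingest -> call -> annotate ->
differential test -> genomic statistics, with a read-accounting ledger,
plus the one-command synthetic demo."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import differential as de
from . import genome_stats as gs
from . import read_processing as rp
from . import simulate as sim
from . import site_calling as sc

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Frozen set of inputs and thresholds for one pipeline run.

    The sample sheet is a CSV with columns library, condition (KO/WT),
    fastq, alignments (SAM/BAM or BED6 of the trimmed reads).
    """

    genome_fasta: str
    gff3: str
    sample_sheet: str
    signal_list: str | None = None
    output_dir: str = "apsflow_out"
    mode: str = "APS"
    read_orientation: str = "antisense"
    qual_threshold: int = rp.DEFAULT_Q_THRESHOLD
    max_low_fraction: float = rp.DEFAULT_MAX_LOW_FRACTION
    min_length: int = rp.DEFAULT_MIN_LENGTH
    min_mapq: int = 0
    window: int = sc.DEFAULT_WINDOW
    min_reads: int = sc.DEFAULT_MIN_READS
    downstream_len: int = ann.DEFAULT_DOWNSTREAM_LEN
    upstream_len: int = ann.DEFAULT_UPSTREAM_LEN
    min_penetration: int = ann.DEFAULT_MIN_INTRON_PENETRATION
    max_downstream: int = ann.DEFAULT_MAX_DOWNSTREAM_DISTANCE
    alpha: float = de.DEFAULT_ALPHA
    cluster_window: int = gs.DEFAULT_CLUSTER_WINDOW
    cluster_min_sites: int = gs.DEFAULT_CLUSTER_MIN_SITES
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome_fasta", "gff3", "sample_sheet"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} not found: {path}")
        if self.signal_list is not None and not Path(self.signal_list).exists():
            raise FileNotFoundError(f"signal_list not found: {self.signal_list}")
        if self.mode.upper() not in ("APS", "ASS"):
            raise ValueError(f"mode must be APS or ASS, got {self.mode!r}")
        sheet = pd.read_csv(self.sample_sheet)
        required = {"library", "condition", "fastq", "alignments"}
        if missing := required - set(sheet.columns):
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        for col in ("fastq", "alignments"):
            for p in sheet[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{col} not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    annotations: pd.DataFrame
    de_results: pd.DataFrame
    regions: list[gs.ClusterRegion]
    contingency: dict[str, dict]
    ledger: pd.DataFrame
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # halt with stage name and cause
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in order and write the result bundle to
    ``config.output_dir``. Re-running with an identical config and inputs
    reproduces identical outputs."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    sheet = pd.read_csv(config.sample_sheet, dtype=str)
    conditions = dict(zip(sheet["library"], sheet["condition"]))
    genome = ann.load_genome_fasta(config.genome_fasta)
    ref_lengths = {c: len(s) for c, s in genome.items()}

    ledger_rows = []
    termini_frames = []
    for row in sheet.itertuples():
        reads, stats = _stage("qc+trim")(rp.process_fastq)(
            row.fastq,
            out_path=outdir / f"{row.library}.trimmed.fastq",
            q_threshold=config.qual_threshold,
            max_low_fraction=config.max_low_fraction,
            min_length=config.min_length,
            library=row.library,
        )
        termini = _stage("ingest")(rp.ingest_alignments)(
            row.alignments,
            reads,
            library=row.library,
            orientation=config.read_orientation,
            min_mapq=config.min_mapq,
            reference_lengths=ref_lengths,
            stats=stats,
        )
        stats.assert_conserved()
        ledger_rows.append(dataclasses.asdict(stats))
        termini_frames.append(termini)
        log.info(
            "%s: %d raw -> %d QC-passed -> %d length-passed -> %d mapped",
            row.library,
            stats.n_raw,
            stats.n_raw - stats.n_dropped_quality,
            stats.n_raw - stats.n_dropped_quality - stats.n_dropped_short,
            stats.n_termini,
        )
    ledger = pd.DataFrame(ledger_rows)

    all_termini = pd.concat(termini_frames, ignore_index=True)
    sites = _stage("call")(sc.call_sites)(
        all_termini,
        mode=config.mode,
        window=config.window,
        min_reads=config.min_reads,
    )

    genes = _stage("annotate")(ann.load_gene_models)(config.gff3)
    signals = (
        ann.load_signal_list(config.signal_list)
        if config.signal_list
        else list(ann.DEFAULT_SIGNALS)
    )
    annotations = _stage("annotate")(ann.annotate_sites)(
        sites,
        genes,
        genome,
        signals,
        downstream_len=config.downstream_len,
        upstream_len=config.upstream_len,
        min_penetration=config.min_penetration,
        max_downstream=config.max_downstream,
    )
    summaries = ann.summarize_by_biotype(annotations)

    count_cols = [c for c in sites.columns if c.startswith("count_")]
    counts = sites.set_index("site_id")[count_cols]
    counts.columns = [c.removeprefix("count_") for c in count_cols]
    de_results = _stage("de")(de.test_de)(counts, conditions, alpha=config.alpha)
    de_results.index.name = "site_id"

    de_sites = de_results[de_results["category"] != "ns"]
    positions = sites.set_index("site_id").loc[de_sites.index, ["chrom", "position"]]
    regions = _stage("stats")(gs.find_de_clusters)(
        positions.reset_index(),
        window=config.cluster_window,
        min_sites=config.cluster_min_sites,
    )
    contingency: dict[str, dict] = {}
    for axis in ("class_code", "ars", "conventionality", "distal"):
        try:
            table, stat, df, p = gs.direction_by_category(
                de_results.reset_index(), annotations, axis
            )
            contingency[axis] = {"table": table, "statistic": stat, "df": df, "p": p}
        except ValueError as exc:
            log.info("contingency axis %s skipped: %s", axis, exc)

    # write bundle
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    sc.sites_to_bed(sites).to_csv(outdir / "sites.bed", sep="\t", header=False, index=False)
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    de_results.to_csv(outdir / "de_results.tsv", sep="\t")
    gs.regions_to_bed(regions).to_csv(
        outdir / "de_regions.bed", sep="\t", header=False, index=False
    )
    ledger.to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    with open(outdir / "contingency.txt", "w") as fh:
        for axis, res in contingency.items():
            fh.write(f"# direction vs {axis}\n{res['table']}\n")
            fh.write(
                f"chi-square = {res['statistic']:.3f}, df = {res['df']}, "
                f"p = {res['p']:.4g}\n\n"
            )
    for name, frame in summaries.items():
        frame.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)

    return PipelineResult(
        sites=sites,
        annotations=annotations,
        de_results=de_results,
        regions=regions,
        contingency=contingency,
        ledger=ledger,
        summaries=summaries,
    )


def model_comparison_report(
    comparisons: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
) -> pd.DataFrame:
    """Cross-model summary of genes with differential sites in more than
    one comparison.

    ``comparisons`` maps a model label to (de_results, annotations).
    Returns one row per (gene, comparison, site): gene_id, comparison,
    site_id, category, class_code, n_de_sites_in_gene — empty when no
    gene is shared.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least two comparisons")
    frames = []
    for label, (de_results, annotations) in comparisons.items():
        d = de_results.reset_index()
        if "site_id" not in d.columns:
            d = d.rename(columns={d.columns[0]: "site_id"})
        d = d[d["category"] != "ns"]
        joined = d.merge(
            annotations[["site_id", "gene_id", "class_code"]], on="site_id"
        )
        joined = joined[joined["gene_id"].notna()]
        joined["comparison"] = label
        frames.append(joined[["gene_id", "comparison", "site_id", "category", "class_code"]])
    allde = pd.concat(frames, ignore_index=True)
    per_gene = allde.groupby("gene_id")["comparison"].nunique()
    shared = per_gene.index[per_gene >= 2]
    report = allde[allde["gene_id"].isin(shared)].copy()
    # per-model entries count separately: the same catalogue site
    # differential in two comparisons is two events
    counts = allde.groupby("gene_id").size()
    report["n_de_sites_in_gene"] = report["gene_id"].map(counts)
    return report.sort_values(["gene_id", "comparison", "site_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic demo
# ---------------------------------------------------------------------------


def demo(
    seed: int = 0,
    outdir: str | Path = "apsflow_demo",
    **sim_overrides,
) -> tuple[sim.SimulatedStudy, sim.SimulatedReads, PipelineResult]:
    """Simulate a study and push it through the full pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = sim.SimConfig(seed=seed, **sim_overrides)
    config.validate()
    study = sim.simulate_genome(config)
    reads = sim.simulate_reads(config, study)

    genome_fa = outdir / "genome.fa"
    gff3 = outdir / "genes.gff3"
    sim.write_genome_fasta(study, genome_fa)
    sim.write_gff3(study.genes, gff3)
    sim.write_truth_table(study, outdir / "truth_sites.tsv")
    fq = sim.write_fastq(reads, outdir / "reads")
    bed = sim.write_truth_bed(reads, outdir / "alignments")
    sheet = pd.DataFrame(
        {
            "library": study.libraries,
            "condition": [lib.split("_")[0] for lib in study.libraries],
            "fastq": [str(fq[lib]) for lib in study.libraries],
            "alignments": [str(bed[lib]) for lib in study.libraries],
        }
    )
    sheet_path = outdir / "sample_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    config.to_yaml(outdir / "sim_config.yaml")

    run_config = RunConfig(
        genome_fasta=str(genome_fa),
        gff3=str(gff3),
        sample_sheet=str(sheet_path),
        output_dir=str(outdir / "results"),
        seed=seed,
    )
    run_config.to_yaml(outdir / "run_config.yaml")
    result = run_pipeline(run_config)
    return study, reads, result
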