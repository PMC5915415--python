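"""Cluster read termini into polyadenylation (APS) or start (ASS) sites.

Clustering is single-linkage chaining per (chromosome, strand): sorted
terminus positions are split wherever the gap to the previous position
exceeds the window (24 nt by default). A cluster's representative
position is its highest-count member position, ties broken toward the
3'-most position with respect to the strand. Sites are then filtered on
the total read count across the libraries of the analysis set (16 by
default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 24
DEFAULT_MIN_READS = 16


def cluster_termini(
    termini: pd.DataFrame, window: int = DEFAULT_WINDOW, prefix: str = "APS"
) -> pd.DataFrame:
    """Cluster a terminus table (chrom, position, strand, library) into
    sites, before any count filtering.

    Returns one row per site: site_id, chrom, strand, position
    (representative), span_start, span_end (inclusive member extremes),
    total_count and one ``count_<library>`` column per library. The sum
    of all counts equals the number of input termini.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    libraries = sorted(termini["library"].unique()) if len(termini) else []
    records: list[dict] = []
    if len(termini):
        for (chrom, strand), sub in termini.groupby(["chrom", "strand"], sort=True):
            pos = np.sort(sub["position"].to_numpy())
            breaks = np.flatnonzero(np.diff(pos) > window) + 1
            bounds = np.concatenate(([0], breaks, [len(pos)]))
            per_pos = sub.groupby(["position", "library"]).size()
            pos_totals = per_pos.groupby("position").sum()
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                members = np.unique(pos[lo:hi])
                totals = pos_totals.loc[members]
                top = totals[totals == totals.max()].index.to_numpy()
                rep = int(top.max() if strand == "+" else top.min())
                rec = {
                    "chrom": chrom,
                    "strand": strand,
                    "position": rep,
                    "span_start": int(members.min()),
                    "span_end": int(members.max()),
                    "total_count": int(totals.sum()),
                }
                for lib in libraries:
                    n = 0
                    for m in members:
                        n += int(per_pos.get((m, lib), 0))
                    rec[f"count_{lib}"] = n
                records.append(rec)
    sites = pd.DataFrame(
        records,
        columns=["chrom", "strand", "position", "span_start", "span_end", "total_count"]
        + [f"count_{lib}" for lib in libraries],
    )
    sites = sites.sort_values(["chrom", "position", "strand"], kind="mergesort")
    sites.insert(
        0, "site_id", [f"{prefix}_{i + 1:05d}" for i in range(len(sites))]
    )
    return sites.reset_index(drop=True)


def filter_sites(
    sites: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    libraries: list[str] | None = None,
) -> pd.DataFrame:
    """Retain sites with at least ``min_reads`` total reads.

    When ``libraries`` is given, the cutoff is applied to the count
    summed over that analysis subset only (e.g. the four libraries of
    one KO-vs-WT pair), so per-comparison site sets can be smaller than
    the all-library catalogue.
    """
    if libraries is None:
        total = sites["total_count"]
    else:
        cols = [f"count_{lib}" for lib in libraries]
        if missing := [c for c in cols if c not in sites.columns]:
            raise KeyError(f"unknown libraries: {missing}")
        total = sites[cols].sum(axis=1)
    kept = sites.loc[total >= min_reads].reset_index(drop=True)
    if len(kept) == 0 and len(sites) > 0:
        log.warning("all %d sites fell below the %d-read cutoff", len(sites), min_reads)
    return kept


def call_sites(
    termini: pd.DataFrame,
    mode: str = "APS",
    window: int = DEFAULT_WINDOW,
    min_reads: int = DEFAULT_MIN_READS,
    libraries: list[str] | None = None,
) -> pd.DataFrame:
    """Cluster then filter. ``mode`` ('APS' for 3' termini, 'ASS' for 5'
    start sites) only changes the site-id labelling; the machinery is
    identical."""
    mode = mode.upper()
    if mode not in ("APS", "ASS"):
        raise ValueError(f"mode must be APS or ASS, got {mode!r}")
    clustered = cluster_termini(termini, window=window, prefix=mode)
    return filter_sites(clustered, min_reads=min_reads, libraries=libraries)


def sites_to_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view: representative position as the feature, span and
    per-library counts as extra columns."""
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["position"],
            "end": sites["position"] + 1,
            "name": sites["site_id"],
            "score": sites["total_count"],
            "strand": sites["strand"],
            "span_start": sites["span_start"],
            "span_end": sites["span_end"],
        }
    )
    for col in sites.columns:
        if col.startswith("count_"):
            bed[col] = sites[col]
    return bed
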