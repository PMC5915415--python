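"""Post-differential genomic statistics.

Covers the clustering of differential sites into 5-Mb genomic regions
(at least 3 differential sites per region), Pearson chi-square tests of
independence between differential direction and site annotation axes
(class code, ARS status, conventionality, distal), and the direction-
group contingency builder that merges gained with up and lost with down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

DEFAULT_CLUSTER_WINDOW = 5_000_000
DEFAULT_CLUSTER_MIN_SITES = 3


@dataclass(frozen=True)
class ClusterRegion:
    """A genomic region enriched for differential sites."""

    chrom: str
    start: int
    end: int
    site_ids: tuple[str, ...]
    comparison: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


def find_de_clusters(
    de_sites: pd.DataFrame,
    window: int = DEFAULT_CLUSTER_WINDOW,
    min_sites: int = DEFAULT_CLUSTER_MIN_SITES,
    comparison: str = "",
) -> list[ClusterRegion]:
    """Greedy left-to-right regions of differential sites.

    Per chromosome, a region grows from the left-most unassigned site
    while its total span stays within ``window`` bp; it is emitted when
    it holds at least ``min_sites`` members, and scanning resumes at the
    next unassigned site either way. ``de_sites`` needs columns
    site_id, chrom, position.
    """
    regions: list[ClusterRegion] = []
    for chrom, sub in de_sites.groupby("chrom", sort=True):
        sub = sub.sort_values("position", kind="mergesort")
        pos = sub["position"].to_numpy()
        ids = sub["site_id"].to_numpy()
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[i] <= window:
                j += 1
            if j - i + 1 >= min_sites:
                regions.append(
                    ClusterRegion(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j]) + 1,
                        site_ids=tuple(ids[i : j + 1]),
                        comparison=comparison,
                    )
                )
            i = j + 1
    return regions


def regions_to_bed(regions: list[ClusterRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [
                f"{r.comparison + ':' if r.comparison else ''}{r.n_sites}_sites"
                for r in regions
            ],
            "score": [r.n_sites for r in regions],
            "strand": ["." for r in regions],
        }
    )


def chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    2x2 tables get the Yates continuity correction; larger tables do not
    (the convention of the statistical environment this workflow
    mirrors). Returns (statistic, df, p). Raises on zero margins.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("table cells must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for axis_name, sums, labels in (
        ("row", row_sums, getattr(table, "index", None)),
        ("column", col_sums, getattr(table, "columns", None)),
    ):
        if (sums == 0).any():
            idx = int(np.flatnonzero(sums == 0)[0])
            name = labels[idx] if labels is not None else idx
            raise ValueError(f"degenerate {axis_name} {name!r} has zero margin")
    expected = np.outer(row_sums, col_sums) / obs.sum()
    diff = np.abs(obs - expected)
    if obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


_DIRECTION_GROUPS = {
    "gained": "gained_up",
    "up": "gained_up",
    "lost": "lost_down",
    "down": "lost_down",
}

_AXES = ("class_code", "ars", "conventionality", "distal")


def direction_by_category(
    de_results: pd.DataFrame,
    annotations: pd.DataFrame,
    axis: str = "class_code",
) -> tuple[pd.DataFrame, float, int, float]:
    """Contingency table of differential direction groups (gained+up vs
    lost+down) against an annotation axis, with its chi-square test.

    ``de_results`` must carry site ids (index or 'site_id' column) and a
    'category' column; ``axis`` is one of class_code, ars,
    conventionality, distal. Categories absent from both direction
    groups are dropped before testing.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    de = de_results.reset_index() if "site_id" not in de_results.columns else de_results
    if "site_id" not in de.columns:
        de = de.rename(columns={de.columns[0]: "site_id"})
    joined = de.merge(annotations, on="site_id", how="inner")
    joined = joined[joined["category"].isin(_DIRECTION_GROUPS)]
    joined["direction"] = joined["category"].map(_DIRECTION_GROUPS)
    col = joined[axis]
    if axis == "ars":
        col = col.map({True: "ARS", False: "NARS"})
    elif axis == "distal":
        col = col.map({True: "distal", False: "proximal"})
    table = (
        pd.crosstab(joined["direction"], col)
        .reindex(index=["gained_up", "lost_down"], fill_value=0)
    )
    empty = table.columns[(table.sum(axis=0) == 0)]
    if len(empty):
        log.info("dropping empty categories %s before testing", list(empty))
        table = table.drop(columns=empty)
    stat, df, p = chi_square(table)
    return table, stat, df, p
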