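"""Normalization and KO-vs-WT differential testing of site (or gene)
counts.

The procedure follows the standard negative-binomial count workflow:
median-of-ratios size factors, per-feature method-of-moments dispersion
shrunk toward a fitted mean-dispersion trend, and a Wald test on the
KO-minus-WT log2 fold change with Benjamini-Hochberg adjustment. It is a
documented re-implementation of that workflow, not a wrapper; exact
numerical agreement with any particular external package is a non-goal.

Significant features (adjusted p below ``alpha``, default 0.1) are
categorized as:

``gained``  expressed in KO only (all WT raw counts zero)
``lost``    expressed in WT only (all KO raw counts zero)
``up``      higher in KO
``down``    lower in KO
``ns``      not significant
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
DEFAULT_MIN_DISPERSION = 1e-4
MAX_DISPERSION = 10.0
#: prior degrees of freedom pulling per-feature dispersions toward the
#: mean-dispersion trend; low-replicate designs need strong shrinkage
DISPERSION_PRIOR_DF = 6.0


def _check_matrix(counts: pd.DataFrame, conditions: pd.Series) -> pd.Series:
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    conditions = conditions.reindex(counts.columns)
    if conditions.isna().any():
        missing = list(conditions.index[conditions.isna()])
        raise KeyError(f"no condition label for libraries {missing}")
    if unknown := set(conditions) - {"KO", "WT"}:
        raise ValueError(f"condition labels must be KO/WT, got {sorted(unknown)}")
    for cond in ("KO", "WT"):
        if (conditions == cond).sum() < 1:
            raise ValueError(f"need at least one {cond} library")
    return conditions


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library scaling factors.

    For each feature present in every library, the ratio of each
    library's count to the feature's geometric mean is taken; a
    library's factor is the median ratio. When no feature is positive
    everywhere, the reference falls back to geometric means over the
    libraries where the feature is observed, computed on features seen
    in at least half the libraries.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.isfinite(logs).all(axis=1)
    if all_positive.any():
        ref = logs[all_positive].mean(axis=1, keepdims=True)
        ratios = logs[all_positive] - ref
    else:
        obs = np.isfinite(logs)
        rows = obs.sum(axis=1) >= mat.shape[1] / 2
        if not rows.any():
            raise ValueError("no feature observed in at least half the libraries")
        log.warning(
            "no feature positive in all libraries; size factors fall back to "
            "%d features observed in >= half of them",
            int(rows.sum()),
        )
        sub = np.where(obs[rows], logs[rows], np.nan)
        ref = np.nanmean(sub, axis=1, keepdims=True)
        ratios = sub - ref
    factors = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; monotone, >= raw p, capped at 1. NaNs are
    passed through and excluded from the count of tests."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def _dispersion_estimates(
    norm: np.ndarray,
    cond_idx: list[np.ndarray],
    inv_sf_mean: float,
    min_dispersion: float,
) -> np.ndarray:
    """Trend-shrunken per-feature NB dispersions.

    Method-of-moments within-condition estimates are regressed on a
    ``a0 + a1/mean`` trend and shrunk toward it on the log scale with
    weight ``df / (df + prior_df)``.
    """
    mu = norm.mean(axis=1)
    n = norm.shape[1]
    k = len(cond_idx)
    wss = np.zeros(norm.shape[0])
    for idx in cond_idx:
        sub = norm[:, idx]
        wss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = max(n - k, 1)
    wvar = wss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (wvar - mu * inv_sf_mean) / mu**2
    mom = np.where(np.isfinite(mom), mom, 0.0)

    usable = (mom > 0) & (mu > 0)
    if usable.sum() >= 10:
        x = 1.0 / mu[usable]
        y = mom[usable]
        # one robustness pass: trim gross outliers after an initial fit
        A = np.column_stack([np.ones(x.size), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ coef
        keep = y <= np.maximum(10 * fitted, 1e-8)
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = max(float(np.median(y)), min_dispersion)
    else:
        a0, a1 = max(float(np.median(mom[usable])) if usable.any() else min_dispersion, min_dispersion), 0.0

    with np.errstate(divide="ignore"):
        trend = np.clip(a0 + a1 / np.maximum(mu, 1e-8), min_dispersion, MAX_DISPERSION)
    w = df / (df + DISPERSION_PRIOR_DF)
    log_mom = np.log(np.clip(mom, min_dispersion, MAX_DISPERSION))
    alpha = np.exp(w * log_mom + (1 - w) * np.log(trend))
    alpha = np.where(mom > 0, alpha, trend)
    return np.clip(alpha, min_dispersion, MAX_DISPERSION)


def test_de(
    counts: pd.DataFrame,
    conditions: pd.Series | dict[str, str],
    factors: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_dispersion: float = DEFAULT_MIN_DISPERSION,
) -> pd.DataFrame:
    """Wald test of the KO-vs-WT log2 fold change for every feature.

    Returns a DataFrame indexed like ``counts`` (all-zero features are
    excluded) with columns base_mean, log2fc (KO minus WT), lfc_se,
    p_value, p_adj and category.
    """
    if isinstance(conditions, dict):
        conditions = pd.Series(conditions)
    conditions = _check_matrix(counts, conditions)
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("excluding %d all-zero features", int((~nonzero).sum()))
    counts = counts.loc[nonzero]
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    sf = factors.to_numpy(dtype=float)
    if (sf <= 0).any() or np.isnan(sf).any():
        raise ValueError("size factors must be positive")

    raw = counts.to_numpy(dtype=float)
    norm = raw / sf
    labels = conditions.to_numpy()
    ko = np.flatnonzero(labels == "KO")
    wt = np.flatnonzero(labels == "WT")
    inv_sf_mean = float((1.0 / sf).mean())
    disp = _dispersion_estimates(norm, [ko, wt], inv_sf_mean, min_dispersion)

    # half-a-read floor (on the normalized scale) keeps the Wald statistic
    # finite for features observed in one condition only
    q_floor = 0.5 * inv_sf_mean
    q_ko = np.maximum(norm[:, ko].mean(axis=1), q_floor)
    q_wt = np.maximum(norm[:, wt].mean(axis=1), q_floor)

    def var_log_q(q: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv = 1.0 / sf[idx]
        return (inv.sum() / q + disp * idx.size) / idx.size**2

    se2 = var_log_q(q_ko, ko) + var_log_q(q_wt, wt)
    lfc = np.log2(q_ko) - np.log2(q_wt)
    z = (np.log(q_ko) - np.log(q_wt)) / np.sqrt(se2)
    pval = 2.0 * sps.norm.sf(np.abs(z))
    padj = benjamini_hochberg(pval)

    result = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "lfc_se": np.sqrt(se2) / np.log(2.0),
            "p_value": pval,
            "p_adj": padj,
        },
        index=counts.index,
    )
    result["category"] = [
        categorize(
            result["p_adj"].iat[i],
            result["log2fc"].iat[i],
            raw[i, ko],
            raw[i, wt],
            alpha,
        )
        for i in range(len(result))
    ]
    return result


def categorize(
    padj: float,
    log2fc: float,
    ko_counts: np.ndarray,
    wt_counts: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Assign the four-way differential category for one feature.

    gained/lost require every raw replicate count of one condition to be
    zero (with at least one read in the other); up/down follow the sign
    of the fold change. Non-significant features are ``ns``.
    """
    if not np.isfinite(padj) or padj >= alpha:
        return "ns"
    ko_counts = np.asarray(ko_counts)
    wt_counts = np.asarray(wt_counts)
    if (wt_counts == 0).all() and (ko_counts > 0).any():
        return "gained"
    if (ko_counts == 0).all() and (wt_counts > 0).any():
        return "lost"
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    warnings.warn("significant feature with zero fold change; kept as ns", stacklevel=2)
    return "ns"


def gene_level_counts(
    sites: pd.DataFrame,
    annotations: pd.DataFrame,
    min_reads: int = 16,
    include_codes: frozenset[str] | set[str] = frozenset("ceiop"),
) -> pd.DataFrame:
    """Aggregate per-site counts to genes.

    Only sites carrying one of ``include_codes`` contribute; antisense
    (x) sites are *not* summed into the opposite-strand host gene by
    default. Genes with fewer than ``min_reads`` total reads are
    dropped.
    """
    count_cols = [c for c in sites.columns if c.startswith("count_")]
    joined = sites.merge(
        annotations[["site_id", "gene_id", "class_code"]], on="site_id", how="left"
    )
    joined = joined[
        joined["gene_id"].notna() & joined["class_code"].isin(include_codes)
    ]
    by_gene = joined.groupby("gene_id")[count_cols].sum()
    by_gene.columns = [c.removeprefix("count_") for c in count_cols]
    return by_gene[by_gene.sum(axis=1) >= min_reads]
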