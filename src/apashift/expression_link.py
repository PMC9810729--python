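"""Linking APA change to gene-expression change.

Genes are classed up/down/unchanged from an externally supplied
differential-expression table (computed on CDS-mapped reads so 3'UTR
length differences between isoforms do not confound the expression
estimate), and the distributions of PDUI log2FC across classes are
compared by two-sample Kolmogorov-Smirnov tests on their empirical CDFs.
Also provides CPM and fold-ratio utilities for small-RNA count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)

DE_UP = "up"
DE_DOWN = "down"
DE_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class KsResult:
    """Two-sample K-S comparison: sup-distance and asymptotic p."""

    d_stat: float
    p: float
    n1: int
    n2: int


def classify_de(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Class each gene up/down/unchanged from log2FC and adjusted p.

    Input columns: gene_id, log2fc, padj. Rows with missing values are
    dropped (logged).
    """
    df = table.copy()
    bad = ~np.isfinite(df["log2fc"]) | ~np.isfinite(df["padj"])
    if bad.any():
        logger.info("classify_de: dropping %d rows with missing values",
                    int(bad.sum()))
        df = df[~bad]
    df = df.copy()
    df["de_class"] = DE_UNCHANGED
    sig = df["padj"] < alpha
    df.loc[sig & (df["log2fc"] > 0), "de_class"] = DE_UP
    df.loc[sig & (df["log2fc"] < 0), "de_class"] = DE_DOWN
    return df


def ks_two_sample(x, y) -> KsResult:
    """Two-sample K-S test with the asymptotic p approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 points")
    res = ks_2samp(x, y, method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue), len(x), len(y))


def _ecdf_table(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    frac = np.arange(1, len(v) + 1) / len(v)
    return pd.DataFrame({"value": v, "cumulative_fraction": frac})


def cdf_compare(
    records: pd.DataFrame,
    classes: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """CDFs of PDUI log2FC per expression class, plus K-S comparisons.

    ``records`` is the differential-APA table (gene_id, pdui_log2fc and,
    if present, event labels); ``classes`` carries gene_id and de_class.
    Returns empirical-CDF tables per class and KsResults for
    up-vs-unchanged and down-vs-unchanged; when event labels exist, the
    shortened-vs-others comparison of expression log2FC is run as well.
    Comparisons with an empty or too-small class are skipped with a
    warning.
    """
    merged = records.merge(classes[["gene_id", "de_class"]], on="gene_id")
    cdfs = {
        cls: _ecdf_table(grp["pdui_log2fc"].to_numpy())
        for cls, grp in merged.groupby("de_class")
    }
    ks: dict[str, KsResult] = {}
    ref = merged.loc[merged["de_class"] == DE_UNCHANGED, "pdui_log2fc"]
    for cls in (DE_UP, DE_DOWN):
        sample = merged.loc[merged["de_class"] == cls, "pdui_log2fc"]
        if len(sample) < 2 or len(ref) < 2:
            logger.warning("cdf_compare: skipping %s vs unchanged "
                           "(too few genes)", cls)
            continue
        ks[f"{cls}_vs_unchanged"] = ks_two_sample(sample, ref)

    if "event" in merged.columns and "log2fc" in classes.columns:
        expr = records.merge(classes[["gene_id", "log2fc"]], on="gene_id")
        short = expr.loc[expr["event"] == "shortened", "log2fc"]
        other = expr.loc[expr["event"] != "shortened", "log2fc"]
        if len(short) >= 2 and len(other) >= 2:
            ks["shortened_vs_others_expression"] = ks_two_sample(short, other)
            cdfs["shortened_expression"] = _ecdf_table(short.to_numpy())
            cdfs["others_expression"] = _ecdf_table(other.to_numpy())
        else:
            logger.warning("cdf_compare: skipping shortened-vs-others "
                           "(too few genes)")
    return {"cdfs": cdfs, "ks": ks}


def cpm(counts, library_size: float):
    """Counts-per-million scaling."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def fold_ratio(cpm_table: pd.Series, a: str, b: str) -> float:
    """Ratio of feature a's CPM to feature b's (e.g. between miRNAs)."""
    if b not in cpm_table.index:
        raise KeyError(f"feature {b!r} absent from table")
    if a not in cpm_table.index:
        raise KeyError(f"feature {a!r} absent from table")
    denom = float(cpm_table[b])
    if denom <= 0:
        raise ZeroDivisionError(f"feature {b!r} has zero CPM")
    return float(cpm_table[a]) / denom
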