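"""Two-condition differential APA analysis.

Per gene, the shift in isoform usage between condition A (reference, e.g.
the earlier timepoint) and condition B is summarized two ways:

* ``PDUI log2FC`` = log2(PDUI_B) - log2(PDUI_A), with a small floor ``eps``
  applied before the log so exclusive-proximal genes stay finite;
* ``RED`` (relative expression difference) =
  log2(aUTR reads / cUTR reads)_B - log2(aUTR reads / cUTR reads)_A,
  with a pseudocount ``pc``.

Negative values of either statistic mean 3'UTR shortening (more
proximal-PA use in B); positive values mean lengthening.

A gene's change is called significant when the BH-adjusted two-sided
Fisher exact p-value on the 2x2 table of long-supporting (aUTR) versus
short-attributable (cUTR minus aUTR, floored at 0) read counts is below
``alpha`` AND the isoform-usage change exceeds ``delta`` (by default an
absolute PDUI change > 0.2; a relative isoform-ratio interpretation is
available via ``criterion="relative"``).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

logger = logging.getLogger(__name__)

EVENT_SHORTENED = "shortened"
EVENT_LENGTHENED = "lengthened"
EVENT_NOCHANGE = "nochange"

# relative tolerance used when comparing table probabilities for the
# two-sided Fisher p, so that near-ties from floating point round the
# same way as the reference enumeration
_TIE_RTOL = 1e-7


def pdui_log2fc(pdui_a: float, pdui_b: float, eps: float = 0.01) -> float:
    """log2 fold-change of PDUI (B over A) with floor ``eps``."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    return float(np.log2(max(pdui_b, eps)) - np.log2(max(pdui_a, eps)))


def red(
    autr_reads_a: float, cutr_reads_a: float,
    autr_reads_b: float, cutr_reads_b: float,
    pc: float = 1.0,
) -> float:
    """Relative expression difference of the aUTR/cUTR read ratio (B - A)."""
    if pc < 0:
        raise ValueError("pseudocount must be >= 0")
    if min(autr_reads_a, cutr_reads_a, autr_reads_b, cutr_reads_b) < 0:
        raise ValueError("read counts must be >= 0")
    if pc == 0 and (cutr_reads_a == 0 or cutr_reads_b == 0
                    or autr_reads_a == 0 or autr_reads_b == 0):
        raise ZeroDivisionError("zero count with pc = 0")
    ratio_b = (autr_reads_b + pc) / (cutr_reads_b + pc)
    ratio_a = (autr_reads_a + pc) / (cutr_reads_a + pc)
    return float(np.log2(ratio_b) - np.log2(ratio_a))


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (with the observed
    margins) that are no more probable than the observed one. Uses the
    unimodality of the hypergeometric pmf: tail masses beyond the
    crossing points on each side of the mode are taken from the cdf/sf,
    with the crossing points located by bisection.
    """
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # zero-margin table: no association testable
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    dist = hypergeom(n, c1, r1)
    p_obs = float(dist.pmf(a))
    thresh = p_obs * (1.0 + _TIE_RTOL)
    mode = int((r1 + 1) * (c1 + 1) // (n + 2))
    mode = min(max(mode, lo), hi)
    if float(dist.pmf(a)) >= float(dist.pmf(mode)) / (1.0 + _TIE_RTOL):
        return 1.0

    def cross_right() -> int:
        # smallest x in (mode, hi] with pmf(x) <= thresh (pmf decreasing)
        l, r = mode, hi
        if float(dist.pmf(hi)) > thresh:
            return hi + 1
        while r - l > 1:
            m = (l + r) // 2
            if float(dist.pmf(m)) <= thresh:
                r = m
            else:
                l = m
        return r

    def cross_left() -> int:
        # largest x in [lo, mode) with pmf(x) <= thresh (pmf increasing)
        l, r = lo, mode
        if float(dist.pmf(lo)) > thresh:
            return lo - 1
        while r - l > 1:
            m = (l + r) // 2
            if float(dist.pmf(m)) <= thresh:
                l = m
            else:
                r = m
        return l

    if a < mode:
        x = cross_right()
        p = float(dist.cdf(a)) + (float(dist.sf(x - 1)) if x <= hi else 0.0)
    else:
        x = cross_left()
        p = float(dist.sf(a - 1)) + (float(dist.cdf(x)) if x >= lo else 0.0)
    return min(1.0, p)


def test_apa_change(
    autr_a: int, cutr_only_a: int, autr_b: int, cutr_only_b: int
) -> float:
    """Two-sided Fisher exact p for an isoform-usage shift.

    Cells are long-supporting (aUTR) vs short-attributable (cUTR minus
    aUTR, floored at 0) read counts in each condition. A zero-margin
    table is untestable and returns p = 1 (logged).
    """
    cells = (autr_a, cutr_only_a, autr_b, cutr_only_b)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        logger.debug("zero-margin Fisher table %s: p = 1", cells)
        return 1.0
    return _fisher_two_sided(a, b, c, d)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def classify_events(
    records: pd.DataFrame,
    alpha: float = 0.05,
    delta: float = 0.2,
    criterion: str = "absolute",
    eps: float = 0.01,
) -> pd.DataFrame:
    """Label each gene shortened / lengthened / nochange.

    ``criterion="absolute"`` (default): significant when padj < alpha and
    |PDUI_B - PDUI_A| > delta. ``criterion="relative"``: the long/short
    isoform ratio (PDUI odds, floored by ``eps``) must change by more than
    ``delta`` relative to condition A.
    """
    out = records.copy()
    dp = out["pdui_b"] - out["pdui_a"]
    sig = out["padj"] < alpha
    if criterion == "absolute":
        big = dp.abs() > delta
    elif criterion == "relative":
        odds = lambda p: np.maximum(p, eps) / np.maximum(1.0 - p, eps)
        rel = odds(out["pdui_b"]) / odds(out["pdui_a"]) - 1.0
        big = rel.abs() > delta
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    out["event"] = EVENT_NOCHANGE
    out.loc[sig & big & (dp < 0), "event"] = EVENT_SHORTENED
    out.loc[sig & big & (dp > 0), "event"] = EVENT_LENGTHENED
    return out


def shortening_ratio(records: pd.DataFrame) -> float:
    """Fold excess of shortening over lengthening calls (inf if none)."""
    n_short = int((records["event"] == EVENT_SHORTENED).sum())
    n_long = int((records["event"] == EVENT_LENGTHENED).sum())
    if n_long == 0:
        if n_short:
            logger.warning("no lengthening events: ratio reported as inf")
        return float("inf") if n_short else float("nan")
    return n_short / n_long


def bin_by_length(
    records: pd.DataFrame,
    lengths: Mapping[str, int],
    n_bins: int = 5,
) -> pd.DataFrame:
    """Equal-count length bins with per-bin mean +/- SEM of PDUI log2FC.

    Genes are sorted by length (ties broken by gene_id) and split into
    ``n_bins`` contiguous groups whose sizes differ by at most one, the
    earlier (shorter-length) bins taking the extra gene.
    """
    df = records.copy()
    df["_len"] = df["gene_id"].map(lengths)
    if df["_len"].isna().any():
        missing = df.loc[df["_len"].isna(), "gene_id"].tolist()
        raise ValueError(f"no length for genes: {missing[:5]}")
    if n_bins > len(df):
        raise ValueError("more bins than genes")
    df = df.sort_values(["_len", "gene_id"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    rows = []
    start = 0
    for i, size in enumerate(sizes, start=1):
        chunk = df.iloc[start:start + size]
        start += size
        vals = chunk["pdui_log2fc"].to_numpy(float)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({
            "bin_index": i,
            "length_min": int(chunk["_len"].min()),
            "length_max": int(chunk["_len"].max()),
            "n_genes": int(size),
            "mean_pdui_log2fc": float(vals.mean()),
            "sem": float(sem),
        })
    return pd.DataFrame(rows)


def method_concordance(records: pd.DataFrame) -> dict[str, float]:
    """Agreement between the PDUI-log2FC and RED views of the same shift.

    Returns the Pearson r between the two statistics, the fraction of
    genes on which their signs agree, and the fraction of
    shortened-called genes whose RED is also negative.
    """
    df = records[np.isfinite(records["pdui_log2fc"])
                 & np.isfinite(records["red"])]
    if len(df) < 3:
        raise ValueError("need at least 3 genes with finite statistics")
    x = df["pdui_log2fc"].to_numpy(float)
    y = df["red"].to_numpy(float)
    r = float(pearsonr(x, y)[0]) if (x.std() > 0 and y.std() > 0) else float("nan")
    sign_agreement = float(np.mean(np.sign(x) == np.sign(y)))
    shortened = df["event"] == EVENT_SHORTENED if "event" in df else None
    if shortened is not None and shortened.any():
        overlap = float((df.loc[shortened, "red"] < 0).mean())
    else:
        overlap = float("nan")
    return {"pearson_r": r, "sign_agreement": sign_agreement,
            "shortened_overlap": overlap}


def build_diff_table(
    quant_a: pd.DataFrame,
    quant_b: pd.DataFrame,
    alpha: float = 0.05,
    delta: float = 0.2,
    eps: float = 0.01,
    pc: float = 1.0,
    criterion: str = "absolute",
) -> pd.DataFrame:
    """Assemble the per-gene differential table from two condition tables.

    Each input needs columns gene_id, pdui, quantifiable, cutr_counts,
    autr_counts, cutr_len, autr_len (region read-count sums from pooled
    coverage). Only genes quantifiable in both conditions are tested; a
    gene-set mismatch between conditions is an error.
    """
    a_ids, b_ids = set(quant_a["gene_id"]), set(quant_b["gene_id"])
    if a_ids != b_ids:
        missing = sorted(a_ids.symmetric_difference(b_ids))
        raise ValueError(
            f"condition gene sets differ; first mismatches: {missing[:10]}"
        )
    m = quant_a.merge(quant_b, on="gene_id", suffixes=("_a", "_b"))
    m = m[m["quantifiable_a"] & m["quantifiable_b"]].reset_index(drop=True)

    recs = pd.DataFrame({"gene_id": m["gene_id"]})
    recs["pdui_a"] = m["pdui_a"].astype(float)
    recs["pdui_b"] = m["pdui_b"].astype(float)
    recs["pdui_log2fc"] = [
        pdui_log2fc(pa, pb, eps) for pa, pb in zip(recs["pdui_a"], recs["pdui_b"])
    ]
    recs["red"] = [
        red(aa, ca, ab, cb, pc)
        for aa, ca, ab, cb in zip(
            m["autr_counts_a"], m["cutr_counts_a"],
            m["autr_counts_b"], m["cutr_counts_b"],
        )
    ]

    def cells(row, cond):
        autr = row[f"autr_counts_{cond}"]
        cutr = row[f"cutr_counts_{cond}"]
        autr_len = row[f"autr_len_{cond}"]
        cutr_len = row[f"cutr_len_{cond}"]
        long_reads = int(round(autr))
        # short-attributable: cUTR reads minus the long isoform's expected
        # contribution over the cUTR (aUTR density times cUTR length)
        short_reads = int(round(max(0.0, cutr - autr / autr_len * cutr_len)))
        return long_reads, short_reads

    ps = []
    for _, row in m.iterrows():
        la, sa = cells(row, "a")
        lb, sb = cells(row, "b")
        ps.append(test_apa_change(la, sa, lb, sb))
    recs["p"] = ps
    recs["padj"] = bh_adjust(recs["p"].to_numpy())
    return classify_events(recs, alpha=alpha, delta=delta,
                           criterion=criterion, eps=eps)
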