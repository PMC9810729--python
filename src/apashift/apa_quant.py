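"""Per-gene, per-condition APA isoform quantification.

The two-site estimator: reads covering the aUTR can only come from the
long (distal-PA) isoform, while reads over the cUTR come from both
isoforms. With mean RPM-per-base densities ``autr_density`` and
``cutr_density``, the long-isoform abundance (lAPA RPM) is the aUTR
density, the short-isoform abundance (sAPA RPM) is the density excess
``cutr_density - autr_density`` (floored at 0), and

    PDUI = lAPA / (lAPA + sAPA)  =  autr_density / cutr_density

clipped to [0, 1]. PDUI = 1 means exclusive distal-PA use, 0 exclusive
proximal-PA use.

When the proximal CPS is not annotated it is fitted de novo as the
change-point of a two-level (step) model of UTR coverage, in the style of
localized-density APA detectors: coverage is ``a_T`` (both isoforms)
upstream of the breakpoint and ``a_L`` (long isoform only) downstream,
fitted by constrained least squares over a grid of candidate breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_coverage import RegionCoverage, UtrSegmentation

# PDUI-group cutpoints (group 1 = exclusive distal, 7 = exclusive proximal).
# The 0.01 tolerance on groups 1/7 absorbs estimator noise around truly
# exclusive usage; interior cutpoints are quintiles of the remainder.
GROUP_EXCLUSIVE_TOL = 0.01
GROUP_CUTPOINTS = (0.8, 0.6, 0.4, 0.2)


@dataclass
class ApaQuant:
    """Isoform usage of one gene in one condition (pooled replicates)."""

    gene_id: str
    condition: str
    cutr_density: float
    autr_density: float
    lapa_rpm: float
    sapa_rpm: float
    pdui: float
    pdui_group: int
    quantifiable: bool
    n_replicates: int = 1


@dataclass
class CpsFit:
    """Two-segment step fit of UTR coverage.

    ``fitted_proximal_cps`` is a transcript coordinate (nt from the UTR
    start). ``degenerate`` flags fits whose step ``a_T - a_L`` is below the
    minimum: effectively single-isoform coverage.
    """

    gene_id: str
    fitted_proximal_cps: int
    long_level: float
    short_plus_long_level: float
    sse: float
    degenerate: bool


@dataclass
class IpaQuant:
    """Simplified intronic-polyadenylation usage statistic.

    ``ipa_usage`` is log2 of the density upstream of the intronic PA over
    the terminal-exon density, both offset by a pseudo-density ``c`` so the
    value is finite for silent regions. Differences of this value between
    conditions give a delta-IPA.
    """

    gene_id: str
    intron_id: str
    condition: str
    upstream_density: float
    terminal_exon_density: float
    ipa_usage: float


def estimate_pdui(cov: RegionCoverage, seg: UtrSegmentation) -> ApaQuant:
    """PDUI of one gene from pooled replicate coverage over the 3'UTR.

    ``cov.per_base_counts`` must span the 3'UTR in transcript orientation;
    the first ``seg.cutr_length`` bases are the cUTR and the following
    ``seg.autr_length`` bases the aUTR. A gene with zero cUTR density is
    returned with ``quantifiable=False``.
    """
    if seg.cutr_length <= 0 or seg.autr_length <= 0:
        raise ValueError(
            f"{seg.gene_id}: bad segmentation "
            f"(cutr={seg.cutr_length}, autr={seg.autr_length})"
        )
    need = seg.cutr_length + seg.autr_length
    if len(cov.per_base_counts) < need:
        raise ValueError(
            f"{seg.gene_id}: coverage vector shorter than cUTR+aUTR"
        )
    dens = cov.density
    cutr_d = float(dens[: seg.cutr_length].mean())
    autr_d = float(dens[seg.cutr_length: need].mean())
    lapa = autr_d
    sapa = max(0.0, cutr_d - autr_d)
    if cutr_d <= 0:
        return ApaQuant(seg.gene_id, cov.condition, cutr_d, autr_d,
                        lapa, sapa, float("nan"), 0, quantifiable=False)
    pdui = min(1.0, max(0.0, autr_d / cutr_d))
    return ApaQuant(seg.gene_id, cov.condition, cutr_d, autr_d, lapa, sapa,
                    pdui, classify_pdui_group(pdui), quantifiable=True)


def fit_proximal_cps(
    cov: RegionCoverage,
    grid_step: int = 10,
    margin: int = 50,
    min_step: float = 2.0,
) -> CpsFit:
    """Fit the proximal CPS as the change-point of a two-level step model.

    Candidate breakpoints run from ``margin`` to ``utr_len - margin`` in
    increments of ``grid_step``. At each candidate ``p`` the density is
    modelled as ``a_T`` on ``[0, p)`` and ``a_L`` on ``[p, L)`` with
    ``0 <= a_L <= a_T``; the least-squares solution under that constraint
    is the pair of segment means, or the global mean for both when the
    downstream mean exceeds the upstream one. The ``p`` minimizing the SSE
    wins; ties go to the smallest (most proximal) ``p``. Fits whose step is
    below ``min_step`` RPM/base are flagged degenerate.
    """
    dens = cov.density
    n = len(dens)
    if n < 2 * margin + grid_step:
        raise ValueError(
            f"{cov.gene_id}: UTR of {n} nt too short for change-point "
            f"search (margin={margin}, grid_step={grid_step})"
        )
    candidates = np.arange(margin, n - margin + 1, grid_step)
    csum = np.concatenate(([0.0], np.cumsum(dens)))
    csq = np.concatenate(([0.0], np.cumsum(dens ** 2)))
    total, total_sq = csum[-1], csq[-1]

    p = candidates.astype(int)
    left_n, right_n = p, n - p
    left_mean = csum[p] / left_n
    right_mean = (total - csum[p]) / right_n
    # constrained LS: if right mean > left mean the constrained optimum
    # collapses both levels to the global mean
    ok = right_mean <= left_mean
    a_t = np.where(ok, left_mean, total / n)
    a_l = np.where(ok, right_mean, total / n)
    sse = (
        csq[p] - 2 * a_t * csum[p] + left_n * a_t ** 2
        + (total_sq - csq[p]) - 2 * a_l * (total - csum[p]) + right_n * a_l ** 2
    )
    best = int(np.argmin(sse))  # argmin takes the first (smallest p) on ties
    fit_a_t, fit_a_l = float(a_t[best]), float(max(0.0, a_l[best]))
    degenerate = (fit_a_t - fit_a_l) < min_step
    return CpsFit(
        gene_id=cov.gene_id,
        fitted_proximal_cps=int(p[best]),
        long_level=fit_a_l,
        short_plus_long_level=fit_a_t,
        sse=float(max(0.0, sse[best])),
        degenerate=bool(degenerate),
    )


def classify_pdui_group(pdui: float) -> int:
    """Map a PDUI to one of 7 usage groups.

    Group 1: PDUI >= 0.99 (exclusive distal use); group 7: PDUI <= 0.01
    (exclusive proximal use); groups 2..6 partition the remainder at
    cutpoints 0.8/0.6/0.4/0.2, boundary values belonging to the
    higher-PDUI group. Groups 2-6 are the "APA genes": both sites used.
    """
    if not (0.0 <= pdui <= 1.0):
        raise ValueError(f"PDUI {pdui} outside [0, 1]")
    if pdui >= 1.0 - GROUP_EXCLUSIVE_TOL:
        return 1
    if pdui <= GROUP_EXCLUSIVE_TOL:
        return 7
    for i, cut in enumerate(GROUP_CUTPOINTS):
        if pdui >= cut:
            return i + 2
    return 6


def minor_isoform_fraction(q: ApaQuant) -> float:
    """Fraction of the gene's signal carried by its less-used isoform."""
    if not q.quantifiable:
        raise ValueError(f"{q.gene_id}: not quantifiable")
    return min(q.pdui, 1.0 - q.pdui)


def ipa_usage(
    intron_cov: RegionCoverage,
    terminal_exon_cov: RegionCoverage,
    ipa_offset: int,
    intron_id: str = "intron1",
    c: float = 1.0,
) -> IpaQuant:
    """Intronic-PA usage for one intron in one condition.

    ``ipa_offset`` is the intronic PA position in nt from the intron's
    transcript-orientation start; density upstream of it (the putative
    terminal extension of the truncated isoform) is compared to the
    gene's terminal-exon density on a log2 scale with pseudo-density
    ``c > 0``.
    """
    if c <= 0:
        raise ValueError("pseudo-density c must be > 0")
    n = len(intron_cov.per_base_counts)
    if not (0 < ipa_offset <= n):
        raise ValueError(
            f"{intron_cov.gene_id}: intronic PA offset {ipa_offset} outside "
            f"intron of {n} nt"
        )
    up = float(intron_cov.density[:ipa_offset].mean())
    term = float(terminal_exon_cov.density.mean())
    usage = float(np.log2((up + c) / (term + c)))
    return IpaQuant(intron_cov.gene_id, intron_id, intron_cov.condition,
                    up, term, usage)
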