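"""End-to-end orchestration: quantify -> diff -> report.

A flat key=value config file drives the stages (CLI flags override).
Every output TSV starts with '#'-prefixed metadata lines (tool version,
config hash, seed) so that reruns with an identical config are
byte-identical and outputs are self-describing.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .annotation_coverage import (
    GeneModel,
    PaSitePair,
    load_coverage,
    load_gene_models,
    load_pa_sites,
    pool_coverage,
    segment_utr,
)
from .apa_quant import (
    classify_pdui_group,
    estimate_pdui,
    fit_proximal_cps,
    minor_isoform_fraction,
)
from .diff_apa import bin_by_length, build_diff_table, method_concordance, \
    shortening_ratio
from .expression_link import cdf_compare, classify_de, cpm

logger = logging.getLogger(__name__)

CONFIG_DEFAULTS = {
    "condition_a": "d14",
    "condition_b": "d21",
    "alpha": 0.05,
    "delta": 0.2,
    "eps": 0.01,
    "pc": 1.0,
    "min_coverage": 5.0,
    "min_utr_len": 150,
    "grid_step": 10,
    "margin": 50,
    "min_step": 2.0,
    "mode": "annotated_pa",
    "criterion": "absolute",
    "seed": 0,
    "n_bins": 5,
}
_NUMERIC_KEYS = {
    "alpha": float, "delta": float, "eps": float, "pc": float,
    "min_coverage": float, "min_utr_len": int, "grid_step": int,
    "margin": int, "min_step": float, "seed": int, "n_bins": int,
}


def parse_config(path: str, overrides: dict | None = None) -> dict:
    """Flat key=value config; '#' lines are comments."""
    cfg = dict(CONFIG_DEFAULTS)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            cfg[key.strip()] = val.strip()
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key, typ in _NUMERIC_KEYS.items():
        if key in cfg:
            cfg[key] = typ(cfg[key])
    if cfg["mode"] not in ("annotated_pa", "denovo_cps"):
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    if not (0 < cfg["alpha"] < 1) or not (0 <= cfg["delta"] < 1):
        raise ValueError("alpha must be in (0,1) and delta in [0,1)")
    return cfg


def config_hash(cfg: dict) -> str:
    text = "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# apashift {__version__}\n")
        fh.write(f"# config_sha256={config_hash(cfg)}\n")
        fh.write(f"# seed={cfg.get('seed', 0)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _paths(cfg: dict, key: str) -> list[str]:
    raw = cfg.get(key, "")
    return [p.strip() for p in str(raw).split(",") if p.strip()]


def _lib_sizes(cfg: dict, key: str, n: int) -> list[float | None]:
    raw = str(cfg.get(key, "")).strip()
    if not raw:
        return [None] * n
    vals = [float(x) for x in raw.split(",")]
    if len(vals) != n:
        raise ValueError(f"{key}: expected {n} values, got {len(vals)}")
    return vals


def _load_condition_coverage(cfg: dict, genes, cond_key: str):
    cond_name = cfg[f"condition_{cond_key}"]
    paths = _paths(cfg, f"coverage_{cond_key}")
    if not paths:
        raise ValueError(f"config missing coverage_{cond_key}")
    libs = _lib_sizes(cfg, f"library_size_{cond_key}", len(paths))
    reps = []
    for i, (path, lib) in enumerate(zip(paths, libs), 1):
        reps.append(load_coverage(path, genes, condition=cond_name,
                                  replicate_id=f"r{i}", library_size=lib))
    return reps


def _passes_coverage_filter(gene_id: str, rep_covs: list[dict],
                            cutr_len: int, min_cov: float) -> bool:
    # mean raw per-base count over the cUTR in EVERY replicate
    for covs in rep_covs:
        vec = covs[gene_id].per_base_counts[:cutr_len]
        if vec.mean() < min_cov:
            return False
    return True


def quantify_condition(
    genes: list[GeneModel],
    segs: dict,
    rep_covs: list[dict],
    condition: str,
) -> pd.DataFrame:
    """Pool replicates and estimate PDUI per gene for one condition."""
    rows = []
    for g in genes:
        seg = segs[g.gene_id]
        pooled = pool_coverage([covs[g.gene_id] for covs in rep_covs])
        q = estimate_pdui(pooled, seg)
        counts = pooled.per_base_counts
        need = seg.cutr_length + seg.autr_length
        rows.append({
            "gene_id": g.gene_id,
            "condition": condition,
            "cutr_density": q.cutr_density,
            "autr_density": q.autr_density,
            "pdui": q.pdui,
            "pdui_group": q.pdui_group if q.quantifiable else 0,
            "quantifiable": q.quantifiable,
            "n_replicates": len(rep_covs),
            "cutr_counts": float(counts[:seg.cutr_length].sum()),
            "autr_counts": float(counts[seg.cutr_length:need].sum()),
            "cutr_len": seg.cutr_length,
            "autr_len": seg.autr_length,
        })
    return pd.DataFrame(rows)


def _segmentations(cfg, genes, rep_covs_all) -> dict:
    """cUTR/aUTR split per gene: annotated PA pair or de-novo fit."""
    if cfg["mode"] == "annotated_pa":
        pa = load_pa_sites(cfg["pa_bed"], genes)
        segs = {}
        for g in genes:
            if g.gene_id not in pa:
                logger.warning("no PA pair for %s; gene dropped", g.gene_id)
                continue
            segs[g.gene_id] = segment_utr(g, pa[g.gene_id])
        return segs
    # de-novo: fit a common change-point on coverage pooled over all
    # replicates of both conditions, distal CPS fixed at the UTR end
    segs = {}
    for g in genes:
        pooled = pool_coverage(
            [covs[g.gene_id] for covs in rep_covs_all]
        )
        try:
            fit = fit_proximal_cps(pooled, grid_step=cfg["grid_step"],
                                   margin=cfg["margin"],
                                   min_step=cfg["min_step"])
        except ValueError:
            logger.warning("UTR too short for change-point fit: %s; "
                           "gene dropped", g.gene_id)
            continue
        p = fit.fitted_proximal_cps
        s, e = g.utr3
        if g.strand == "+":
            pa_pair = PaSitePair(g.gene_id, s + p, e, source="fitted")
        else:
            pa_pair = PaSitePair(g.gene_id, e - p, s, source="fitted")
        segs[g.gene_id] = segment_utr(g, pa_pair)
    return segs


def pdui_group_census(quant: pd.DataFrame) -> pd.DataFrame:
    """Fractions of quantifiable genes per PDUI group and APA summaries.

    APA genes are groups 2-6 (both PA sites used); among them the census
    reports the fraction whose minor isoform carries >= 20% of the signal.
    """
    q = quant[quant["quantifiable"]]
    n = len(q)
    if n == 0:
        raise ValueError("no quantifiable genes for census")
    rows = []
    for grp in range(1, 8):
        rows.append({
            "metric": f"group_{grp}_fraction",
            "value": float((q["pdui_group"] == grp).sum()) / n,
        })
    apa = q[q["pdui_group"].between(2, 6)]
    rows.append({"metric": "apa_gene_fraction", "value": len(apa) / n})
    minor = np.minimum(apa["pdui"], 1.0 - apa["pdui"])
    rows.append({
        "metric": "apa_minor_ge20_fraction",
        "value": float((minor >= 0.2).mean()) if len(apa) else float("nan"),
    })
    return pd.DataFrame(rows)


def run_quantify(cfg: dict) -> dict[str, pd.DataFrame]:
    """Quantify both conditions; write apa_quant.tsv and the group census."""
    outdir = cfg["out_dir"]
    os.makedirs(outdir, exist_ok=True)
    genes = load_gene_models(cfg["gtf"], min_utr_len=cfg["min_utr_len"])
    reps_a = _load_condition_coverage(cfg, genes, "a")
    reps_b = _load_condition_coverage(cfg, genes, "b")
    segs = _segmentations(cfg, genes, reps_a + reps_b)

    kept, n_dropped = [], 0
    for g in genes:
        if g.gene_id not in segs:
            n_dropped += 1
            continue
        if _passes_coverage_filter(g.gene_id, reps_a + reps_b,
                                   segs[g.gene_id].cutr_length,
                                   cfg["min_coverage"]):
            kept.append(g)
        else:
            n_dropped += 1
    logger.info("coverage filter: kept %d genes, dropped %d",
                len(kept), n_dropped)
    if not kept:
        raise ValueError("no gene passes the coverage filter")

    qa = quantify_condition(kept, segs, reps_a, cfg["condition_a"])
    qb = quantify_condition(kept, segs, reps_b, cfg["condition_b"])
    quant = pd.concat([qa, qb], ignore_index=True)
    write_table(quant, os.path.join(outdir, "apa_quant.tsv"), cfg)

    census = []
    for cond, q in ((cfg["condition_a"], qa), (cfg["condition_b"], qb)):
        c = pdui_group_census(q)
        c.insert(0, "condition", cond)
        census.append(c)
    write_table(pd.concat(census, ignore_index=True),
                os.path.join(outdir, "pdui_group_census.tsv"), cfg)

    lengths = {
        g.gene_id: {"utr3": g.utr3_length,
                    "autr": segs[g.gene_id].autr_length}
        for g in kept
    }
    return {"quant_a": qa, "quant_b": qb, "lengths": lengths}


def run_diff(cfg: dict, quant: dict | None = None) -> pd.DataFrame:
    """Differential APA: per-gene table, summaries, length bins."""
    outdir = cfg["out_dir"]
    if quant is None:
        quant = run_quantify(cfg)
    qa, qb = quant["quant_a"], quant["quant_b"]
    diff = build_diff_table(
        qa, qb, alpha=cfg["alpha"], delta=cfg["delta"], eps=cfg["eps"],
        pc=cfg["pc"], criterion=cfg["criterion"],
    )
    write_table(diff, os.path.join(outdir, "diff_apa.tsv"), cfg)

    summary_rows = [
        {"metric": "n_genes_tested", "value": float(len(diff))},
        {"metric": "n_shortened",
         "value": float((diff["event"] == "shortened").sum())},
        {"metric": "n_lengthened",
         "value": float((diff["event"] == "lengthened").sum())},
        {"metric": "n_nochange",
         "value": float((diff["event"] == "nochange").sum())},
        {"metric": "shortening_ratio", "value": shortening_ratio(diff)},
        {"metric": "mean_pdui_log2fc",
         "value": float(diff["pdui_log2fc"].mean())},
        {"metric": "median_pdui_log2fc",
         "value": float(diff["pdui_log2fc"].median())},
        {"metric": "mean_red", "value": float(diff["red"].mean())},
        {"metric": "median_red", "value": float(diff["red"].median())},
    ]
    try:
        conc = method_concordance(diff)
        for k, v in conc.items():
            summary_rows.append({"metric": f"concordance_{k}", "value": v})
    except ValueError as exc:
        logger.warning("concordance skipped: %s", exc)
    write_table(pd.DataFrame(summary_rows),
                os.path.join(outdir, "diff_summary.tsv"), cfg)

    # length-binned trend over significantly shortened genes
    shortened = diff[diff["event"] == "shortened"]
    target = shortened if len(shortened) >= cfg["n_bins"] else diff
    if target is diff:
        logger.warning("too few shortened genes; binning all genes")
    lengths = quant["lengths"]
    for kind in ("utr3", "autr"):
        lmap = {gid: lv[kind] for gid, lv in lengths.items()}
        bins = bin_by_length(target, lmap, n_bins=cfg["n_bins"])
        write_table(bins, os.path.join(outdir, f"bins_{kind}.tsv"), cfg)
    return diff


def run_report(cfg: dict, diff: pd.DataFrame | None = None) -> int:
    """Expression-linkage report: per-class CDFs, K-S tests, miRNA CPM.

    Returns 0 even when the DE table is absent (report skipped with a
    warning) so pipelines without expression data still succeed.
    """
    outdir = cfg["out_dir"]
    os.makedirs(outdir, exist_ok=True)
    de_path = cfg.get("de_table", "")
    if not de_path or not os.path.exists(str(de_path)):
        logger.warning("DE table missing; expression-linkage report skipped")
        return 0
    if diff is None:
        diff_path = os.path.join(outdir, "diff_apa.tsv")
        if not os.path.exists(diff_path):
            raise FileNotFoundError(
                "diff_apa.tsv not found; run the diff stage first"
            )
        diff = read_table(diff_path)
    de = classify_de(read_table(str(de_path)), alpha=cfg["alpha"])
    res = cdf_compare(diff, de, alpha=cfg["alpha"])
    for cls, table in res["cdfs"].items():
        write_table(table, os.path.join(outdir, f"cdf_{cls}.tsv"), cfg)
    ks_rows = [
        {"comparison": name, "d_stat": ks.d_stat, "p": ks.p,
         "n1": ks.n1, "n2": ks.n2}
        for name, ks in res["ks"].items()
    ]
    write_table(pd.DataFrame(ks_rows),
                os.path.join(outdir, "ks_results.tsv"), cfg)

    mirna_path = str(cfg.get("mirna_counts", ""))
    if mirna_path and os.path.exists(mirna_path):
        counts = read_table(mirna_path)
        vals = cpm(counts["count"].to_numpy(), counts["count"].sum())
        out = pd.DataFrame({"feature": counts["feature"], "cpm": vals})
        write_table(out, os.path.join(outdir, "mirna_cpm.tsv"), cfg)

    _maybe_plot_cdfs(res, outdir)
    return 0


def _maybe_plot_cdfs(res: dict, outdir: str) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"up": "tab:red", "down": "tab:blue", "unchanged": "black"}
    for cls in ("up", "down", "unchanged"):
        if cls in res["cdfs"]:
            t = res["cdfs"][cls]
            ax.step(t["value"], t["cumulative_fraction"], where="post",
                    label=cls, color=colors[cls])
    ax.set_xlabel("PDUI log2FC")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "cdf_pdui_log2fc.png"), dpi=120)
    plt.close(fig)


def run_all(cfg: dict) -> int:
    quant = run_quantify(cfg)
    diff = run_diff(cfg, quant)
    return run_report(cfg, diff)
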