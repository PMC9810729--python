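"""Synthetic two-condition RNA-seq coverage with known APA ground truth.

The generator emulates the data structure the APA pipeline consumes: genes
with one proximal and one distal PA in the last exon, per-gene expression
(log-normal), a per-gene long-isoform fraction (PDUI) per condition, a
configurable excess of shortening over lengthening events between the
conditions, Poisson per-base read noise with a moving-average smoothing of
the expected density emulating fragment edges, biological replicates, a
CDS-count table with expression changes coupled to shortening, and a
small-RNA (miRNA) count table with configurable CPM fold-ratios.

Coverage is simulated at per-base density level rather than by placing
reads: the pipeline consumes coverage, and density-level simulation keeps
runtimes in seconds while preserving the statistical structure that
matters for the estimators (two-level UTR density, Poisson counting
noise, smoothed steps).

All randomness flows from ``SimParams.seed``; identical parameters give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic dataset.

    Defaults emulate the pipeline's intended regime: 2 000 genes, three
    biological replicates per condition, ~50x mean cUTR coverage, and a
    24:1 designed excess of shortening (240) over lengthening (10) truth
    events with |dPDUI| in [0.25, 0.5]. ``de_coupling`` is the expression
    log2FC added to shortened genes (lengthened genes get its negative),
    coupling 3'UTR shortening with up-regulation.
    """

    n_genes: int = 2000
    seed: int = 0
    # 3'UTR length: log-normal, clipped to [200, 3000] nt
    utr_len_mu: float = 6.6
    utr_len_sigma: float = 0.5
    utr_len_range: tuple[int, int] = (200, 3000)
    # aUTR fraction of the 3'UTR: Beta(a, b); cUTR kept >= 60 nt from
    # either UTR end so the change-point search window always contains it
    autr_frac_a: float = 2.0
    autr_frac_b: float = 2.0
    min_cutr_margin: int = 60
    # expression: log-normal mean cUTR coverage (x-fold per base)
    expr_mean: float = 50.0
    expr_sigma: float = 0.5
    # baseline PDUI in condition A: Beta(a, b), clipped to [0.01, 0.99]
    pdui_a_alpha: float = 2.0
    pdui_a_beta: float = 2.0
    # truth events: dPDUI uniform in the given ranges
    n_shortened: int = 240
    n_lengthened: int = 10
    dpdui_shortened: tuple[float, float] = (-0.5, -0.25)
    dpdui_lengthened: tuple[float, float] = (0.25, 0.5)
    replicates: int = 3
    condition_a: str = "d14"
    condition_b: str = "d21"
    smooth_window: int = 25
    noiseless: bool = False
    de_coupling: float = 1.0
    de_background_sigma: float = 0.2
    cds_count_factor: float = 10.0
    # gene layout
    cds1_len: int = 300
    intron_len: int = 200
    cds2_len: int = 200
    intergenic_gap: int = 500
    genes_per_contig: int = 100

    @property
    def shortening_to_lengthening_target(self) -> float:
        return self.n_shortened / max(1, self.n_lengthened)


def _draw_truth(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    p = params
    if p.n_shortened + p.n_lengthened > p.n_genes:
        raise ValueError("more truth events than genes")
    n = p.n_genes
    utr_len = np.clip(
        np.round(rng.lognormal(p.utr_len_mu, p.utr_len_sigma, n)),
        *p.utr_len_range,
    ).astype(int)
    autr_frac = rng.beta(p.autr_frac_a, p.autr_frac_b, n)
    cutr_len = np.round((1.0 - autr_frac) * utr_len).astype(int)
    cutr_len = np.clip(cutr_len, p.min_cutr_margin,
                       utr_len - p.min_cutr_margin)
    autr_len = utr_len - cutr_len

    mu = np.log(p.expr_mean) - 0.5 * p.expr_sigma ** 2
    expr = rng.lognormal(mu, p.expr_sigma, n)
    pdui_a = np.clip(rng.beta(p.pdui_a_alpha, p.pdui_a_beta, n), 0.01, 0.99)

    # assign truth events only to genes with enough PDUI headroom for the
    # drawn shift, so truth labels always mean a real shift of that size
    dpdui = np.zeros(n)
    event = np.array(["none"] * n, dtype=object)
    d_short = rng.uniform(*p.dpdui_shortened, p.n_shortened)
    d_long = rng.uniform(*p.dpdui_lengthened, p.n_lengthened)
    order = rng.permutation(n)
    queue = [("shortened", d) for d in d_short] + \
            [("lengthened", d) for d in d_long]
    qi = 0
    for gi in order:
        if qi >= len(queue):
            break
        ev, d = queue[qi]
        if 0.01 <= pdui_a[gi] + d <= 0.99:
            event[gi], dpdui[gi] = ev, d
            qi += 1
    if qi < len(queue):
        raise ValueError(
            f"could not place {len(queue) - qi} truth events: "
            "not enough genes with PDUI headroom"
        )
    pdui_b = np.clip(pdui_a + dpdui, 0.0, 1.0)

    expr_l2fc = rng.normal(0.0, p.de_background_sigma, n)
    expr_l2fc[event == "shortened"] += p.de_coupling
    expr_l2fc[event == "lengthened"] -= p.de_coupling

    strand = np.where(rng.random(n) < 0.5, "+", "-")

    # non-overlapping placement on synthetic contigs
    span = p.cds1_len + p.intron_len + p.cds2_len + utr_len
    chrom, gstart = [], []
    pos, contig_i, in_contig = 0, 1, 0
    for i in range(n):
        if in_contig == p.genes_per_contig:
            contig_i += 1
            pos, in_contig = 0, 0
        chrom.append(f"chrS{contig_i}")
        gstart.append(pos)
        pos += int(span[i]) + p.intergenic_gap
        in_contig += 1
    gstart = np.array(gstart)

    df = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "chrom": chrom,
        "strand": strand,
        "gene_start": gstart,
        "gene_end": gstart + span,
        "utr_len": utr_len,
        "cutr_len": cutr_len,
        "autr_len": autr_len,
        "expr": expr,
        "pdui_a": pdui_a,
        "pdui_b": pdui_b,
        "true_event": event,
        "expr_log2fc": expr_l2fc,
    })

    # genomic UTR and CPS coordinates
    plus = df["strand"] == "+"
    utr3_start = np.where(
        plus,
        df["gene_start"] + p.cds1_len + p.intron_len + p.cds2_len,
        df["gene_start"],
    )
    utr3_end = utr3_start + utr_len
    df["utr3_start"], df["utr3_end"] = utr3_start, utr3_end
    df["proximal_cps"] = np.where(plus, utr3_start + cutr_len,
                                  utr3_end - cutr_len)
    df["distal_cps"] = np.where(plus, utr3_end, utr3_start)
    return df


def write_gtf(truth: pd.DataFrame, params: SimParams, path: str) -> None:
    """Emit gene/transcript/exon/CDS features (1-based inclusive)."""
    p = params
    with open(path, "w") as fh:
        fh.write("#!genome synthetic\n")
        for _, g in truth.iterrows():
            s, e = int(g.gene_start), int(g.gene_end)
            if g.strand == "+":
                exon1 = (s, s + p.cds1_len)
                exon2 = (s + p.cds1_len + p.intron_len, e)
                cds1 = exon1
                cds2 = (exon2[0], exon2[0] + p.cds2_len)
            else:
                exon2 = (s, s + int(g.utr_len) + p.cds2_len)
                exon1 = (exon2[1] + p.intron_len, e)
                cds2 = (s + int(g.utr_len), exon2[1])
                cds1 = exon1
            tid = f"{g.gene_id}.t1"

            def line(feat, iv, parent_tx=True):
                attrs = f'gene_id "{g.gene_id}";'
                if parent_tx:
                    attrs += f' transcript_id "{tid}";'
                return (f"{g.chrom}\tsynth\t{feat}\t{iv[0] + 1}\t{iv[1]}\t."
                        f"\t{g.strand}\t.\t{attrs}\n")

            fh.write(line("gene", (s, e), parent_tx=False))
            fh.write(line("transcript", (s, e)))
            for iv in sorted([exon1, exon2]):
                fh.write(line("exon", iv))
            for iv in sorted([cds1, cds2]):
                fh.write(line("CDS", iv))


def write_pa_bed(truth: pd.DataFrame, path: str) -> None:
    """Two BED6 rows per gene, one per CPS (0-based half-open)."""
    with open(path, "w") as fh:
        for _, g in truth.iterrows():
            for pos in sorted((int(g.proximal_cps), int(g.distal_cps))):
                fh.write(f"{g.chrom}\t{pos}\t{pos + 1}\t{g.gene_id}\t0"
                         f"\t{g.strand}\n")


def _expected_gene_density(g, params: SimParams, condition: str) -> np.ndarray:
    """Expected per-base density over the gene span, transcript 5'->3'."""
    p = params
    utr_len, cutr_len = int(g.utr_len), int(g.cutr_len)
    expr = float(g.expr)
    if condition == "b":
        expr *= 2.0 ** float(g.expr_log2fc)
    pdui = float(g.pdui_a if condition == "a" else g.pdui_b)
    parts = [
        np.full(p.cds1_len, expr),
        np.zeros(p.intron_len),
        np.full(p.cds2_len, expr),
        np.full(cutr_len, expr),
        np.full(utr_len - cutr_len, expr * pdui),
    ]
    dens = np.concatenate(parts)
    if p.smooth_window > 1:
        dens = uniform_filter1d(dens, size=p.smooth_window, mode="nearest")
    return np.clip(dens, 0.0, None)  # guard against filter round-off


def simulate_coverage_arrays(
    truth: pd.DataFrame,
    params: SimParams,
    condition: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One replicate's per-chrom coverage arrays (genomic orientation)."""
    chrom_len = truth.groupby("chrom")["gene_end"].max().to_dict()
    arrays = {c: np.zeros(int(l), dtype=np.int64)
              for c, l in chrom_len.items()}
    for _, g in truth.iterrows():
        dens = _expected_gene_density(g, params, condition)
        if g.strand == "-":
            dens = dens[::-1]
        counts = (np.round(dens).astype(np.int64) if params.noiseless
                  else rng.poisson(dens))
        arrays[g.chrom][int(g.gene_start):int(g.gene_end)] += counts
    return arrays


def write_bedgraph(arrays: dict[str, np.ndarray], path: str) -> None:
    """Run-length-encoded 4-column bedGraph; zero runs omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            v = arrays[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            vals = v[starts]
            keep = vals != 0
            block = pd.DataFrame({
                "chrom": chrom,
                "start": starts[keep],
                "end": ends[keep],
                "value": vals[keep],
            })
            block.to_csv(fh, sep="\t", header=False, index=False)


def simulate_mirna_table(
    features: list[str],
    target_ratios: dict[tuple[str, str], float],
    depth: int = 10_000_000,
    seed: int = 0,
    anchor: tuple[str, float] | None = None,
) -> pd.DataFrame:
    """Multinomial small-RNA counts honoring CPM fold-ratios.

    ``target_ratios[(a, b)] = r`` constrains expected CPM(a)/CPM(b) = r.
    Ratios are resolved into relative weights by graph propagation;
    redundant constraints that contradict each other raise. ``anchor``
    optionally pins one constrained feature's expected CPM; unconstrained
    features share the remaining mass equally.
    """
    for (a, b), r in target_ratios.items():
        if r <= 0:
            raise ValueError(f"ratio for ({a},{b}) must be positive")
        if a not in features or b not in features:
            raise ValueError(f"ratio references unknown feature ({a},{b})")
    # propagate weights over the constraint graph
    adj: dict[str, list[tuple[str, float]]] = {f: [] for f in features}
    for (a, b), r in target_ratios.items():
        adj[a].append((b, 1.0 / r))
        adj[b].append((a, r))
    weight: dict[str, float] = {}
    for root in features:
        if root in weight or not adj[root]:
            continue
        weight[root] = 1.0
        stack = [root]
        while stack:
            u = stack.pop()
            for v, f in adj[u]:
                w = weight[u] * f
                if v in weight:
                    if not np.isclose(weight[v], w, rtol=1e-6):
                        raise ValueError(
                            f"inconsistent ratio constraints at {v}"
                        )
                else:
                    weight[v] = w
                    stack.append(v)
    constrained = [f for f in features if f in weight]
    free = [f for f in features if f not in weight]
    probs = np.zeros(len(features))
    if constrained:
        wsum = sum(weight[f] for f in constrained)
        if anchor is not None:
            af, acpm = anchor
            if af not in weight:
                raise ValueError(f"anchor {af!r} is not ratio-constrained")
            scale = (acpm / 1e6) / (weight[af])
            mass = min(1.0, scale * wsum)
        else:
            mass = 0.5 if free else 1.0
        for i, f in enumerate(features):
            if f in weight:
                probs[i] = weight[f] / wsum * mass
        rest = 1.0 - mass
    else:
        rest = 1.0
    if free:
        for i, f in enumerate(features):
            if f in weight:
                continue
            probs[i] = rest / len(free)
    elif rest > 1e-12:
        probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), probs / probs.sum())
    return pd.DataFrame({"feature": features, "count": counts})


DEFAULT_MIRNAS = (
    ["miR-29a-3p", "miR-29b-3p", "miR-29c-3p", "miR-6980-5p"]
    + [f"miR-x{i:02d}" for i in range(1, 12)]
)
DEFAULT_MIRNA_RATIOS = {
    ("miR-29a-3p", "miR-29c-3p"): 8.0,
    ("miR-29a-3p", "miR-29b-3p"): 34.0,
    ("miR-29a-3p", "miR-6980-5p"): 2500.0,
}


def simulate_genome(params: SimParams) -> pd.DataFrame:
    """Draw the ground-truth table (deterministic given the seed)."""
    rng = np.random.default_rng(params.seed)
    return _draw_truth(params, rng)


def simulate_dataset(params: SimParams, outdir: str) -> pd.DataFrame:
    """Generate and write the full synthetic dataset; return the truth.

    Files written: genome.gtf, pa_sites.bed, cov_{cond}_{rep}.bedGraph,
    cds_counts.tsv, de_truth.tsv, mirna_counts.tsv, truth.tsv,
    params.json.
    """
    os.makedirs(outdir, exist_ok=True)
    p = params
    rng = np.random.default_rng(p.seed)
    truth = _draw_truth(p, rng)

    write_gtf(truth, p, os.path.join(outdir, "genome.gtf"))
    write_pa_bed(truth, os.path.join(outdir, "pa_sites.bed"))

    for cond_key, cond_name in (("a", p.condition_a), ("b", p.condition_b)):
        for rep in range(1, p.replicates + 1):
            arrays = simulate_coverage_arrays(truth, p, cond_key, rng)
            write_bedgraph(
                arrays,
                os.path.join(outdir, f"cov_{cond_name}_r{rep}.bedGraph"),
            )

    # CDS counts (reads mapping to the coding region only)
    cds = pd.DataFrame({"gene_id": truth["gene_id"]})
    mean_a = truth["expr"].to_numpy() * p.cds_count_factor
    mean_b = mean_a * 2.0 ** truth["expr_log2fc"].to_numpy()
    for rep in range(1, p.replicates + 1):
        cds[f"{p.condition_a}_r{rep}"] = rng.poisson(mean_a)
    for rep in range(1, p.replicates + 1):
        cds[f"{p.condition_b}_r{rep}"] = rng.poisson(mean_b)
    cds.to_csv(os.path.join(outdir, "cds_counts.tsv"), sep="\t", index=False)

    # truth-based DE table (stands in for an external DE fit)
    de = pd.DataFrame({"gene_id": truth["gene_id"]})
    de["log2fc"] = truth["expr_log2fc"] + rng.normal(0, 0.05, len(truth))
    is_de = truth["true_event"].isin(["shortened", "lengthened"]) \
        & (p.de_coupling != 0)
    de["padj"] = np.where(
        is_de,
        rng.uniform(1e-8, 1e-3, len(truth)),
        rng.uniform(0.06, 1.0, len(truth)),
    )
    de.to_csv(os.path.join(outdir, "de_truth.tsv"), sep="\t", index=False)

    mirna = simulate_mirna_table(
        list(DEFAULT_MIRNAS), dict(DEFAULT_MIRNA_RATIOS),
        depth=10_000_000, seed=p.seed,
        anchor=("miR-29a-3p", 20_000.0),
    )
    mirna.to_csv(os.path.join(outdir, "mirna_counts.tsv"), sep="\t",
                 index=False)

    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    meta = dataclasses.asdict(p)
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return truth
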