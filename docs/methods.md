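# Methods

This note documents the statistical model behind `apashift`, the
defaults it ships with, what the synthetic data generator does and does
not emulate, and the numerical choices that affect results.

## 1. Coverage model and segmentation

All genomic coordinates are handled internally as 0-based, half-open
intervals; GTF input (1-based, closed) is converted on read. Per-gene
coverage vectors are oriented 5′→3′ in transcript space (reversed for
minus-strand genes), so "proximal" always means closer to the stop
codon.

Given two poly(A) sites per gene — a proximal and a distal CPS — the
3′UTR is split at the proximal CPS into:

* **cUTR** (common UTR): transcribed in both isoforms;
* **aUTR** (alternative UTR): the region between proximal and distal
  CPS, transcribed only in the long isoform. Its length is the distance
  between the two sites.

Read densities are normalised to reads per million (RPM) per base using
the library size (sum of the bedGraph by default, or user-supplied).
Replicates of a condition are pooled by summing counts and library
sizes before estimation; an identical per-replicate quantification
would be noisier without changing the estimator.

## 2. PDUI estimation

Under uniform within-region coverage, the cUTR density is proportional
to short + long isoform abundance and the aUTR density to the long
isoform alone. The percentage of distal poly(A) site usage is therefore

```
PDUI = autr_density / cutr_density, clipped to [0, 1]
```

and the short-isoform density is `sAPA = max(0, cutr − autr)`. A gene is
*unquantifiable* when its cUTR density is zero. Assumptions: no internal
priming artefacts, no overlapping transcription, and only two isoforms
per terminal exon; more complex isoform structures bias PDUI toward the
aggregate long-fraction.

Genes are binned into seven PDUI groups: group 1 iff PDUI ≥ 0.99
(exclusive distal use), group 7 iff PDUI ≤ 0.01 (exclusive proximal
use), with cutpoints 0.8 / 0.6 / 0.4 / 0.2 in between; boundary values
belong to the higher-PDUI group. Groups 2–6 are "APA genes" (both
isoforms detectably expressed); the minor-isoform fraction is
`min(PDUI, 1 − PDUI)`.

## 3. De novo change-point CPS

When the proximal CPS is not annotated, it is fitted per gene by
two-segment constrained least squares on the 3′UTR coverage pooled over
all replicates of both conditions (a single common breakpoint keeps the
two conditions comparable). For each candidate breakpoint `p` on a grid
(`grid_step` = 10 nt, excluded `margin` = 50 nt at each end), segment
means are fitted subject to `0 ≤ a_L ≤ a_T` (the long-isoform level
cannot exceed the total); when the unconstrained means violate the
ordering, the constrained optimum collapses to the global mean. The
breakpoint minimising the summed squared error wins; ties go to the
most proximal candidate. A fit is *degenerate* (no usable step) when
`a_T − a_L` < `min_step` = 2 RPM/base. The fit is exhaustively
vectorised with cumulative sums and is exactly equivalent to a brute
force scan (tested).

## 4. Differential APA

For each gene quantifiable in both conditions:

* `pdui_log2fc = log2(max(PDUI_B, ε)/max(PDUI_A, ε))` with ε = 0.01;
  the floor keeps exclusive-proximal genes finite and caps the
  reportable fold change at `log2(1/ε)`.
* `RED = log2((aUTR_B + c)/(cUTR_B + c)) − log2((aUTR_A + c)/(cUTR_A + c))`
  on region read counts, pseudocount c = 1. RED is the count-space
  analogue of the PDUI shift and is used as an internal concordance
  check (Pearson r, sign agreement).
* Significance: a two-sided Fisher exact test on the 2×2 table of
  long- vs short-attributable read counts in A vs B. Long counts are
  the aUTR read counts; short counts are the cUTR counts minus the long
  isoform's expected contribution (`autr_density × cutr_len`), floored
  at 0. The implementation sums hypergeometric probabilities ≤ the
  observed one (relative tie tolerance 1e-7) using unimodality of the
  pmf and bisection for the crossing points, making it O(log support)
  and exact for the large (~10⁴–10⁵) counts typical of pooled coverage;
  it matches full enumeration and `scipy.stats.fisher_exact` (tested).
* Multiple testing: Benjamini–Hochberg (`statsmodels`).
* A gene is **shortened** (PDUI down) or **lengthened** when
  `padj < alpha` (0.05) **and** the effect size exceeds `delta` (0.2).
  The default effect criterion is absolute `|ΔPDUI| > 0.2`; a
  `relative` option instead requires a >20% change of the long/short
  isoform odds, which is more sensitive near PDUI 0.5 and less at the
  extremes.

Summaries include the shortened:lengthened call ratio (infinite, and
flagged, when nothing is lengthened) and PDUI log2FC means binned by
3′UTR or aUTR length (equal-occupancy bins, ties broken by gene id,
remainders to the earlier bins).

## 5. Expression linkage

Genes are classed up / down / unchanged from an external DE table
(`log2fc`, `padj`; `padj < alpha` and sign of `log2fc`). Per-class
empirical CDFs of PDUI log2FC are compared with two-sample
Kolmogorov–Smirnov tests (asymptotic p, via `scipy`); classes with
fewer than 2 members are skipped with a warning. When event labels are
available, the expression log2FC of shortened genes is additionally
compared against all others. miRNA count tables are normalised to
counts per million for fold-ratio readouts between family members.

## 6. Synthetic data generator

The generator produces a complete input bundle (GTF, poly(A) BED,
per-replicate bedGraphs, DE table, miRNA counts) with known truth, at
the density level:

* 3′UTR lengths log-normal (μ = 6.6, σ = 0.5 in log-space), truncated
  to [200, 3000] nt; the aUTR fraction Beta(2,2) with the proximal CPS
  kept ≥ 60 nt from either UTR end.
* Gene expression log-normal with mean 50 RPM-equivalents per cUTR base
  (σ = 0.5), i.e. ~50× coverage; condition-A PDUI Beta(2,2) clipped to
  [0.01, 0.99].
* By default 240 genes are shortened and 10 lengthened in condition B,
  with |ΔPDUI| uniform in [0.25, 0.5]; events are assigned only to
  genes with enough PDUI headroom so truth labels always correspond to
  realisable shifts. The 24:1 default asymmetry is the generator's
  model of a strongly shortening biological transition.
* Expected per-base density (cUTR level, aUTR level = PDUI × cUTR
  level) is smoothed with a 25-nt moving average to emulate fragment
  edges, then Poisson-sampled per base and replicate (3 replicates).
* Expression is coupled to APA: shortened genes get +1 log2FC in the
  DE table, lengthened genes −1, background N(0, 0.2) — emulating the
  association between 3′UTR shortening and up-regulation.
* The miRNA table places configured abundance ratios (miR-29a-3p :
  miR-29c-3p = 8, : miR-29b-3p = 34, : miR-6980-5p = 2500; 29a anchored
  at 20 000 CPM) by propagating the ratio graph and multinomial
  sampling, rejecting inconsistent ratio sets.

It does **not** emulate: read mappability or alignment artefacts,
internal priming, fragment-length distributions beyond the smoothing
window, GC or positional bias, overlapping genes, >2 poly(A) sites per
gene, or intronic APA coverage. Estimator error measured on this
generator is therefore a lower bound on real-data error.

All outputs derive from a single seeded generator, so a given
(parameters, seed) pair yields byte-identical files.

## 7. Pipeline defaults

| parameter | default | rationale |
|---|---|---|
| `alpha` | 0.05 | conventional FDR level |
| `delta` | 0.2 | ≥20% PDUI change; below this, calls are dominated by density-ratio noise |
| `eps` | 0.01 | PDUI floor; matches the group-7 "exclusive proximal" boundary |
| `pc` | 1.0 | RED pseudocount; keeps zero-count regions finite |
| `min_coverage` | 5.0 | mean cUTR counts required in every replicate of both conditions; below this PDUI variance is large |
| `min_utr_len` | 150 | shorter UTRs leave no room for a reliable cUTR/aUTR split |
| `grid_step` / `margin` / `min_step` | 10 / 50 / 2.0 | change-point grid resolution, end exclusion and minimal usable step |
| `criterion` | `absolute` | absolute ΔPDUI effect size |
| `mode` | `annotated_pa` | use the poly(A) BED; `denovo_cps` fits the breakpoint |
| `n_bins` | 5 | length-trend bins |

Output TSVs carry a three-line metadata header (package version, config
SHA-256, seed) so identical configuration and seed reproduce results
byte-for-byte.

## 8. Limitations

* PDUI is a coverage-ratio estimator; systematic within-UTR coverage
  non-uniformity (bias toward the 3′ end, internal priming) biases it.
* Pooling replicates before the Fisher test treats reads, not
  replicates, as the sampling unit; with few replicates and strong
  biological variability the test is anti-conservative. The coverage
  filter and the ΔPDUI effect-size requirement mitigate but do not
  remove this.
* The asymptotic K-S p-value is approximate for small classes.
* The two-site model aggregates genes with >2 CPSs into one proximal /
  distal split.
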