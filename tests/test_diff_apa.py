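import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from apashift import (
    bh_adjust,
    bin_by_length,
    build_diff_table,
    classify_events,
    method_concordance,
    pdui_log2fc,
    red,
    shortening_ratio,
    test_apa_change as fisher_apa_p,
)


class TestPduiLog2fc:
    def test_halving(self):
        assert pdui_log2fc(0.5, 0.25, eps=0.01) == pytest.approx(-1.0)

    def test_identity(self):
        assert pdui_log2fc(0.37, 0.37, eps=0.001) == 0.0

    def test_floor_applied_before_log(self):
        assert pdui_log2fc(0.5, 0.0, eps=0.01) == pytest.approx(
            math.log2(0.01 / 0.5)
        )

    def test_bad_eps_rejected(self):
        with pytest.raises(ValueError):
            pdui_log2fc(0.5, 0.5, eps=0.0)


class TestRed:
    def test_ratio_shift(self):
        assert red(10, 40, 40, 40, pc=0) == pytest.approx(2.0)

    def test_identical_conditions(self):
        assert red(7, 21, 7, 21, pc=1) == 0.0

    def test_pseudocount_arithmetic(self):
        assert red(15, 15, 3, 15, pc=1) == pytest.approx(-2.0)

    def test_zero_count_without_pseudocount_rejected(self):
        with pytest.raises(ZeroDivisionError):
            red(0, 10, 5, 10, pc=0)


def naive_fisher_two_sided(a, b, c, d):
    """Full hypergeometric enumeration over the fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values()
                        if p <= p_obs * (1 + 1e-7)))


class TestFisherExact:
    def test_no_association(self):
        assert fisher_apa_p(5, 5, 5, 5) == 1.0

    def test_perfect_association(self):
        # [[0,10],[10,0]]: only the two extreme tables are as improbable
        assert fisher_apa_p(0, 10, 10, 0) == pytest.approx(
            2 / 184756, rel=1e-9
        )

    def test_zero_margin_table_returns_one(self):
        assert fisher_apa_p(0, 0, 3, 7) == 1.0

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_apa_p(1.5, 2, 3, 4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            assert fisher_apa_p(a, b, c, d) == pytest.approx(
                naive_fisher_two_sided(a, b, c, d), rel=1e-6, abs=1e-12
            )

    def test_matches_scipy_on_large_tables(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(100, 5000, 4)
            assert fisher_apa_p(*t) == pytest.approx(
                fisher_exact([[t[0], t[1]], [t[2], t[3]]])[1],
                rel=1e-6, abs=1e-12,
            )


def naive_bh(pvals):
    """O(m^2) Benjamini-Hochberg reference."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestBhAdjust:
    def test_closed_form(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 300)
        assert np.allclose(bh_adjust(p), naive_bh(list(p)), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 100)
        assert np.all(bh_adjust(p) >= p - 1e-15)


def _records(rows):
    return pd.DataFrame(rows)


class TestClassifyEvents:
    def _base(self, padj, pa, pb):
        return _records([{"gene_id": "g", "pdui_a": pa, "pdui_b": pb,
                          "pdui_log2fc": 0.0, "red": 0.0, "p": padj,
                          "padj": padj}])

    @pytest.mark.parametrize("padj,pa,pb,expected", [
        (0.01, 0.8, 0.5, "shortened"),
        (0.01, 0.4, 0.7, "lengthened"),
        (0.2, 0.8, 0.5, "nochange"),
        (0.01, 0.8, 0.7, "nochange"),  # below the 20% change threshold
    ])
    def test_dual_criterion(self, padj, pa, pb, expected):
        out = classify_events(self._base(padj, pa, pb))
        assert out["event"].iloc[0] == expected

    def test_relative_criterion_uses_isoform_ratio(self):
        # PDUI 0.50 -> 0.55: |dPDUI| = 0.05 (absolute: nochange) but the
        # long/short odds rise 1.0 -> 1.22, a 22% relative change
        out_abs = classify_events(self._base(0.001, 0.50, 0.55))
        out_rel = classify_events(self._base(0.001, 0.50, 0.55),
                                  criterion="relative")
        assert out_abs["event"].iloc[0] == "nochange"
        assert out_rel["event"].iloc[0] == "lengthened"

    def test_events_partition_gene_set(self):
        rng = np.random.default_rng(5)
        n = 200
        df = _records([
            {"gene_id": f"g{i}", "pdui_a": rng.uniform(0, 1),
             "pdui_b": rng.uniform(0, 1), "padj": rng.uniform(0, 1)}
            for i in range(n)
        ])
        out = classify_events(df)
        counts = out["event"].value_counts()
        assert counts.sum() == n


class TestShorteningRatio:
    def _labelled(self, n_short, n_long, n_none=5):
        rows = (
            [{"gene_id": f"s{i}", "event": "shortened"} for i in range(n_short)]
            + [{"gene_id": f"l{i}", "event": "lengthened"} for i in range(n_long)]
            + [{"gene_id": f"n{i}", "event": "nochange"} for i in range(n_none)]
        )
        return _records(rows)

    def test_headline_fold(self):
        assert shortening_ratio(self._labelled(240, 10)) == pytest.approx(24.0)

    def test_zero_shortened(self):
        assert shortening_ratio(self._labelled(0, 5)) == 0.0

    def test_no_lengthened_is_infinite(self):
        assert math.isinf(shortening_ratio(self._labelled(3, 0)))


class TestBinByLength:
    def _recs(self, n, l2fc=None):
        return _records([
            {"gene_id": f"g{i:03d}",
             "pdui_log2fc": (l2fc[i] if l2fc is not None else 0.0)}
            for i in range(n)
        ])

    def test_even_split(self):
        lengths = {f"g{i:03d}": 100 * (i + 1) for i in range(10)}
        bins = bin_by_length(self._recs(10), lengths, n_bins=5)
        assert bins["n_genes"].tolist() == [2, 2, 2, 2, 2]

    def test_remainder_goes_to_early_bins(self):
        lengths = {f"g{i:03d}": 100 * (i + 1) for i in range(11)}
        bins = bin_by_length(self._recs(11), lengths, n_bins=5)
        assert bins["n_genes"].tolist() == [3, 2, 2, 2, 2]

    def test_trend_recovered_when_shift_grows_with_length(self):
        # shortening magnitude increasing in length -> decreasing bin means
        n = 50
        lengths = {f"g{i:03d}": 200 + 10 * i for i in range(n)}
        l2fc = [-0.01 * i for i in range(n)]
        bins = bin_by_length(self._recs(n, l2fc), lengths, n_bins=5)
        means = bins["mean_pdui_log2fc"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_ties_broken_by_gene_id(self):
        lengths = {f"g{i:03d}": 500 for i in range(4)}
        bins = bin_by_length(self._recs(4), lengths, n_bins=2)
        assert bins["n_genes"].tolist() == [2, 2]

    def test_more_bins_than_genes_rejected(self):
        with pytest.raises(ValueError):
            bin_by_length(self._recs(3), {f"g{i:03d}": 1 for i in range(3)},
                          n_bins=5)


class TestMethodConcordance:
    def test_identical_statistics_give_r_one(self):
        vals = [-1.0, -0.5, 0.2, 0.8]
        df = _records([
            {"gene_id": f"g{i}", "pdui_log2fc": v, "red": v,
             "event": "nochange"}
            for i, v in enumerate(vals)
        ])
        out = method_concordance(df)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["sign_agreement"] == 1.0

    def test_too_few_genes_rejected(self):
        df = _records([{"gene_id": "g", "pdui_log2fc": 1.0, "red": 1.0,
                        "event": "nochange"}])
        with pytest.raises(ValueError):
            method_concordance(df)


class TestBuildDiffTable:
    def _quant(self, gene_ids, pduis, autr, cutr):
        return pd.DataFrame({
            "gene_id": gene_ids,
            "pdui": pduis,
            "quantifiable": True,
            "autr_counts": autr,
            "cutr_counts": cutr,
            "cutr_len": 100,
            "autr_len": 100,
        })

    def test_gene_set_mismatch_is_error(self):
        qa = self._quant(["g1", "g2"], [0.5, 0.5], [50, 50], [100, 100])
        qb = self._quant(["g1", "g3"], [0.5, 0.5], [50, 50], [100, 100])
        with pytest.raises(ValueError, match="g2"):
            build_diff_table(qa, qb)

    def test_signs_agree_on_clean_shift(self):
        # equal-length cUTR/aUTR: PDUI and read-ratio views must both
        # flag the same direction
        qa = self._quant(["g1"], [0.8], [8000], [10000])
        qb = self._quant(["g1"], [0.2], [2000], [10000])
        out = build_diff_table(qa, qb)
        assert out["pdui_log2fc"].iloc[0] < 0
        assert out["red"].iloc[0] < 0
        assert out["event"].iloc[0] == "shortened"
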