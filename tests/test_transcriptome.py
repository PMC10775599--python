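"""DEG filtering, Venn partitioning, concordance and enrichment."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acidflux import transcriptome as tx


def deg_table(rows):
    """rows: (gene_id, log2fc, fdr, fpm_a, fpm_b)"""
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr", "fpm_ctrl", "fpm_trt"])


class TestComputeFpm:
    def test_basic_scaling(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [5, 5]}, index=["g1", "g2"])
        fpm, _ = tx.compute_fpm(counts, {"s1": 1e6, "s2": 1e6})
        assert fpm.loc["g1", "s1"] == pytest.approx(10.0)
        assert fpm.loc["g2", "s1"] == 0.0

    def test_default_library_sizes_normalize_columns_to_1e6(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (40, 4)),
                              columns=list("abcd"))
        fpm, _ = tx.compute_fpm(counts)
        np.testing.assert_allclose(fpm.sum(axis=0), 1e6)

    def test_group_means(self):
        counts = pd.DataFrame({"s1": [10], "s2": [30]}, index=["g1"])
        _, means = tx.compute_fpm(counts, {"s1": 1e6, "s2": 1e6},
                                  groups={"s1": "ctrl", "s2": "ctrl"})
        assert means.loc["g1", "ctrl"] == pytest.approx(20.0)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [10]})
        with pytest.raises(ValueError, match="library size"):
            tx.compute_fpm(counts, {"s1": 0.0})


class TestFilterDegs:
    def test_boundary_inclusive_fc_and_fdr_strict_fpm(self):
        table = deg_table([
            ("keep", 0.59, 0.05, 6.0, 1.0),      # on both inclusive bounds
            ("low_fc", 0.58, 0.01, 100.0, 100.0),
            ("fpm_at_5", 2.0, 0.001, 5.0, 5.0),  # needs strictly > 5
        ])
        kept = set(tx.filter_degs(table)["gene_id"])
        assert kept == {"keep"}

    def test_negative_fc_symmetric(self):
        table = deg_table([("dn", -0.59, 0.05, 10.0, 10.0)])
        assert set(tx.filter_degs(table)["gene_id"]) == {"dn"}

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="fdr"):
            tx.filter_degs(pd.DataFrame({"gene_id": [], "log2fc": [], "fpm_x": []}))
        with pytest.raises(KeyError, match="fpm"):
            tx.filter_degs(pd.DataFrame({"gene_id": [], "log2fc": [], "fdr": []}))

    @given(
        fc=st.floats(0.0, 2.0), fdr=st.floats(0.001, 1.0), fpm=st.floats(0.1, 50.0)
    )
    def test_monotone_in_thresholds(self, fc, fdr, fpm):
        """Relaxing any threshold never removes a retained gene."""
        rng = np.random.default_rng(12)
        table = deg_table([
            (f"g{i}", rng.normal(0, 1), rng.uniform(0, 1),
             rng.uniform(0, 40), rng.uniform(0, 40))
            for i in range(60)
        ])
        strict = set(tx.filter_degs(table, fc, fdr, fpm)["gene_id"])
        relaxed = set(
            tx.filter_degs(table, fc * 0.5, min(1.0, fdr * 2), fpm * 0.5)["gene_id"]
        )
        assert strict <= relaxed


def brute_force_regions(a, b, c, labels):
    """Oracle: enumerate each gene's membership pattern directly."""
    sets = dict(zip(labels, (set(a), set(b), set(c))))
    regions = {}
    for r in (1, 2, 3):
        for inside in combinations(labels, r):
            regions[frozenset(inside)] = {
                g
                for g in set().union(*sets.values())
                if all(g in sets[l] for l in inside)
                and not any(g in sets[l] for l in set(labels) - set(inside))
            }
    return regions


class TestVennPartition:
    def test_printed_margin(self):
        """A contrast of 492 genes sharing 433 with a second one leaves 59
        specific genes."""
        shared = {f"s{i}" for i in range(433)}
        hcl = shared | {f"h{i}" for i in range(59)}
        la = shared | {f"l{i}" for i in range(1212)}
        lactate = {f"n{i}" for i in range(15)}
        venn = tx.venn_partition(hcl, la, lactate)
        assert len(venn.specific("HCl")) == 59
        assert venn.total("HCl") == 492
        assert venn.counts()[frozenset({"HCl", "LA"})] == 433

    def test_empty_sets(self):
        venn = tx.venn_partition(set(), set(), set())
        assert all(len(g) == 0 for g in venn.regions.values())

    @given(
        a=st.sets(st.integers(0, 19), max_size=20),
        b=st.sets(st.integers(0, 19), max_size=20),
        c=st.sets(st.integers(0, 19), max_size=20),
    )
    def test_matches_exhaustive_enumeration(self, a, b, c):
        labels = ("A", "B", "C")
        venn = tx.venn_partition(a, b, c, labels=labels)
        oracle = brute_force_regions(a, b, c, labels)
        assert {k: set(v) for k, v in venn.regions.items()} == oracle
        # regions are disjoint and margins add up
        all_genes = [g for v in venn.regions.values() for g in v]
        assert len(all_genes) == len(set(all_genes))
        for label, s in zip(labels, (a, b, c)):
            assert venn.total(label) == len(s)


def conc_table(pairs):
    return deg_table([
        (f"g{i}", lfc, 0.001, 100.0, 100.0) for i, lfc in enumerate(pairs)
    ])


class TestConcordance:
    def test_identical_tables(self):
        t = conc_table([1.0, -2.0, 0.8])
        res = tx.concordance(t, t)
        assert res.fraction_same_sign == 1.0
        assert res.slope == pytest.approx(1.0)
        assert res.bisector_deviation == pytest.approx(0.0)

    def test_all_signs_flipped(self):
        t = conc_table([1.0, -2.0, 0.8])
        flipped = t.copy()
        flipped["log2fc"] *= -1
        assert tx.concordance(t, flipped).fraction_same_sign == 0.0

    def test_zero_discordant_with_nonzero(self):
        a = conc_table([1.0, 1.0, 1.0, 1.0])
        b = a.copy()
        b.loc[0, "log2fc"] = 0.0
        b_filter_safe = b.copy()
        res = tx.concordance(a, b_filter_safe, universe="union")
        assert res.fraction_same_sign == pytest.approx(0.75)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        a = conc_table(rng.normal(0, 2, 50))
        b = conc_table(rng.normal(0, 2, 50))
        assert (
            tx.concordance(a, b).fraction_same_sign
            == tx.concordance(b, a).fraction_same_sign
        )

    def test_tls_slope_reciprocal_on_collinear_data(self):
        x = np.linspace(-3, 3, 30)
        a = conc_table(x)
        b = conc_table(0.7 * x)
        s_ab = tx.concordance(a, b, slope_method="tls").slope
        s_ba = tx.concordance(b, a, slope_method="tls").slope
        assert s_ab == pytest.approx(0.7, rel=1e-9)
        assert s_ab * s_ba == pytest.approx(1.0, rel=1e-9)

    def test_too_few_shared_genes_rejected(self):
        t = conc_table([1.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            tx.concordance(t, t)


def hypergeom_oracle(k, M, K, n):
    """Exact upper tail by enumeration over all draw outcomes (Fractions)."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(M - K, n - j), comb(M, n))
    return float(total)


class TestEnrich:
    def test_worked_formula_example(self):
        """query 100, intersection 10, term 200, domain 20000 -> E = 10."""
        domain = [f"g{i}" for i in range(20000)]
        term = set(domain[:200])
        query = set(domain[:10]) | {f"g{i}" for i in range(19000, 19090)}
        results = tx.enrich(query, {"T": term}, domain_size=20000, return_all=True)
        (r,) = results
        assert r.intersection_size == 10 and r.query_size == 100
        assert r.E == pytest.approx(10.0)

    def test_size_window_excludes_terms(self):
        query = {"a", "b", "c", "d", "e"}
        terms = {"tiny": ["a", "b", "c", "d"], "ok": ["a", "b", "c", "d", "e"]}
        results = tx.enrich(query, terms, domain_size=100, return_all=True)
        assert [r.term_id for r in results] == ["ok"]
        big = {"huge": [f"g{i}" for i in range(50)]}
        assert tx.enrich(query, big, domain_size=100, max_term=40, return_all=True) == []

    def test_hypergeometric_matches_combinatorial_oracle(self):
        """Small domain (50): scipy tail equals exact enumeration to 1e-10."""
        domain = 50
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(domain)]
        for _ in range(10):
            term = set(rng.choice(genes, size=rng.integers(5, 20), replace=False))
            query = set(rng.choice(genes, size=rng.integers(5, 20), replace=False))
            (r,) = tx.enrich(query, {"T": term}, domain_size=domain, return_all=True)
            oracle = hypergeom_oracle(r.intersection_size, domain, r.term_size, r.query_size)
            assert r.p_hyper == pytest.approx(oracle, abs=1e-10)

    def test_e_scale_invariance(self):
        """Doubling query, intersection, term and domain together leaves E fixed."""
        domain = [f"g{i}" for i in range(1000)]
        term = set(domain[:50])
        query = set(domain[:5]) | set(domain[500:545])
        (r1,) = tx.enrich(query, {"T": term}, domain_size=1000, return_all=True)
        domain2 = [f"g{i}" for i in range(2000)]
        term2 = set(domain2[:100])
        query2 = set(domain2[:10]) | set(domain2[500:590])
        (r2,) = tx.enrich(query2, {"T": term2}, domain_size=2000, return_all=True)
        assert r1.E == pytest.approx(r2.E)

    def test_threshold_contract(self):
        """Returned terms all satisfy the adjusted-p and E gates."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(2000)]
        query = set(genes[:100])
        terms = {"enr": genes[:60] + genes[1000:1040]}
        for i in range(20):
            terms[f"null{i}"] = list(rng.choice(genes, size=80, replace=False))
        results = tx.enrich(query, terms, domain_size=2000)
        assert any(r.term_id == "enr" for r in results)
        for r in results:
            assert r.p_adjusted <= 0.001 and r.E >= 2.5

    def test_empty_query_and_small_domain_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            tx.enrich(set(), {"T": ["a"]}, domain_size=10)
        with pytest.raises(ValueError, match="domain"):
            tx.enrich({"a"}, {"T": [f"g{i}" for i in range(30)]}, domain_size=20)


class TestGmtRoundTrip:
    def test_write_then_read(self, tmp_path):
        collection = {"T1": ["a", "b", "c"], "T2": ["d", "e"]}
        path = tmp_path / "sets.gmt"
        tx.write_gmt(collection, path)
        assert tx.read_gmt(path) == collection
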