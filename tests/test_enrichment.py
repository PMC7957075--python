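"""Overlap matrix, stratum-matched resampling, permutation p-values, BH, and
the co-overlap listing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bernoulli_binding, matched_pool, toy_bins
from m6arbp import enrichment
from m6arbp.core import (
    EXONIC,
    JUNCTION,
    BindingMatrix,
    ControlPool,
    EnrichmentResult,
    GenomicBin,
    InputError,
    ParameterError,
)


def sites_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rbp"]).assign(
        score=0, strand="."
    )


class TestOverlapMatrix:
    def test_one_bp_overlap_counts(self):
        regions = [
            GenomicBin("r", "chr1", 1000, 1200, "g", EXONIC, ((1000, 1200),))
        ]
        bm = enrichment.overlap_matrix(regions, sites_frame([("chr1", 1199, 1220, "A")]))
        assert bm.bound[0, 0] == 1

    def test_half_open_abutment_does_not_count(self):
        regions = [
            GenomicBin("r", "chr1", 1000, 1200, "g", EXONIC, ((1000, 1200),))
        ]
        bm = enrichment.overlap_matrix(regions, sites_frame([("chr1", 1200, 1220, "A")]))
        assert bm.bound[0, 0] == 0

    def test_junction_intron_gap_not_bound(self):
        # a site entirely inside the intron touches the span but no fragment
        regions = [
            GenomicBin("r", "chr1", 0, 550, "g", JUNCTION, ((0, 150), (500, 550)))
        ]
        bm = enrichment.overlap_matrix(
            regions, sites_frame([("chr1", 200, 400, "A"), ("chr1", 100, 160, "B")])
        )
        assert bm.bound[0].tolist() == [0, 1]  # A intronic, B hits fragment 1

    def test_malformed_interval_raises(self):
        regions = toy_bins(1)
        with pytest.raises(InputError, match="end <= start"):
            enrichment.overlap_matrix(regions, sites_frame([("chrS", 100, 100, "A")]))

    def test_random_instance_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        regions = []
        for i in range(40):
            start = int(rng.integers(0, 5000))
            if rng.random() < 0.3:
                frags = ((start, start + 80), (start + 200, start + 320))
                regions.append(
                    GenomicBin(f"r{i}", "chr1", frags[0][0], frags[1][1], "g",
                               JUNCTION, frags)
                )
            else:
                regions.append(
                    GenomicBin(f"r{i}", "chr1", start, start + 200, "g", EXONIC,
                               ((start, start + 200),))
                )
        rows = []
        for j in range(120):
            s = int(rng.integers(0, 5200))
            rows.append(("chr1", s, s + int(rng.integers(1, 120)), f"P{j % 7}"))
        sites = sites_frame(rows)
        bm = enrichment.overlap_matrix(regions, sites)
        # brute force: all pairs, >=1 bp against any fragment
        expected = np.zeros_like(bm.bound)
        for i, reg in enumerate(regions):
            for _, site in sites.iterrows():
                hit = any(
                    max(fs, site["start"]) < min(fe, site["end"])
                    for fs, fe in reg.fragments
                )
                if hit:
                    expected[i, list(bm.rbps).index(site["rbp"])] = 1
        assert np.array_equal(bm.bound, expected)


class TestControlPool:
    def test_pool_excludes_m6a_and_restricts_to_m6a_genes(self):
        bins = toy_bins(30, gene_size=10)  # genes g0, g1, g2
        m6a = [b for b in bins if b.gene_id in ("g0", "g1")][:5]
        pool = enrichment.build_control_pool(bins, m6a)
        ids = {b.bin_id for b in pool.regions}
        assert ids.isdisjoint({b.bin_id for b in m6a})
        assert all(b.gene_id in ("g0", "g1") for b in pool.regions)
        assert pool.required == {EXONIC: 5}

    def test_matched_counts_per_stratum(self):
        strata = [EXONIC] * 80 + [JUNCTION] * 40
        pool = matched_pool(toy_bins(120, stratum=strata), {EXONIC: 20, JUNCTION: 8})
        sets = enrichment.sample_matched_control(pool, n_perm=25, seed=1)
        for idx in sets:
            assert len(idx) == 28
            drawn = [pool.regions[i].stratum for i in idx]
            assert drawn.count(EXONIC) == 20 and drawn.count(JUNCTION) == 8
            assert len(set(idx)) == len(idx)  # without replacement

    def test_pool_equal_to_required_returns_whole_pool(self):
        pool = matched_pool(toy_bins(6), {EXONIC: 6})
        for idx in enrichment.sample_matched_control(pool, n_perm=5, seed=0):
            assert sorted(idx) == list(range(6))

    def test_deficient_stratum_raises_named_error(self):
        pool = matched_pool(toy_bins(4), {EXONIC: 3, JUNCTION: 2})
        with pytest.raises(ParameterError, match="junction"):
            enrichment.sample_matched_control(pool, n_perm=2, seed=0)

    def test_deterministic_sequence(self):
        pool = matched_pool(toy_bins(50), {EXONIC: 10})
        a = enrichment.sample_matched_control(pool, n_perm=10, seed=9)
        b = enrichment.sample_matched_control(pool, n_perm=10, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestEnrichmentTest:
    def test_ratio_and_inclusive_p(self):
        # pool == required, so every control set is the whole pool: E(Nc) exact
        pool = matched_pool(toy_bins(4), {EXONIC: 4})
        bm_pool = BindingMatrix(pool.regions, ["A"], np.array([[1], [1], [0], [0]]))
        m6a = toy_bins(3)
        bm_m6a = BindingMatrix(m6a, ["A"], np.array([[1], [1], [0]]))
        res = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=10, seed=0)[0]
        assert res.n_t == 2 and res.e_nc == 2.0
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value == 1.0  # Nc == Nt counts as extreme (inclusive)

    def test_infinite_and_undefined_ratio_flags(self):
        pool = matched_pool(toy_bins(3), {EXONIC: 3})
        bm_pool = BindingMatrix(pool.regions, ["A", "B"], np.zeros((3, 2), dtype=int))
        m6a = toy_bins(2)
        bm_m6a = BindingMatrix(m6a, ["A", "B"], np.array([[1, 0], [0, 0]]))
        res = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=5, seed=0)
        by = {r.rbp: r for r in res}
        assert math.isinf(by["A"].ratio) and by["A"].ratio_flag == "infinite"
        assert math.isnan(by["B"].ratio) and by["B"].ratio_flag == "undefined"
        assert by["B"].p_value == 1.0

    def test_pseudo_count_option(self):
        pool = matched_pool(toy_bins(4), {EXONIC: 4})
        bm_pool = BindingMatrix(pool.regions, ["A"], np.array([[1], [1], [0], [0]]))
        bm_m6a = BindingMatrix(toy_bins(2), ["A"], np.array([[1], [1]]))
        raw = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=10, seed=0)[0]
        ps = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=10, seed=0,
                                        pseudo=True)[0]
        assert raw.p_value == 1.0 and ps.p_value == pytest.approx(11 / 11)

    def test_deterministic_bit_for_bit(self):
        strata = [EXONIC] * 150 + [JUNCTION] * 50
        bm_pool = bernoulli_binding(200, [("A", 0.3), ("B", 0.4)], seed=2, strata=strata)
        pool = ControlPool(bm_pool.regions, {EXONIC: 30, JUNCTION: 10})
        bm_m6a = bernoulli_binding(40, [("A", 0.5), ("B", 0.4)], seed=3,
                                   strata=[EXONIC] * 30 + [JUNCTION] * 10)
        r1 = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=200, seed=7)
        r2 = enrichment.enrichment_test(bm_m6a, bm_pool, pool, n_perm=200, seed=7)
        assert r1 == r2

    def test_p_display_formats_zero_as_resolution_bound(self):
        res = [EnrichmentResult("A", 5, 1.0, 5.0, 0.0, 0.01, 1000)]
        frame = enrichment.results_to_frame(res)
        assert frame.loc[0, "p_display"] == "<0.001"
        assert frame.loc[0, "p_value"] == 0.0


def bh_oracle(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_step_up_arithmetic(self):
        q = enrichment.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert enrichment.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            enrichment.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=40)
    )
    def test_matches_independent_step_up_oracle(self, p):
        assert np.allclose(enrichment.bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestFilterAndCoOverlap:
    def test_threshold_boundaries_inclusive(self):
        res = [
            EnrichmentResult("keep", 10, 5.0, 1.31, 0.001, 0.04, 1000),
            EnrichmentResult("dropR", 10, 8.0, 1.29, 0.0, 0.001, 1000),
            EnrichmentResult("edge", 10, 5.0, 1.30, 0.001, 0.05, 1000),
            EnrichmentResult("dropQ", 10, 2.0, 5.0, 0.2, 0.3, 1000),
        ]
        kept = enrichment.filter_enriched(res)
        assert [r.rbp for r in kept] == ["keep", "edge"]  # ranked by R desc

    def test_empty_input(self):
        assert enrichment.filter_enriched([]) == []

    def test_fraction_and_strict_min_regions(self):
        rng = np.random.default_rng(1)
        n = 300
        a = np.zeros(n, dtype=int)
        a[:200] = 1  # A bound in 200 regions
        b = np.zeros(n, dtype=int)
        b[:150] = 1  # B covers 150 of A's 200 -> 0.75
        c = np.zeros(n, dtype=int)
        c[:100] = 1  # C has N_t = 100: excluded as a row ("more than 100" strict)
        bm = BindingMatrix(toy_bins(n), ["A", "B", "C"], np.column_stack([a, b, c]))
        tab = enrichment.co_overlap_table(bm, ["A", "C"], min_regions=100, frac=0.6)
        assert set(tab["rbp_a"]) == {"A"}
        row = tab[(tab.rbp_a == "A") & (tab.rbp_b == "B")].iloc[0]
        assert row["fraction"] == pytest.approx(0.75)
        assert not ((tab.rbp_a == tab.rbp_b).any())  # self-pairs suppressed

    def test_unknown_enriched_name_raises(self):
        bm = BindingMatrix(toy_bins(3), ["A"], np.ones((3, 1), dtype=int))
        with pytest.raises(InputError):
            enrichment.co_overlap_table(bm, ["NOPE"])
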