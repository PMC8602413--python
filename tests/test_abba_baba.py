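import numpy as np
import pandas as pd
import pytest

from introscan.abba_baba import (call_introgressed_tracts, f3_statistic,
                                 fdr_bh, genome_wide_d, merge_intervals,
                                 site_patterns, weighted_block_jackknife,
                                 window_fd_scan)
from introscan.genotype_io import (FrequencyTable, make_windows)


def freq_table(freqs_by_pop, n_per_pop=20, positions=None, chrom="chr1",
               usable=None):
    """FrequencyTable straight from per-population frequency vectors."""
    pops = list(freqs_by_pop)
    f = np.array([freqs_by_pop[p] for p in pops], dtype=np.float64)
    s = f.shape[1]
    pos = np.asarray(positions if positions is not None
                     else np.arange(s) * 10, dtype=np.int64)
    n = np.full(f.shape, 2 * n_per_pop, dtype=np.int32)
    u = np.ones(s, bool) if usable is None else np.asarray(usable, bool)
    return FrequencyTable(np.full(s, chrom, object), pos, pops, f, n, u,
                          np.ones(s, bool))


QUARTET = ("P1", "P2", "P3", "O")


def quartet_table(p1, p2, p3, **kw):
    z = np.zeros(len(np.atleast_1d(p1)))
    return freq_table({"P1": np.atleast_1d(p1), "P2": np.atleast_1d(p2),
                       "P3": np.atleast_1d(p3), "O": z}, **kw)


class TestSitePatterns:
    def test_perfect_abba(self):
        s = site_patterns(quartet_table([0.0], [1.0], [1.0]), QUARTET)
        assert s.abba[0] == 1.0 and s.baba[0] == 0.0

    def test_perfect_baba(self):
        s = site_patterns(quartet_table([1.0], [0.0], [1.0]), QUARTET)
        assert s.abba[0] == 0.0 and s.baba[0] == 1.0

    def test_matches_per_site_enumeration(self, rng):
        p1, p2, p3 = rng.random((3, 50))
        s = site_patterns(quartet_table(p1, p2, p3), QUARTET)
        for i in range(50):
            assert s.abba[i] == pytest.approx((1 - p1[i]) * p2[i] * p3[i],
                                              rel=1e-12)
            assert s.baba[i] == pytest.approx(p1[i] * (1 - p2[i]) * p3[i],
                                              rel=1e-12)
            pd_ = max(p2[i], p3[i])
            assert s.abba_donor[i] == pytest.approx(
                (1 - p1[i]) * pd_ * pd_, rel=1e-12)

    def test_unusable_sites_skipped(self):
        ft = quartet_table([0, 0], [1, 1], [1, 1], usable=[True, False])
        assert site_patterns(ft, QUARTET).n_sites == 1


class TestGenomeWideD:
    def test_all_abba_gives_one(self):
        ft = quartet_table(np.zeros(30), np.ones(30), np.ones(30))
        d = genome_wide_d(site_patterns(ft, QUARTET), block_size=10)
        assert d.statistic == 1.0

    def test_sign_flips_when_p1_p2_swapped(self, rng):
        p1, p2, p3 = rng.random((3, 200))
        a = genome_wide_d(site_patterns(quartet_table(p1, p2, p3), QUARTET),
                          block_size=100)
        b = genome_wide_d(site_patterns(quartet_table(p2, p1, p3), QUARTET),
                          block_size=100)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)

    def test_constant_blocks_zero_se(self):
        # 30 identical blocks of one perfect-ABBA + one perfect-BABA site
        p1 = np.tile([0.0, 1.0], 30)
        p2 = 1 - p1
        p3 = np.ones(60)
        ft = quartet_table(p1, p2, p3, positions=np.arange(60) * 10)
        d = genome_wide_d(site_patterns(ft, QUARTET), block_size=20)
        assert d.n_blocks == 30
        assert d.statistic == 0.0
        assert d.se == 0.0

    def test_empty_block_invariance(self):
        ft = quartet_table([0.2, 0.4], [0.9, 0.8], [0.9, 0.7],
                           positions=[5, 5_000_005])
        d_gap = genome_wide_d(site_patterns(ft, QUARTET))
        ft2 = quartet_table([0.2, 0.4], [0.9, 0.8], [0.9, 0.7],
                            positions=[5, 1_000_005])
        d_near = genome_wide_d(site_patterns(ft2, QUARTET))
        assert d_gap.statistic == pytest.approx(d_near.statistic)
        assert d_gap.n_blocks == d_near.n_blocks == 2

    def test_jackknife_equal_weights_closed_form(self, rng):
        # with equal weights the weighted formula reduces to the classic
        # delete-one jackknife variance of a ratio
        num = rng.random(25)
        den = rng.random(25) + 1.0
        w = np.full(25, 4.0)
        theta, se = weighted_block_jackknife(num, den, w)
        loo = np.array([(num.sum() - num[j]) / (den.sum() - den[j])
                        for j in range(25)])
        pseudo = 25 * theta - 24 * loo
        var = np.sum((pseudo - pseudo.mean()) ** 2) / (24 * 25)
        assert se == pytest.approx(np.sqrt(var), rel=1e-10)


class TestF3:
    def test_target_equals_source_matches_per_site_oracle(self, rng):
        p = rng.random(100)
        pb = rng.random(100)
        n_dip = 10
        ft = freq_table({"C": p, "A": p, "B": pb, "O": np.zeros(100)},
                        n_per_pop=n_dip)
        res = f3_statistic(ft, "C", "A", "B", block_size=200)
        expected = np.mean(-p * (1 - p) / (2 * n_dip - 1))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert expected <= 0

    def test_admixed_target_significantly_negative(self, rng):
        # C is a 50/50 frequency mixture of two diverged sources
        n_sites = 20_000
        anc = rng.beta(0.8, 0.8, n_sites)
        f = 0.3
        c_ = (1 - f) / f
        pa = rng.beta(anc * c_ + 1e-9, (1 - anc) * c_ + 1e-9)
        pb = rng.beta(anc * c_ + 1e-9, (1 - anc) * c_ + 1e-9)
        pc = 0.5 * pa + 0.5 * pb
        # sampled frequencies from finite panels
        n_dip = 10
        pa_h = rng.binomial(2 * n_dip, pa) / (2 * n_dip)
        pb_h = rng.binomial(2 * n_dip, pb) / (2 * n_dip)
        pc_h = rng.binomial(2 * n_dip, pc) / (2 * n_dip)
        pos = np.sort(rng.choice(20_000_000, n_sites, replace=False))
        ft = freq_table({"C": pc_h, "A": pa_h, "B": pb_h,
                         "O": np.zeros(n_sites)}, n_per_pop=n_dip,
                        positions=pos)
        res = f3_statistic(ft, "C", "A", "B")
        assert res.statistic < 0
        assert res.z < -3

    def test_source_symmetry(self, rng):
        pc, pa, pb = rng.random((3, 60))
        ft = freq_table({"C": pc, "A": pa, "B": pb, "O": np.zeros(60)})
        r1 = f3_statistic(ft, "C", "A", "B", block_size=100)
        r2 = f3_statistic(ft, "C", "B", "A", block_size=100)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)


def brute_bh(p):
    """BH step-up from its definition: q_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestFdrBh:
    def test_all_ones_no_discoveries(self):
        q, rej = fdr_bh(np.ones(10))
        assert not rej.any() and (q == 1).all()

    def test_single_p_identity(self):
        q, rej = fdr_bh([0.01])
        assert q[0] == pytest.approx(0.01) and rej[0]

    def test_matches_step_up_definition(self):
        p = [0.01, 0.02, 0.30, 0.80]
        q, _ = fdr_bh(p)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.40, 0.80], rtol=1e-12)
        np.testing.assert_allclose(q, brute_bh(p), rtol=1e-12)

    def test_matches_step_up_on_random(self, rng):
        p = rng.random(200)
        q, rej = fdr_bh(p, alpha=0.1)
        np.testing.assert_allclose(q, brute_bh(p), rtol=1e-12)
        np.testing.assert_array_equal(rej, q < 0.1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestWindowFdScan:
    def test_complete_sharing_saturates(self, rng):
        # p2 == p3 everywhere, p1 = 0 -> fd = 1 in every defined window
        p23 = rng.uniform(0.3, 0.9, 40)
        ft = quartet_table(np.zeros(40), p23, p23,
                           positions=np.arange(40) * 100)
        grid = make_windows({"chr1": 4000}, 2000, 2000)
        scan = window_fd_scan(ft, grid, QUARTET, min_sites=5)
        assert np.allclose(scan["fd"].dropna(), 1.0)
        assert scan["fd"].notna().all()

    def test_invariant_donor_undefined(self, rng):
        ft = quartet_table(rng.random(40), rng.random(40), np.zeros(40),
                           positions=np.arange(40) * 100)
        grid = make_windows({"chr1": 4000}, 2000, 2000)
        scan = window_fd_scan(ft, grid, QUARTET, min_sites=1)
        assert scan["fd"].isna().all()
        assert (scan["n_sites"] == 0).all()

    def test_min_sites_gate(self, rng):
        p23 = rng.uniform(0.3, 0.9, 4)
        ft = quartet_table(np.zeros(4), p23, p23, positions=[0, 10, 20, 30])
        grid = make_windows({"chr1": 100}, 100, 100)
        assert window_fd_scan(ft, grid, QUARTET,
                              min_sites=5)["fd"].isna().all()
        assert window_fd_scan(ft, grid, QUARTET,
                              min_sites=4)["fd"].notna().all()

    def test_matches_direct_formula_recomputation(self, rng):
        """Every window's D and fd recomputed straight from the formulas."""
        n = 500
        pos = np.sort(rng.choice(100_000, n, replace=False))
        p1, p2, p3 = rng.random((3, n))
        ft = quartet_table(p1, p2, p3, positions=pos)
        grid = make_windows({"chr1": 100_000}, 10_000, 2_000)
        scan = window_fd_scan(ft, grid, QUARTET, min_sites=1)
        for w in range(grid.n_windows):
            s, e = grid.start[w], grid.end[w]
            sel = (pos >= s) & (pos < e)
            abba = ((1 - p1) * p2 * p3)[sel].sum()
            baba = (p1 * (1 - p2) * p3)[sel].sum()
            pd_ = np.maximum(p2, p3)[sel]
            denom = (((1 - p1[sel]) * pd_ * pd_)
                     - (p1[sel] * (1 - pd_) * pd_)).sum()
            if abba + baba > 0:
                assert scan["D"][w] == pytest.approx(
                    (abba - baba) / (abba + baba), rel=1e-9)
            d = scan["D"][w]
            if (d > 0 and denom > 0 and sel.sum() >= 1
                    and not grid.partial[w]):
                assert scan["fd"][w] == pytest.approx(
                    (abba - baba) / denom, rel=1e-9)
            else:
                assert np.isnan(scan["fd"][w])

    def test_fd_bounded_when_defined(self, rng):
        p1, p2, p3 = rng.random((3, 2000))
        pos = np.sort(rng.choice(400_000, 2000, replace=False))
        ft = quartet_table(p1, p2, p3, positions=pos)
        grid = make_windows({"chr1": 400_000}, 20_000, 5_000)
        fd = window_fd_scan(ft, grid, QUARTET, min_sites=1)["fd"].dropna()
        assert len(fd) > 0
        assert ((fd >= 0) & (fd <= 1 + 1e-12)).all()


def scan_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "D", "fd", "q"])
    df["n_sites"], df["Z"], df["p"] = 10, 1.0, df["q"]
    df["significant"] = (df["D"] > 0) & (df["q"] < 0.05)
    return df


class TestTractCalling:
    def test_overlap_merges(self):
        scan = scan_frame([("chr1", 0, 100_000, 0.5, 0.4, 0.01),
                           ("chr1", 20_000, 120_000, 0.5, 0.6, 0.01)])
        tr = call_introgressed_tracts(scan)
        assert len(tr) == 1
        assert (tr.loc[0, "start"], tr.loc[0, "end"]) == (0, 120_000)
        assert tr.loc[0, "n_windows"] == 2
        assert tr.loc[0, "mean_fd"] == pytest.approx(0.5)
        assert tr.loc[0, "max_fd"] == pytest.approx(0.6)

    def test_gap_preserved(self):
        scan = scan_frame([("chr1", 0, 100_000, 0.5, 0.4, 0.01),
                           ("chr1", 200_000, 300_000, 0.5, 0.4, 0.01)])
        assert len(call_introgressed_tracts(scan)) == 2

    def test_negative_d_and_high_q_excluded(self):
        scan = scan_frame([("chr1", 0, 100_000, -0.5, 0.4, 0.01),
                           ("chr1", 200_000, 300_000, 0.5, 0.4, 0.2)])
        assert call_introgressed_tracts(scan).empty

    def test_output_disjoint_sorted(self, rng):
        rows = [("chr%d" % rng.integers(1, 3), int(s), int(s) + 100_000,
                 0.5, 0.4, 0.01)
                for s in rng.choice(2_000_000, 40, replace=False)]
        tr = call_introgressed_tracts(scan_frame(rows))
        for c in tr["chrom"].unique():
            sub = tr[tr["chrom"] == c]
            assert (sub["start"].to_numpy()[1:]
                    > sub["end"].to_numpy()[:-1]).all()


def brute_union_length(intervals):
    points = set()
    for c, s, e in intervals:
        points.update((c, x) for x in range(s, e))
    return len(points)


def test_merge_intervals_union_oracle(rng):
    iv = [("c1", int(s), int(s) + int(l))
          for s, l in zip(rng.integers(0, 500, 30), rng.integers(1, 80, 30))]
    merged = merge_intervals(np.array([c for c, _, _ in iv], object),
                             np.array([s for _, s, _ in iv]),
                             np.array([e for _, _, e in iv]))
    assert sum(e - s for _, s, e, _ in merged) == brute_union_length(iv)
    assert sum(len(m) for _, _, _, m in merged) == 30
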