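import math

import numpy as np
import pytest

from divscan.allsites import PopulationMap
from divscan.windows import (
    WindowSpec,
    make_windows,
    pearson_correlation,
    region_pi,
    site_counts,
    window_summaries,
    windows_to_dataframe,
)

from conftest import make_site, random_site_records
from oracles import brute_pi_dxy, brute_window_fst, wc_components_site

SAMPLES = ["s1", "s2", "s3", "s4"]


@pytest.fixture
def pm():
    return PopulationMap({"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"})


class TestMakeWindows:
    def test_truncated_last_window(self):
        w = make_windows({"c": 12_000}, 5_000)
        assert [(x.start, x.end) for x in w] == [(0, 5000), (5000, 10000), (10000, 12000)]

    def test_exact_fit(self):
        assert len(make_windows({"c": 5000}, 5000)) == 1

    def test_degenerate_length_one(self):
        (w,) = make_windows({"c": 1}, 5000)
        assert (w.start, w.end) == (0, 1)

    def test_bad_size(self):
        with pytest.raises(ValueError):
            make_windows({"c": 10}, 0)


class TestSiteCounts:
    def test_balanced_within_pop(self, pm):
        # pop1 alleles {A,A,T,T}: 4 differing pairs of 6
        site = make_site(0, [[0, 0], [1, 1], [0, 0], [0, 0]])
        c = site_counts(site, pm, SAMPLES)
        assert c.pi_diffs["p1"] == 4
        assert c.pi_comps["p1"] == 6
        assert c.pi_diffs["p1"] / c.pi_comps["p1"] == pytest.approx(2 / 3)

    def test_fixed_difference(self, pm):
        site = make_site(0, [[0, 0], [0, 0], [1, 1], [1, 1]])
        c = site_counts(site, pm, SAMPLES)
        assert c.dxy_diffs == 16 and c.dxy_comps == 16
        fst = c.wc_a / (c.wc_a + c.wc_b + c.wc_c)
        assert fst == pytest.approx(1.0)

    def test_invariant_site(self):
        pm6 = PopulationMap({f"s{i}": ("p1" if i < 3 else "p2") for i in range(6)})
        site = make_site(0, np.zeros((6, 2)), alts=())
        c = site_counts(site, pm6, [f"s{i}" for i in range(6)])
        assert c.pi_diffs == {"p1": 0, "p2": 0}
        assert c.pi_comps == {"p1": 15, "p2": 15}
        assert c.dxy_comps == 36 and c.dxy_diffs == 0

    def test_single_genotype_pop_contributes_no_fst(self, pm):
        site = make_site(0, [[0, 1], [-1, -1], [0, 1], [1, 1]])
        c = site_counts(site, pm, SAMPLES)
        assert (c.wc_a, c.wc_b, c.wc_c) == (0.0, 0.0, 0.0)
        assert c.pi_comps["p1"] == 1  # one diploid still yields a within-ind pair

    def test_multiallelic_all_zero(self, pm):
        site = make_site(0, [[0, 2], [1, 1], [0, 0], [2, 2]], alts=("T", "G"))
        c = site_counts(site, pm, SAMPLES)
        assert c.pi_comps == {"p1": 0.0, "p2": 0.0} and c.dxy_comps == 0.0


class TestWindowSummaries:
    def test_all_invariant_window(self, pm):
        sites = [make_site(i, np.zeros((4, 2)), alts=()) for i in range(100)]
        (st,) = window_summaries(sites, [WindowSpec("chr1", 0, 100)], pm, SAMPLES)
        assert st.pi["p1"] == 0 and st.pi["p2"] == 0 and st.dxy == 0
        assert math.isnan(st.fst)
        assert st.any_missing
        assert st.n_sites == 100

    def test_fixed_snp_plus_invariants(self, pm):
        sites = [make_site(0, [[0, 0], [0, 0], [1, 1], [1, 1]])]
        sites += [make_site(i, np.zeros((4, 2)), alts=()) for i in range(1, 100)]
        (st,) = window_summaries(sites, [WindowSpec("chr1", 0, 100)], pm, SAMPLES)
        assert st.dxy == pytest.approx(16 / 1600)
        assert st.fst == pytest.approx(1.0)

    def test_unsorted_raises(self, pm):
        sites = [make_site(5, np.zeros((4, 2)), alts=()), make_site(2, np.zeros((4, 2)), alts=())]
        with pytest.raises(ValueError, match="unsorted"):
            window_summaries(sites, [WindowSpec("chr1", 0, 10)], pm, SAMPLES)

    def test_masking_preserves_expectation(self, pm):
        # denominator-aware estimator: masked-data mean stays near full-data pi
        rng = np.random.default_rng(42)
        base = random_site_records(rng, 4, 400, missing_rate=0.0, p_multi=0, p_indel=0)
        win = [WindowSpec("chr1", 0, 400)]
        (full,) = window_summaries(base, win, pm, SAMPLES)
        estimates = []
        for rep in range(60):
            masked = []
            for r in base:
                g = r.genotypes.copy()
                g[rng.random(4) < 0.3] = -1
                masked.append(make_site(r.pos, g, alts=r.alts))
            (st,) = window_summaries(masked, win, pm, SAMPLES)
            estimates.append(st.pi["p1"])
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - full.pi["p1"]) < 3 * se + 1e-12

    def test_ratio_of_sums_not_mean_of_ratios(self, pm):
        # site A: pi=2/3 on 6 comps; site B: pi=0 but only 1 comp (3 missing)
        site_a = make_site(0, [[0, 0], [1, 1], [0, 0], [0, 0]])
        site_b = make_site(1, [[0, 0], [-1, -1], [0, 0], [0, 0]])
        (st,) = window_summaries([site_a, site_b], [WindowSpec("chr1", 0, 2)], pm, SAMPLES)
        ratio_of_sums = (4 + 0) / (6 + 1)
        mean_of_ratios = (4 / 6 + 0 / 1) / 2
        assert st.pi["p1"] == pytest.approx(ratio_of_sums)
        assert st.pi["p1"] != pytest.approx(mean_of_ratios)

    def test_matches_brute_force_oracle(self, pm):
        rng = np.random.default_rng(123)
        sites = random_site_records(rng, 4, 300, missing_rate=0.25)
        windows = [WindowSpec("chr1", 0, 150), WindowSpec("chr1", 150, 300)]
        stats = window_summaries(sites, windows, pm, SAMPLES)
        idx = pm.indices(SAMPLES)
        G = np.stack([s.genotypes for s in sites])
        usable = np.array([s.is_biallelic_snp or s.is_invariant for s in sites])
        for w, st in zip(windows, stats):
            sl = slice(w.start, w.end)
            (d1, c1), (d2, c2), (dx, cx) = brute_pi_dxy(
                G[sl], idx["p1"], idx["p2"], usable[sl]
            )
            assert st.pi_diffs["p1"] == pytest.approx(d1, abs=1e-10)
            assert st.pi_comps["p1"] == pytest.approx(c1, abs=1e-10)
            assert st.pi_diffs["p2"] == pytest.approx(d2, abs=1e-10)
            assert st.dxy_diffs == pytest.approx(dx, abs=1e-10)
            assert st.dxy_comps == pytest.approx(cx, abs=1e-10)
            fst = brute_window_fst(G[sl], idx["p1"], idx["p2"], usable[sl])
            if math.isnan(fst):
                assert math.isnan(st.fst)
            else:
                assert st.fst == pytest.approx(fst, abs=1e-10)

    def test_wc_components_match_oracle_per_site(self, pm):
        rng = np.random.default_rng(5)
        sites = random_site_records(rng, 4, 200, missing_rate=0.3, p_multi=0, p_indel=0)
        idx = pm.indices(SAMPLES)
        for s in sites:
            c = site_counts(s, pm, SAMPLES)
            a, b, cc = wc_components_site([s.genotypes[idx["p1"]], s.genotypes[idx["p2"]]])
            assert c.wc_a == pytest.approx(a, abs=1e-12)
            assert c.wc_b == pytest.approx(b, abs=1e-12)
            assert c.wc_c == pytest.approx(cc, abs=1e-12)


class TestRegionPi:
    def test_cds_738(self, pm):
        sites = []
        seg_positions = {10, 300, 600}
        for i in range(738):
            if i in seg_positions:
                sites.append(make_site(i, [[0, 0], [1, 1], [0, 0], [0, 0]]))
            else:
                sites.append(make_site(i, np.zeros((4, 2)), alts=()))
        intervals = [WindowSpec("chr1", 0, 738, label="gene")]
        # only pop1's two diploids (4 alleles, balanced 2/2 at each SNP)
        out = region_pi(sites, intervals, pm, "p1", SAMPLES)
        assert out["gene"] == pytest.approx((3 * 4) / (738 * 6))

    def test_no_called_sites_undefined(self, pm):
        sites = [make_site(0, -np.ones((4, 2)), alts=())]
        out = region_pi(sites, [WindowSpec("chr1", 0, 1, label="g")], pm, "p1", SAMPLES)
        assert math.isnan(out["g"])

    def test_split_intervals_pool_like_concatenation(self, pm):
        rng = np.random.default_rng(9)
        sites = random_site_records(rng, 4, 100, missing_rate=0.2)
        split = [
            WindowSpec("chr1", 0, 40, label="g"),
            WindowSpec("chr1", 40, 100, label="g"),
        ]
        whole = [WindowSpec("chr1", 0, 100, label="g")]
        a = region_pi(sites, split, pm, "p1", SAMPLES)
        b = region_pi(iter(sites), whole, pm, "p1", SAMPLES)
        assert a["g"] == pytest.approx(b["g"], abs=1e-12)

    def test_empty_intervals_rejected(self, pm):
        with pytest.raises(ValueError):
            region_pi([], [], pm, "p1", SAMPLES)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = pearson_correlation(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


def test_dataframe_schema(pm):
    sites = [make_site(i, np.zeros((4, 2)), alts=()) for i in range(10)]
    stats = window_summaries(sites, [WindowSpec("chr1", 0, 10)], pm, SAMPLES)
    df = windows_to_dataframe(stats, pm)
    assert list(df.columns[:8]) == [
        "chrom", "start", "end", "n_sites", "fst", "pi_p1", "pi_p2", "dxy",
    ]
    assert df.loc[0, "start"] == 1 and df.loc[0, "end"] == 10
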