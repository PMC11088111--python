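import numpy as np
import pytest

from divscan.goenrich import Gene2Go, fisher_overrep, parse_obo, run_enrichment
from divscan.annotate import welch_t_test, window_repeat_proportion
from divscan.clusters import cds_pi
from divscan.simulate import (
    CdsFixtureConfig,
    CollapseConfig,
    CompositeConfig,
    GoFixtureConfig,
    RepeatFixtureConfig,
    SplitModelConfig,
    apparent_site_pi,
    inject_missingness,
    sim_cds_fixture,
    sim_collapsed_cluster,
    sim_composite_genome,
    sim_gene_fixture,
    sim_go_fixture,
    sim_recomb_fixture,
    sim_repeat_fixture,
    sim_split_coalescent,
)
from divscan.windows import WindowSpec, make_windows, pearson_correlation, window_summaries


class TestSplitModel:
    def test_seed_determinism(self):
        cfg = SplitModelConfig(n1=3, n2=3, L=500, theta=0.01, T=0.5, seed=7)
        a = sim_split_coalescent(cfg)
        b = sim_split_coalescent(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert list(a.refs) == list(b.refs) and list(a.alts) == list(b.alts)

    def test_theta_zero_all_invariant(self):
        res = sim_split_coalescent(SplitModelConfig(n1=2, n2=2, L=200, theta=0.0, T=1.0))
        assert (res.genotypes == 0).all()
        assert all(a == "" for a in res.alts)

    def test_panmixia_fst_near_zero(self):
        vals = []
        for seed in range(4):
            res = sim_split_coalescent(
                SplitModelConfig(n1=8, n2=8, L=20_000, theta=0.01, T=0.0, seed=seed)
            )
            stats = window_summaries(
                res.site_records(),
                [WindowSpec("sim1", 0, res.config.L)],
                res.population_map(),
                res.sample_names,
            )
            vals.append(stats[0].fst)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean) < 3 * se + 0.02

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SplitModelConfig(n1=1, n2=2, L=10, theta=0.01, T=1.0)
        with pytest.raises(ValueError):
            SplitModelConfig(n1=2, n2=2, L=10, theta=0.2, T=1.0)
        with pytest.raises(ValueError):
            SplitModelConfig(n1=2, n2=2, L=10, theta=0.01, T=-1.0)

    def test_vcf_roundtrip(self, tmp_path):
        from divscan.allsites import read_allsites_vcf

        res = sim_split_coalescent(SplitModelConfig(n1=2, n2=2, L=300, theta=0.02, T=1.0, seed=1))
        path = tmp_path / "sim.vcf"
        res.to_vcf(path)
        order, sites = read_allsites_vcf(path)
        assert order == res.sample_names
        got = list(sites)
        assert len(got) == 300
        G = np.stack([g.genotypes for g in got])
        np.testing.assert_array_equal(G, res.genotypes)


class TestMissingness:
    def test_rate_zero_identity(self):
        res = sim_split_coalescent(SplitModelConfig(n1=2, n2=2, L=50, theta=0.02, T=1.0, seed=2))
        out = list(inject_missingness(res.site_records(), 0.0, seed=1))
        G = np.stack([s.genotypes for s in out])
        np.testing.assert_array_equal(G, res.genotypes)

    def test_rate_realised_within_3se(self):
        res = sim_split_coalescent(SplitModelConfig(n1=5, n2=5, L=1000, theta=0.0, T=1.0, seed=3))
        out = list(inject_missingness(res.site_records(), 0.3, seed=9))
        G = np.stack([s.genotypes for s in out])
        frac = (G[:, :, 0] < 0).mean()
        n = G.shape[0] * G.shape[1]
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < 3 * se

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            list(inject_missingness([], 1.0, seed=0))


class TestCollapse:
    def test_all_psv_sites_universally_het(self):
        cfg = CollapseConfig(
            n1=2, n2=2, k_copies=2, psv_density=0.05, cluster_span=2000,
            flank_span=0, seed=4,
        )
        res = sim_collapsed_cluster(cfg)
        psv = res.truth["psv_positions"]
        assert len(psv) > 50
        for p in psv:
            gt = res.genotypes[p]
            assert ((gt[:, 0] == 0) & (gt[:, 1] == 1)).all()
        # non-PSV sites are invariant (no allelic variation configured)
        mask = np.ones(res.L, dtype=bool)
        mask[psv] = False
        assert (res.genotypes[mask] == 0).all()

    def test_apparent_site_pi_formula(self):
        assert apparent_site_pi(4) == pytest.approx(2 / 3)
        assert apparent_site_pi(20) == pytest.approx(20 / 38)

    def test_window_pi_matches_enumeration_and_fst_near_zero(self):
        cfg = CollapseConfig(
            n1=10, n2=10, k_copies=2, psv_density=0.02, cluster_span=5000,
            flank_span=5000, flank_theta=0.002, flank_T=1.0, seed=5,
        )
        res = sim_collapsed_cluster(cfg)
        wins = make_windows({"sim1": res.L}, 5000)
        stats = window_summaries(
            res.site_records(), wins, res.population_map(), res.sample_names
        )
        cluster = stats[1]  # [5000, 10000) is the cluster
        n_psv = res.truth["n_psv"]
        f = apparent_site_pi(20)  # per-population: 20 called alleles
        assert cluster.pi["pop1"] == pytest.approx(n_psv * f / 5000)
        assert cluster.pi["pop2"] == pytest.approx(n_psv * f / 5000)
        # PSV allele frequencies identical in both populations -> FST ~ 0
        assert abs(cluster.fst) < 0.05
        flank = stats[0]
        assert flank.fst > 0.3

    def test_partial_presence_shifts_allele_frequency(self):
        # copy 1 always present, copy 2 on half the haplotypes.  Genotypes
        # are deterministic given the realized presence matrix, so enumerate
        # each individual's pooled alleles and compare exactly; the frequency
        # must shift off the full-presence value of 0.5.
        cfg = CollapseConfig(
            n1=10, n2=10, k_copies=2, psv_density=0.05,
            presence_prob=(1.0, 0.5), cluster_span=20_000, flank_span=0, seed=6,
        )
        res = sim_collapsed_cluster(cfg)
        presence = res.truth["presence"]  # (2n, K)
        n = cfg.n1 + cfg.n2
        for p, o in zip(res.truth["psv_positions"], res.truth["psv_owner"]):
            gt = res.genotypes[p]
            for ind in range(n):
                pres = presence[2 * ind : 2 * ind + 2]
                alt = int(pres[:, o].sum())
                ref = int(pres.sum() - alt)
                if alt and ref:
                    expected = (0, 1)
                elif alt:
                    expected = (1, 1)
                elif ref:
                    expected = (0, 0)
                else:
                    expected = (-1, -1)
                assert tuple(gt[ind]) == expected
        # copy2-owned PSVs: called alt frequency below 0.5 (some hom-ref inds)
        copy2_sites = res.truth["psv_positions"][res.truth["psv_owner"] == 1]
        gt = res.genotypes[copy2_sites]
        freq = (gt == 1).sum() / (2 * gt.shape[0] * n)
        assert freq < 0.5

    def test_allelic_variation_adds_non_psv_variants(self):
        cfg = CollapseConfig(
            n1=3, n2=3, k_copies=2, psv_density=0.01, allelic_theta=0.02,
            cluster_span=5000, flank_span=0, seed=8,
        )
        res = sim_collapsed_cluster(cfg)
        psv = set(res.truth["psv_positions"].tolist())
        variant_sites = {
            int(i) for i in range(res.L) if (res.genotypes[i] == 1).any()
        }
        assert variant_sites - psv  # some within-copy variants appeared

    def test_read_sampling_mode_runs(self):
        cfg = CollapseConfig(
            n1=2, n2=2, cluster_span=1000, flank_span=0, depth=8, seed=9,
        )
        res = sim_collapsed_cluster(cfg)
        psv = res.truth["psv_positions"]
        gt = res.genotypes[psv]
        assert ((gt == 0) | (gt == 1)).all()  # depth>0: never missing here

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            CollapseConfig(k_copies=1)


class TestComposite:
    def test_cluster_windows_stand_out(self):
        cfg = CompositeConfig(
            n_windows=50, window_size=2000, cluster_windows=(10, 30),
            theta=0.002, T=1.0, psv_density=0.02, seed=11,
        )
        res = sim_composite_genome(cfg)
        wins = make_windows({"sim1": res.L}, cfg.window_size)
        stats = window_summaries(
            res.site_records(), wins, res.population_map(), res.sample_names
        )
        fst = np.array([s.fst for s in stats])
        pi1 = np.array([s.pi["pop1"] for s in stats])
        baseline = [i for i in range(50) if i not in (10, 30)]
        assert fst[10] < np.nanmin(fst[baseline])
        assert fst[30] < np.nanmin(fst[baseline])
        assert pi1[10] > np.nanmax(pi1[baseline])
        assert pi1[30] > np.nanmax(pi1[baseline])

    def test_determinism(self):
        cfg = CompositeConfig(n_windows=5, window_size=500, cluster_windows=(2,), seed=1)
        a = sim_composite_genome(cfg)
        b = sim_composite_genome(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert list(a.alts) == list(b.alts)


class TestGoFixture:
    def test_implanted_terms_have_minimal_p(self):
        fix = sim_go_fixture(GoFixtureConfig(), seed=0)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            obo = pathlib.Path(d) / "t.obo"
            obo.write_text(fix.obo_text)
            dag = parse_obo(obo)
        g2g = Gene2Go(fix.gene2go, dag)
        results = run_enrichment(
            fix.study, fix.universe, g2g, dag, algorithm="classic", min_genes=10
        )
        by_p = [r.term for r in results]
        assert set(by_p[: len(fix.implanted)]) == fix.implanted

    def test_determinism(self):
        a = sim_go_fixture(GoFixtureConfig(), seed=3)
        b = sim_go_fixture(GoFixtureConfig(), seed=3)
        assert a.gene2go == b.gene2go and a.obo_text == b.obo_text


class TestRepeatFixture:
    def test_depletion_detected_by_welch(self):
        windows = [WindowSpec("c", i * 5000, (i + 1) * 5000) for i in range(400)]
        hdr = set(range(0, 400, 2))
        feats = sim_repeat_fixture(windows, hdr, RepeatFixtureConfig(), seed=0)
        df = window_repeat_proportion(feats, windows)
        hdr_mask = np.array([i in hdr for i in range(400)])
        t, _, p = welch_t_test(df["total"][hdr_mask], df["total"][~hdr_mask])
        assert t < 0 and p < 0.001


class TestGeneAndRecombFixtures:
    def test_genes_non_overlapping(self):
        genes = sim_gene_fixture("c", 200_000, 60, seed=0)
        assert len(genes) > 10
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_recomb_correlation_near_target(self):
        rng = np.random.default_rng(0)
        fst = rng.normal(0.5, 0.1, size=2000)
        rate = sim_recomb_fixture(fst, target_corr=-0.5, seed=1)
        r, p = pearson_correlation(fst, rate)
        assert r == pytest.approx(-0.5, abs=0.06)
        assert (rate >= 0).all()


class TestCdsFixture:
    def test_planted_distances_recovered_exactly(self):
        fix = sim_cds_fixture(CdsFixtureConfig(private_counts=(2, 1, 3), length=100), seed=0)
        seqs = [c.sequence for c in fix.copies if c.status == "complete"]
        assert cds_pi(seqs) == pytest.approx(0.04, abs=1e-12)
        assert fix.expected_pi == pytest.approx(0.04)

    def test_null_copies_marked(self):
        fix = sim_cds_fixture(
            CdsFixtureConfig(private_counts=(1, 1), length=60, n_null=2), seed=1
        )
        statuses = [c.status for c in fix.copies]
        assert statuses.count("null") == 2
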