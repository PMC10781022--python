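import numpy as np
import pytest
from scipy.stats import chisquare, multivariate_normal

from finemapvi import (
    SimulationConfig,
    assign_causal,
    run_gwas,
    simulate_genotypes,
    simulate_locus,
    simulate_trait,
)
from finemapvi.simulate import FULL_SCALE_NCP, bvn_upper_orthant, simulate_annotations


class TestBvnOrthant:
    @pytest.mark.parametrize("h,k,rho", [
        (-1.5, 0.3, -0.9), (0.5, 0.5, 0.95), (2.0, -1.0, 0.4),
        (0.7, 1.3, 0.0), (-0.4, -0.4, -0.3), (1.0, 1.0, 0.999),
    ])
    def test_against_mvn_cdf(self, h, k, rho):
        expect = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([-h, -k])
        assert bvn_upper_orthant(h, k, rho) == pytest.approx(expect, abs=1e-9)

    def test_independence_factorizes(self):
        from scipy.stats import norm

        got = bvn_upper_orthant(0.8, -0.2, 0.0)
        assert got == pytest.approx(norm.sf(0.8) * norm.sf(-0.2), abs=1e-12)


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(g=30, n=500, seed=42)
        d1, l1 = simulate_genotypes(cfg)
        d2, l2 = simulate_genotypes(cfg)
        assert np.array_equal(d1, d2) and np.array_equal(l1, l2)

    def test_no_decay_gives_independent_variants(self):
        cfg = SimulationConfig(g=40, n=10_000, ld_decay=0.0, seed=4)
        d, ld_true = simulate_genotypes(cfg)
        emp = np.corrcoef(d.T.astype(float))
        assert np.abs(ld_true - np.eye(40)).max() < 1e-9
        assert np.abs(emp - np.eye(40)).max() < 0.05

    def test_empirical_matches_theoretical_ld(self):
        cfg = SimulationConfig(g=60, n=10_000, ld_decay=0.95, seed=3)
        d, ld_true = simulate_genotypes(cfg)
        emp = np.corrcoef(d.T.astype(float))
        assert np.abs(emp - ld_true).max() <= 0.05
        # adjacent correlations positive and decaying with distance
        assert ld_true[0, 1] > ld_true[0, 5] > ld_true[0, 20] >= 0

    def test_block_structure_breaks_ld(self):
        cfg = SimulationConfig(g=20, n=2000, ld_decay=0.9, n_blocks=2, seed=8)
        _, ld_true = simulate_genotypes(cfg)
        assert np.abs(ld_true[:10, 10:]).max() < 1e-9
        assert ld_true[0, 1] > 0.3


class TestAssignCausal:
    def test_no_enrichment_is_uniform(self):
        rng = np.random.default_rng(77)
        cfg = SimulationConfig(g=20, k_causal=1, w_intensity=0.0, m_anno=2,
                               enriched_idx=(0,), seed=1)
        anno = simulate_annotations(cfg, rng)
        counts = np.zeros(20)
        for _ in range(10_000):
            counts[assign_causal(cfg, anno, rng)] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_enrichment_ratio_e2(self, rng):
        from finemapvi import AnnotationMatrix

        g = 40
        col = np.zeros((g, 1), dtype=int)
        col[: g // 2] = 1  # annotation covers half the variants
        anno = AnnotationMatrix(["a"], col)
        cfg = SimulationConfig(g=g, k_causal=1, w_intensity=2.0, m_anno=1,
                               enriched_idx=(0,), seed=1)
        hits = np.zeros(g)
        for _ in range(10_000):
            hits[assign_causal(cfg, anno, rng)] += 1
        ratio = hits[: g // 2].mean() / hits[g // 2:].mean()
        assert ratio == pytest.approx(np.exp(2.0), rel=0.10)

    def test_all_variants_causal(self, rng):
        cfg = SimulationConfig(g=6, k_causal=6, w_intensity=1.0, m_anno=1,
                               enriched_idx=(0,), seed=1)
        anno = simulate_annotations(cfg, rng)
        assert assign_causal(cfg, anno, rng).tolist() == [0, 1, 2, 3, 4, 5]


class TestSimulateTrait:
    def test_h2_zero_is_pure_noise(self, rng):
        x = rng.integers(0, 3, size=(500, 5)).astype(np.int8)
        trait, beta = simulate_trait(x, np.array([0, 1]), 0.0, rng)
        assert np.all(beta == 0)
        assert trait.mean() == pytest.approx(0.0, abs=1e-12)

    def test_exact_genetic_variance_share(self, rng):
        cfg = SimulationConfig(g=30, n=2000, seed=10)
        d, _ = simulate_genotypes(cfg, rng)
        causal = np.array([3, 17])
        h2 = 0.2
        trait, beta = simulate_trait(d, causal, h2, rng)
        xc = d[:, causal].astype(float)
        xc = (xc - xc.mean(0)) / xc.std(0)
        assert (xc @ beta).var() == pytest.approx(h2, abs=1e-9)

    def test_half_heritability_correlation(self, rng):
        cfg = SimulationConfig(g=10, n=10_000, ld_decay=0.0, seed=12)
        d, _ = simulate_genotypes(cfg, rng)
        trait, _ = simulate_trait(d, np.array([4]), 0.5, rng)
        r2 = np.corrcoef(d[:, 4].astype(float), trait)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.02)


class TestRunGwas:
    def test_null_trait_unit_chisquare(self, rng):
        cfg = SimulationConfig(g=100, n=4000, ld_decay=0.0, seed=14)
        d, _ = simulate_genotypes(cfg, rng)
        trait, _ = simulate_trait(d, np.array([0]), 0.0, rng)
        locus = run_gwas(d, trait)
        assert (locus.z**2).mean() == pytest.approx(1.0, abs=0.35)

    def test_noncentrality_of_causal_z(self):
        # expected z^2 ~ N*h2 + 1 for a lone causal variant
        zz = []
        for seed in range(8):
            cfg = SimulationConfig(g=10, n=50_000, k_causal=1, h2=0.01,
                                   ld_decay=0.0, w_intensity=0.0, seed=seed)
            sim = simulate_locus(cfg)
            zz.append(sim.locus.z[sim.causal_idx[0]] ** 2)
        assert np.mean(zz) == pytest.approx(50_000 * 0.01 + 1, rel=0.35)

    def test_permuted_trait_breaks_association(self, rng):
        cfg = SimulationConfig(g=50, n=5000, k_causal=1, h2=0.02, seed=16)
        sim = simulate_locus(cfg)
        perm = rng.permutation(sim.trait)
        locus = run_gwas(sim.genotypes, perm)
        assert np.abs(locus.z).max() < 5.0  # consistent with 50 null draws

    def test_monomorphic_gets_zero_z(self, rng):
        d = rng.integers(0, 3, size=(200, 3)).astype(np.int8)
        d[:, 1] = 2
        trait = rng.standard_normal(200)
        locus = run_gwas(d, trait)
        assert locus.z[1] == 0.0
        assert np.isfinite(locus.ld).all()


class TestSimulateLocus:
    def test_reproducible_end_to_end(self):
        cfg = SimulationConfig.reduced(n=2000, g=50, k_causal=5, w_intensity=2.0, seed=77)
        s1, s2 = simulate_locus(cfg), simulate_locus(cfg)
        assert np.array_equal(s1.locus.z, s2.locus.z)
        assert np.array_equal(s1.causal_idx, s2.causal_idx)
        assert np.array_equal(s1.anno.values, s2.anno.values)

    def test_default_design_shape(self):
        cfg = SimulationConfig()
        assert cfg.g == 1000 and cfg.k_causal == 5
        assert cfg.h2_resolved == pytest.approx(5e-4)
        assert cfg.m_anno == 10 and len(cfg.enriched_idx) == 5

    def test_reduced_preserves_per_causal_noncentrality(self):
        cfg = SimulationConfig.reduced(n=25_000, g=200, k_causal=5)
        assert cfg.n * cfg.h2_resolved / cfg.k_causal == pytest.approx(FULL_SCALE_NCP)

    def test_w0_causals_independent_of_annotations(self):
        # point-biserial correlation between causal status and annotation
        # membership vanishes without enrichment
        cors = []
        for seed in range(30):
            cfg = SimulationConfig(g=100, n=50, k_causal=10, w_intensity=0.0,
                                   seed=600 + seed)
            rng = np.random.default_rng(cfg.seed)
            anno = simulate_annotations(cfg, rng)
            causal = np.zeros(100)
            causal[assign_causal(cfg, anno, rng)] = 1
            for j in range(anno.m):
                col = anno.values[:, j]
                if 0 < col.sum() < 100:
                    cors.append(np.corrcoef(causal, col)[0, 1])
        assert abs(np.mean(cors)) < 0.02
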