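import numpy as np
import pytest
from scipy import stats

from r2vim import (ConfigError, SimConfig, permute_phenotype,
                   simulate_genotypes, simulate_phenotype, truth_annotation,
                   with_functional)


class TestSimulateGenotypes:
    def test_dosage_domain_and_boundary_maf(self):
        gm = simulate_genotypes(SimConfig(n_samples=4, n_variants=2,
                                          maf_range=(0.5, 0.5), seed=1))
        assert np.isin(gm.dosages, (0, 1, 2)).all()

    def test_boundary_maf_frequency(self):
        gm = simulate_genotypes(SimConfig(n_samples=20000, n_variants=3,
                                          maf_range=(0.5, 0.5), seed=2))
        freq = gm.dosages.mean(axis=0) / 2
        assert np.allclose(freq, 0.5, atol=3 * np.sqrt(0.25 / (2 * 20000)))

    def test_observed_maf_within_binomial_error(self):
        n = 10_000
        gm = simulate_genotypes(SimConfig(n_samples=n, n_variants=20,
                                          maf_range=(0.01, 0.01), seed=3))
        freq = gm.dosages.mean(axis=0) / 2
        se = np.sqrt(0.01 * 0.99 / (2 * n))
        assert (np.abs(freq - 0.01) < 3 * se).mean() >= 0.9

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_samples=30, n_variants=40, seed=11)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.samples == b.samples and a.variants == b.variants

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_samples=5, n_variants=5, maf_range=(0.0, 0.3))
        with pytest.raises(ConfigError):
            SimConfig(n_samples=5, n_variants=5, maf_range=(0.1, 0.6))

    def test_contiguous_gene_blocks(self):
        gm = simulate_genotypes(SimConfig(n_samples=5, n_variants=23, seed=0))
        genes = [gm.genes[v] for v in gm.variants]
        # contiguous: once a gene ends it never reappears
        seen, last = set(), None
        for g in genes:
            if g != last:
                assert g not in seen
                seen.add(g)
                last = g
        assert len(seen) == 5  # ceil(23 / 5)

    def test_ld_mode_induces_within_gene_correlation(self):
        cfg = SimConfig(n_samples=4000, n_variants=10, n_genes=2,
                        maf_range=(0.3, 0.5), seed=8, ld_rho=0.8)
        gm = simulate_genotypes(cfg)
        r_within = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
        r_between = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 7])[0, 1]
        assert r_within > 0.3
        assert abs(r_between) < 0.1


class TestSimulatePhenotype:
    def test_zero_noise_forbidden(self):
        with pytest.raises(ConfigError):
            SimConfig(n_samples=10, n_variants=5, noise_sd=0.0)

    def test_strong_single_effect_dominates(self):
        cfg = with_functional(
            SimConfig(n_samples=400, n_variants=10, maf_range=(0.3, 0.5),
                      noise_sd=0.1, seed=21, age_missing_rate=0.0), {0: 5.0})
        gm = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        r = np.corrcoef(ph.outcome, gm.dosages[:, 0])[0, 1]
        assert r > 0.99

    def test_null_outcome_uncorrelated_with_variants(self):
        cfg = SimConfig(n_samples=200, n_variants=50, maf_range=(0.2, 0.5),
                        noise_sd=1.0, seed=22)
        gm = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        d = gm.dosages - gm.dosages.mean(axis=0)
        y = ph.outcome - ph.outcome.mean()
        r = (d.T @ y) / (np.linalg.norm(d, axis=0) * np.linalg.norm(y))
        # max |r| over 50 null variants at n=200: Bonferroni-style null bound
        assert np.abs(r).max() < stats.norm.ppf(1 - 0.0005) / np.sqrt(200)

    def test_effect_recovery_within_three_se(self):
        hits = 0
        for seed in range(100):
            cfg = with_functional(
                SimConfig(n_samples=150, n_variants=5, maf_range=(0.2, 0.5),
                          noise_sd=1.0, seed=seed), {1: 0.8})
            gm = simulate_genotypes(cfg)
            ph = simulate_phenotype(gm, cfg)
            res = stats.linregress(gm.dosages[:, 1].astype(float), ph.outcome)
            hits += abs(res.slope - 0.8) < 3 * res.stderr
        assert hits >= 95  # nominal coverage 99.7%

    def test_missing_functional_variant_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_samples=10, n_variants=5, seed=0,
                      functional_variant_ids=("v99",), effect_sizes={"v99": 1.0})
        gm = simulate_genotypes(SimConfig(n_samples=10, n_variants=5, seed=0))
        with pytest.raises(ConfigError):
            truth_annotation(SimConfig(n_samples=10, n_variants=4, seed=0), gm)

    def test_age_has_missingness_other_covariates_complete(self):
        cfg = SimConfig(n_samples=2000, n_variants=5, seed=13, age_missing_rate=0.01)
        gm = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        assert ph.covariates["age"].isna().sum() > 0
        assert not ph.covariates[["sex", "medication", "smoking"]].isna().any().any()


class TestPermutePhenotype:
    def test_multiset_and_moments_preserved(self):
        cfg = SimConfig(n_samples=50, n_variants=5, seed=31)
        gm = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        perm = permute_phenotype(ph, seed=9)
        assert sorted(perm.outcome) == pytest.approx(sorted(ph.outcome))
        assert perm.outcome.mean() == pytest.approx(ph.outcome.mean())
        assert perm.outcome.var() == pytest.approx(ph.outcome.var())
        assert perm.covariates.equals(ph.covariates)

    def test_association_p_uniform_over_seeds(self):
        cfg = with_functional(
            SimConfig(n_samples=100, n_variants=3, maf_range=(0.3, 0.5),
                      noise_sd=0.5, seed=33), {0: 2.0})
        gm = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        d = gm.dosages[:, 0].astype(float)
        pvals = [stats.pearsonr(permute_phenotype(ph, s).outcome, d).pvalue
                 for s in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTruthAnnotation:
    def test_partition_and_classes(self):
        cfg = with_functional(
            SimConfig(n_samples=10, n_variants=20, n_genes=4, seed=41), {0: 1.0})
        gm = simulate_genotypes(cfg)
        truth = truth_annotation(cfg, gm)
        assert truth["v1"] == "functional"
        # v1 is in gene g1 with variants v1..v5
        gene1 = [v for v in gm.variants if gm.genes[v] == gm.genes["v1"]]
        for v in gene1:
            if v != "v1":
                assert truth[v] == "functional_gene"
        # genes without functional variants are all 'neither'
        cold = [v for v in gm.variants if gm.genes[v] != gm.genes["v1"]]
        assert all(truth[v] == "neither" for v in cold)
        counts = {c: sum(t == c for t in truth.values())
                  for c in ("functional", "functional_gene", "neither")}
        assert sum(counts.values()) == 20
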