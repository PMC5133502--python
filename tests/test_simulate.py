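"""Synthetic pedigrees, gene-dropped genotypes and polygenic traits."""

import numpy as np
import pytest
from scipy import stats as sps

import famcombine as fc


class TestPedigreeTemplates:
    def test_default_template_arithmetic(self):
        # 2 founders + 5 married children (+5 spouses) + 5*6 grandchildren = 42
        ped = fc.simulate_pedigrees(fc.SimConfig(n_families=20, seed=0))
        assert ped.n == 840
        assert len(ped.families) == 20

    def test_nuclear_template(self):
        cfg = fc.SimConfig(n_families=1, family_template="nuclear", children_per_couple=2)
        ped = fc.simulate_pedigrees(cfg)
        assert ped.n == 4
        assert len(ped.founders()) == 2

    def test_same_seed_identical(self):
        cfg = fc.SimConfig(n_families=3, seed=7)
        a, b = fc.simulate_pedigrees(cfg), fc.simulate_pedigrees(cfg)
        assert a.individuals == b.individuals and a.parent_map == b.parent_map

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fc.SimConfig(h2=1.0)
        with pytest.raises(ValueError):
            fc.SimConfig(causal_fraction=1.5)
        with pytest.raises(ValueError):
            fc.SimConfig(family_template="clan")


class TestGeneDrop:
    def test_founders_only_frequency_matches_maf(self):
        """Sample allele frequency of unrelated founders is Binomial(2n, maf)."""
        cfg = fc.SimConfig(n_families=5000, family_template="founders", seed=3)
        ped = fc.simulate_pedigrees(cfg)
        maf = np.array([0.02, 0.1, 0.4])
        gene = fc.gene_drop(ped, cfg, np.random.default_rng(11), maf=maf)
        n_alleles = 2 * ped.n
        for i in range(3):
            freq = gene.G[i].sum() / n_alleles
            lo, hi = sps.binom.interval(0.999, n_alleles, maf[i])
            assert lo / n_alleles <= freq <= hi / n_alleles

    def test_zero_maf_variant_dropped_as_monomorphic(self):
        cfg = fc.SimConfig(n_families=2, seed=1)
        ped = fc.simulate_pedigrees(cfg)
        gene = fc.gene_drop(ped, cfg, np.random.default_rng(2), maf=np.array([0.0, 0.2]))
        assert gene.n_variants == 1  # all-zero variant cannot be tested

    def test_mendelian_consistency_all_trios(self, small_study):
        ped, gene = small_study.pedigree, small_study.genotypes[0]
        pos = {iid: k for k, iid in enumerate(ped.individuals)}
        for iid in ped.individuals:
            fa, mo = ped.parent_map.get(iid, (None, None))
            if fa is None or mo is None:
                continue
            child = gene.G[:, pos[iid]]
            f, m = gene.G[:, pos[fa]], gene.G[:, pos[mo]]
            # orientation flips preserve Mendelian bounds in flipped coordinates
            assert np.all(child <= (f > 0).astype(int) + (m > 0).astype(int))
            assert np.all(child >= (f == 2).astype(int) + (m == 2).astype(int))

    def test_deterministic_given_seed(self):
        cfg = fc.SimConfig(n_families=2, seed=5)
        ped = fc.simulate_pedigrees(cfg)
        a = fc.gene_drop(ped, cfg, np.random.default_rng(1))
        b = fc.gene_drop(ped, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(a.G, b.G)


class TestTraitSimulation:
    def test_unheritable_trait_has_no_sib_correlation(self):
        cfg = fc.SimConfig(
            n_families=2500, family_template="nuclear", children_per_couple=2,
            h2=0.0, seed=13,
        )
        ped = fc.simulate_pedigrees(cfg)
        trait, _ = fc.simulate_trait(ped, None, cfg, np.random.default_rng(17))
        resid = trait.y - trait.X @ np.linalg.lstsq(trait.X, trait.y, rcond=None)[0]
        sibs = resid.reshape(2500, 4)[:, 2:]
        r = np.corrcoef(sibs[:, 0], sibs[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_heritable_trait_parent_offspring_correlation(self):
        """At h2 = 0.5 the parent-offspring trait correlation is h2 * 2phi = 0.25."""
        cfg = fc.SimConfig(
            n_families=2500, family_template="nuclear", children_per_couple=2,
            h2=0.5, seed=19,
        )
        ped = fc.simulate_pedigrees(cfg)
        trait, _ = fc.simulate_trait(ped, None, cfg, np.random.default_rng(23))
        resid = trait.y - trait.X @ np.linalg.lstsq(trait.X, trait.y, rcond=None)[0]
        fam = resid.reshape(2500, 4)
        r = np.corrcoef(fam[:, 0], fam[:, 2])[0, 1]  # father vs first child
        assert r == pytest.approx(0.25, abs=0.04)

    def test_huge_effects_make_trait_track_burden(self, small_study):
        cfg = fc.SimConfig(
            n_families=4, h2=0.3, seed=42, causal_fraction=1.0, effect_size_scale=1e4
        )
        gene = small_study.genotypes[0]
        trait, truth = fc.simulate_trait(
            small_study.pedigree, gene, cfg, np.random.default_rng(3),
            kinship=small_study.kinship,
        )
        burden = truth["variant_betas"] @ gene.G
        rho = sps.spearmanr(trait.y, burden).statistic
        assert rho > 0.99  # ties among discrete burden values cap the rank correlation

    def test_genic_variance_fraction_calibrated(self, small_study):
        cfg = fc.SimConfig(n_families=4, seed=42, causal_fraction=0.5, genic_variance=0.1)
        gene = small_study.genotypes[0]
        _, truth = fc.simulate_trait(
            small_study.pedigree, gene, cfg, np.random.default_rng(5),
            kinship=small_study.kinship,
        )
        genic = truth["variant_betas"] @ gene.G
        assert genic.var() == pytest.approx(0.1, rel=1e-6)
        assert truth["causal"].sum() == round(0.5 * gene.n_variants)

    def test_mixed_direction_assigns_both_signs(self, small_study):
        cfg = fc.SimConfig(
            n_families=4, seed=42, causal_fraction=1.0, effect_model="mixed_direction"
        )
        _, truth = fc.simulate_trait(
            small_study.pedigree, small_study.genotypes[0], cfg,
            np.random.default_rng(8), kinship=small_study.kinship,
        )
        betas = truth["variant_betas"][truth["causal"]]
        assert (betas > 0).any() and (betas < 0).any()


class TestWritersRoundTrip:
    def test_ped_vcf_phenotype_roundtrip(self, tmp_path, small_study):
        from famcombine import io as fio

        ped, gene, trait = (
            small_study.pedigree,
            small_study.genotypes[0],
            small_study.trait,
        )
        fc.write_ped(ped, tmp_path / "s.ped", phenotype=trait.y)
        fc.write_vcf([gene], trait.sample_order, tmp_path / "s.vcf")
        fc.write_phenotypes(trait, tmp_path / "s.tsv")

        ped2 = fc.read_pedigree(tmp_path / "s.ped")
        assert ped2.individuals == ped.individuals
        genes, samples = fio.read_vcf_genes(tmp_path / "s.vcf")
        assert samples == trait.sample_order
        np.testing.assert_allclose(genes[0].G, gene.G)
        np.testing.assert_allclose(genes[0].maf, gene.maf, atol=1e-12)
        data = fio.read_phenotype_table(tmp_path / "s.tsv", "trait", ["covar1"])
        np.testing.assert_allclose(data.y, trait.y, atol=1e-5)
        assert data.sample_order == trait.sample_order

    def test_dosage_matrix_roundtrip(self, tmp_path, small_study):
        import pandas as pd
        from famcombine import io as fio

        gene = small_study.genotypes[0]
        pd.DataFrame(
            gene.G, index=gene.variant_ids, columns=small_study.trait.sample_order
        ).to_csv(tmp_path / "g.tsv", sep="\t")
        gene2, samples = fio.read_dosage_matrix(tmp_path / "g.tsv", gene_id="GENE1")
        np.testing.assert_allclose(gene2.G, gene.G)
        assert samples == small_study.trait.sample_order


def test_mean_arterial_pressure_formula():
    assert fc.mean_arterial_pressure(90.0, 120.0) == pytest.approx(100.0)


def test_gene_drop_kinship_estimator_sib_pair():
    ped = fc.Pedigree(
        ["pa", "ma", "s1", "s2"],
        {"pa": (None, None), "ma": (None, None),
         "s1": ("pa", "ma"), "s2": ("pa", "ma")},
        {i: "F1" for i in ["pa", "ma", "s1", "s2"]},
    )
    phi_hat, se = fc.estimate_kinship_gene_drop(ped, n_drops=20_000, seed=1)
    assert phi_hat[2, 3] == pytest.approx(0.25, abs=3 * se[2, 3])
    assert phi_hat[0, 1] == 0.0
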