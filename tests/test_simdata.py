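"""Population generator: determinism, drift, panels, phenotypes, progeny EBVs."""

import numpy as np
import pytest

import ovinepred as op
from ovinepred.simdata import progeny_mean_accuracy


def hudson_fst(p1, p2, n1, n2):
    """Direct Hudson FST estimator from two samples' allele frequencies."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return num[ok].sum() / den[ok].sum()


class TestConfig:
    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            op.PopulationConfig(density_ratio=0.0)
        with pytest.raises(ValueError):
            op.PopulationConfig(h2_target=0.6, var_maternal=0.3, var_breed=0.2, var_sireflock=0.1)
        with pytest.raises(ValueError):
            op.PopulationConfig(n_qtl=2000, n_snps_dense=1000)

    def test_rejects_unknown_cross_breed(self):
        with pytest.raises(ValueError):
            op.PopulationConfig(cross_design=[("Nope", "Merino", 100)])


class TestSimulatePopulation:
    def test_shapes_and_determinism(self):
        cfg = op.PopulationConfig(
            n_snps_dense=400, n_reference=100, n_founders_per_breed=30,
            divergence_generations=5, effective_size=30, n_qtl=40,
            n_validation_sires_per_breed=4, seed=42,
        )
        g1, p1, t1 = op.simulate_population(cfg)
        g2, p2, t2 = op.simulate_population(cfg)
        assert g1.calls.shape[1] == 400
        # founders: 30 per breed x 4 breeds, plus distant sires and offspring
        assert (p1.table["role"] == "reference").sum() == 100
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert list(g1.ids) == list(g2.ids)
        np.testing.assert_allclose(t1.tbv, t2.tbv)

    def test_divergence_increases_fst(self):
        fsts = {}
        for gens in (10, 200):
            cfg = op.PopulationConfig(
                n_breeds=2, breed_labels=("A", "B"), n_snps_dense=600,
                n_reference=40, n_founders_per_breed=50, divergence_generations=gens,
                effective_size=100, n_qtl=30, n_validation_sires_per_breed=2,
                cross_design=[("A", "B", 40)], seed=11,
            )
            geno, ped, _ = op.simulate_population(cfg)
            is_a = np.array([i.startswith("A_F") for i in geno.ids])
            is_b = np.array([i.startswith("B_F") for i in geno.ids])
            pa = geno.calls[is_a].mean(axis=0) / 2
            pb = geno.calls[is_b].mean(axis=0) / 2
            fsts[gens] = hudson_fst(pa, pb, is_a.sum(), is_b.sum())
        assert fsts[200] > fsts[10]

    def test_tbv_matches_centered_qtl_dosages(self, small_multibreed):
        _, geno, ped, truth, _ = small_multibreed
        lookup = {s: j for j, s in enumerate(geno.snp_ids)}
        qtl_idx = [lookup[q] for q in truth.qtl_ids]
        dos = geno.calls[:, qtl_idx].astype(float)
        founder = np.array([not i.startswith("REF") for i in geno.ids])
        centered = dos - dos[founder].mean(axis=0)[None, :]
        np.testing.assert_allclose(centered @ truth.qtl_effects, truth.tbv, atol=1e-9)

    def test_founder_tbv_variance_matches_target(self, small_multibreed):
        cfg, geno, ped, truth, _ = small_multibreed
        founder = np.array([not i.startswith("REF") for i in geno.ids])
        v = truth.tbv[founder].var()
        assert abs(v - cfg.h2_target) / cfg.h2_target < 0.05

    def test_offspring_frequency_drift_is_unbiased(self):
        """Mean allele-frequency change parent pool -> offspring ~ 0."""
        deltas = []
        for seed in range(5):
            cfg = op.PopulationConfig(
                n_breeds=1, breed_labels=("A",), n_snps_dense=500, n_reference=200,
                n_founders_per_breed=100, divergence_generations=5, effective_size=80,
                n_qtl=20, var_breed=0.0, n_validation_sires_per_breed=2, seed=seed,
            )
            geno, ped, _ = op.simulate_population(cfg)
            is_f = np.array([not i.startswith("REF") for i in geno.ids])
            deltas.append(
                (geno.calls[~is_f].mean(axis=0) - geno.calls[is_f].mean(axis=0)).mean() / 2
            )
        assert abs(np.mean(deltas)) < 0.01


class TestArchitectures:
    @staticmethod
    def _variance_shares(cfg_kwargs):
        cfg = op.PopulationConfig(
            n_breeds=1, breed_labels=("A",), n_snps_dense=1200, n_reference=100,
            n_founders_per_breed=200, divergence_generations=10, effective_size=100,
            var_breed=0.0, n_validation_sires_per_breed=2, seed=3, **cfg_kwargs,
        )
        geno, ped, truth = op.simulate_population(cfg)
        lookup = {s: j for j, s in enumerate(geno.snp_ids)}
        qtl_idx = [lookup[q] for q in truth.qtl_ids]
        founder = np.array([not i.startswith("REF") for i in geno.ids])
        dos = geno.calls[founder][:, qtl_idx].astype(float)
        per_qtl = dos.var(axis=0) * truth.qtl_effects**2
        return per_qtl / truth.tbv[founder].var()

    def test_gaussian_many_qtl_no_dominant_locus(self):
        shares = self._variance_shares({"n_qtl": 500, "qtl_effect_distribution": "gaussian"})
        assert shares.max() < 0.02

    def test_few_large_has_dominant_locus(self):
        shares = self._variance_shares({"n_qtl": 50, "qtl_effect_distribution": "few_large"})
        assert shares.max() >= 0.10


class TestSubsetDensity:
    def test_identity_at_ratio_one(self, small_multibreed):
        _, geno, _, _, _ = small_multibreed
        sub = op.subset_density(geno, 1.0, seed=1)
        assert set(sub.snp_ids) == set(geno.snp_ids)

    def test_retained_count_is_rounded_fraction(self, small_multibreed):
        _, geno, _, _, _ = small_multibreed
        sub = op.subset_density(geno, 0.095, seed=1)
        assert sub.n_snps == round(0.095 * geno.n_snps)

    def test_sorted_by_chrom_pos_and_reproducible(self, small_multibreed):
        _, geno, _, _, _ = small_multibreed
        s1 = op.subset_density(geno, 0.2, seed=5)
        s2 = op.subset_density(geno, 0.2, seed=5)
        assert list(s1.snp_ids) == list(s2.snp_ids)
        key = [(int(c), p) for c, p in zip(s1.chrom, s1.pos)]
        assert key == sorted(key)

    def test_excludes_requested_snps(self, small_multibreed):
        _, geno, _, truth, _ = small_multibreed
        sub = op.subset_density(geno, 1.0, seed=1, exclude_snp_ids=truth.qtl_ids)
        assert not set(truth.qtl_ids) & set(sub.snp_ids)


class TestPhenotypes:
    def test_degenerate_h2_one_gives_y_equal_tbv(self):
        cfg = op.PopulationConfig(
            n_breeds=1, breed_labels=("A",), n_snps_dense=400, n_reference=80,
            n_founders_per_breed=40, divergence_generations=5, effective_size=40,
            n_qtl=40, h2_target=1.0, var_maternal=0.0, var_breed=0.0,
            var_sireflock=0.0, n_validation_sires_per_breed=2, seed=2,
        )
        geno, ped, truth = op.simulate_population(cfg)
        design = op.simulate_phenotypes(geno, ped, truth, cfg, seed=3, fixed_effect_scale=0.0)
        np.testing.assert_allclose(design.y, truth.tbv_for(design.animal_ids), atol=1e-9)

    def test_heritability_fraction_recovered(self, small_singlebreed):
        """var(tbv) / var(y - Xb) lands near the configured h2 = 0.3."""
        cfg, geno, ped, truth, design = small_singlebreed
        vc = truth.realized_var_components
        ratio = vc["additive"] / sum(vc.values())
        assert 0.25 < ratio < 0.35

    def test_variance_components_match_config(self, small_multibreed):
        cfg, _, _, truth, _ = small_multibreed
        vc = truth.realized_var_components
        assert vc["maternal"] == pytest.approx(cfg.var_maternal, rel=1e-9)
        assert vc["breed"] == pytest.approx(cfg.var_breed, rel=1e-9)
        assert vc["sireflock"] == pytest.approx(cfg.var_sireflock, rel=1e-9)
        assert vc["residual"] == pytest.approx(
            1 - cfg.h2_target - cfg.var_maternal - cfg.var_breed - cfg.var_sireflock, rel=1e-9
        )
        total = sum(vc.values())
        assert abs(total - 1.0) < 0.1

    def test_missing_dam_raises_with_maternal_variance(self, small_multibreed):
        cfg, geno, ped, truth, _ = small_multibreed
        bad = ped.table.copy()
        bad.loc[bad["role"] == "reference", "dam"] = ""
        bad_ped = op.Pedigree(table=bad, breeds=list(ped.breeds))
        with pytest.raises(ValueError, match="dam"):
            op.simulate_phenotypes(geno, bad_ped, truth, cfg, seed=1)


class TestProgenyEBV:
    def test_accuracy_formula_values(self):
        # limit: huge progeny group -> accuracy -> 1
        assert progeny_mean_accuracy(10**6, 0.3) > 0.99
        # closed form at n=100, h2=0.3: sqrt(7.5 / (1 + 0.25*99*0.3)) ~ 0.9435
        assert progeny_mean_accuracy(100, 0.3) == pytest.approx(np.sqrt(7.5 / 8.425), abs=1e-12)

    def test_rejects_bad_h2(self):
        with pytest.raises(ValueError):
            progeny_mean_accuracy(10, 0.0)

    def test_generative_correlation_matches_recorded_accuracy(self):
        rng = np.random.default_rng(1)
        n_sires = 500
        ids = np.array([f"S{i}" for i in range(n_sires)], dtype=object)
        truth = op.TrueGeneticValues(
            qtl_ids=np.array([], dtype=object), qtl_effects=np.array([]),
            ids=ids, tbv=rng.normal(0, np.sqrt(0.3), n_sires), additive_variance=0.3,
        )
        ebv = op.simulate_progeny_ebv(truth, ids, n_progeny=60, h2=0.3, seed=5)
        r = np.corrcoef(ebv.ebv, truth.tbv)[0, 1]
        assert abs(r - ebv.accuracy[0]) < 0.05
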