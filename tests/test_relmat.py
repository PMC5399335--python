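"""Relationship matrices: VanRaden G, pedigree A, relatedness classes, scale."""

import numpy as np
import pandas as pd
import pytest

import ovinepred as op
from ovinepred.containers import GenotypeMatrix
from ovinepred.relmat import RelationshipMatrix


def _geno(calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        ids=np.array(ids if ids else [f"s{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        calls=calls,
    )


def _ped(rows, breeds=("A",)):
    t = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    t["flock"] = "FL1"
    t["birth_year"] = 0
    t["role"] = "founder"
    for b in breeds:
        t[f"breed_{b}"] = 1.0 / len(breeds)
    return op.Pedigree(table=t, breeds=list(breeds))


class TestGRM:
    def test_two_individual_single_snp_by_hand(self):
        # dosages (2, 0): p = 0.5, M = (1, -1), denom = 0.5 -> G = [[2,-2],[-2,2]]
        G = op.compute_grm(_geno([[2], [0]]))
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]], atol=1e-12)

    def test_entries_sum_to_zero(self, rng):
        geno = op.simulate_hwe_genotypes(80, 300, seed=1)
        G = op.compute_grm(geno)
        assert abs(G.values.sum()) < 1e-8

    def test_hwe_population_scale(self):
        geno = op.simulate_hwe_genotypes(1000, 5000, seed=2)
        d = op.scale_diagnostics(op.compute_grm(geno))
        assert 0.97 < d.mean_diagonal < 1.03
        assert abs(d.mean_offdiagonal) < 0.01

    def test_monomorphic_snps_contribute_nothing(self, rng):
        calls = rng.binomial(2, 0.4, size=(30, 100))
        mono = np.hstack([calls, np.full((30, 20), 2, dtype=int)])
        G1 = op.compute_grm(_geno(calls))
        G2 = op.compute_grm(_geno(mono))
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-12)

    def test_all_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            op.compute_grm(_geno(np.full((10, 5), 2)))

    def test_positive_semidefinite(self):
        geno = op.simulate_hwe_genotypes(150, 400, seed=3)
        ev = np.linalg.eigvalsh(op.compute_grm(geno).values)
        assert ev.min() >= -1e-8 * ev.max()

    def test_panel_density_barely_changes_g(self):
        """Dense (m=5000) vs moderate G of the same animals correlate strongly:
        close relatives dominate G, and they need few markers to resolve."""
        cfg = op.PopulationConfig(
            n_breeds=1, breed_labels=("A",), n_snps_dense=5000, n_reference=150,
            n_founders_per_breed=60, divergence_generations=15, effective_size=60,
            n_qtl=100, var_breed=0.0, n_validation_sires_per_breed=4, seed=17,
        )
        geno, ped, truth = op.simulate_population(cfg)
        ids = [i for i in geno.ids if i.startswith("REF")]
        dense = op.subset_density(geno, 1.0, seed=1, exclude_snp_ids=truth.qtl_ids)
        mod = op.subset_density(geno, 0.2, seed=2, exclude_snp_ids=truth.qtl_ids)
        Gd = op.compute_grm(dense.loc_individuals(ids)).values
        Gm = op.compute_grm(mod.loc_individuals(ids)).values
        iu = np.triu_indices(len(ids), k=1)
        assert np.corrcoef(Gd[iu], Gm[iu])[0, 1] > 0.95


class TestNRM:
    def test_unrelated_founders_identity(self):
        A = op.compute_nrm(_ped([["a", "", ""], ["b", "", ""]]))
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_parent_offspring_half(self):
        A = op.compute_nrm(_ped([["p", "", ""], ["q", "", ""], ["o", "p", "q"]]))
        assert A.values[0, 2] == pytest.approx(0.5)
        assert A.values[2, 2] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        rows = [
            ["g1", "", ""], ["g2", "", ""],
            ["s1", "g1", "g2"], ["s2", "g1", "g2"],
            ["x", "s1", "s2"],
        ]
        A = op.compute_nrm(_ped(rows))
        assert A.values[4, 4] == pytest.approx(1.25)  # F = 0.25

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(ValueError):
            _ped([["o", "p", ""], ["p", "", ""]])

    def test_matches_gene_dropping_ibd_oracle(self, rng):
        """Tabular A vs brute-force gene-dropping IBD on a 3-generation family."""
        rows = [
            ["f1", "", ""], ["f2", "", ""], ["f3", "", ""], ["f4", "", ""],
            ["a", "f1", "f2"], ["b", "f1", "f2"], ["c", "f3", "f4"],
            ["d", "a", "c"], ["e", "b", "c"], ["g", "d", "e"],
        ]
        ped = _ped(rows)
        A = op.compute_nrm(ped)
        n_rep = 100_000
        ids = list(ped.ids)
        idx = {v: i for i, v in enumerate(ids)}
        sires = [idx.get(s, -1) for s in ped.table["sire"]]
        dams = [idx.get(d, -1) for d in ped.table["dam"]]
        # drop two distinct founder-allele labels per individual
        alleles = np.empty((n_rep, len(ids), 2), dtype=np.int32)
        counter = 0
        for i in range(len(ids)):
            if sires[i] == -1:
                alleles[:, i, 0] = counter
                alleles[:, i, 1] = counter + 1
                counter += 2
            else:
                pick_s = rng.integers(0, 2, n_rep)
                pick_d = rng.integers(0, 2, n_rep)
                alleles[:, i, 0] = alleles[np.arange(n_rep), sires[i], pick_s]
                alleles[:, i, 1] = alleles[np.arange(n_rep), dams[i], pick_d]
        for i, j in [(idx["d"], idx["e"]), (idx["g"], idx["a"]), (idx["g"], idx["g"])]:
            shared = np.zeros(n_rep)
            for u in range(2):
                for v in range(2):
                    if i == j and u == v:
                        continue
                    shared += alleles[:, i, u] == alleles[:, j, v]
            if i == j:
                est = 1 + 0.5 * shared.mean()  # 1 + F from the two own alleles
            else:
                est = 0.5 * shared.mean()
            assert abs(est - A.values[i, j]) < 0.02


class TestClassifyRelatedness:
    def _grm(self, values, ids):
        return RelationshipMatrix(ids=np.array(ids, dtype=object),
                                  values=np.asarray(values, float), source="markers")

    def test_three_way_partition(self):
        n_ref = 40
        ids = [f"r{i}" for i in range(n_ref)] + ["high", "low", "mid"]
        V = np.eye(n_ref + 3)
        V[:30, n_ref] = V[n_ref, :30] = 0.25      # high: top-30 mean 0.25
        V[:n_ref, n_ref + 1] = V[n_ref + 1, :n_ref] = 0.05  # low: max 0.05
        V[0, n_ref + 2] = V[n_ref + 2, 0] = 0.30  # mid: max 0.3, top-30 mean 0.15
        V[1:5, n_ref + 2] = V[n_ref + 2, 1:5] = 0.15
        groups = op.classify_relatedness(self._grm(V, ids), ids[:n_ref], ids[n_ref:])
        assert groups.high == ["high"]
        assert groups.low == ["low"]
        assert groups.neither == ["mid"]

    def test_small_reference_warns_and_uses_all(self):
        ids = ["r0", "r1", "c"]
        V = np.eye(3)
        V[0, 2] = V[2, 0] = 0.5
        with pytest.warns(UserWarning, match="k_top"):
            groups = op.classify_relatedness(self._grm(V, ids), ids[:2], ["c"])
        assert groups.high == ["c"]  # mean of (0.5, 0) = 0.25 >= 0.2

    def test_overlapping_sets_rejected(self):
        V = np.eye(2)
        with pytest.raises(ValueError):
            op.classify_relatedness(self._grm(V, ["a", "b"]), ["a"], ["a", "b"])


class TestScaleDiagnostics:
    def test_identity(self):
        rel = RelationshipMatrix(
            ids=np.array([f"i{k}" for k in range(5)], dtype=object),
            values=np.eye(5), source="markers",
        )
        d = op.scale_diagnostics(rel)
        assert d.mean_diagonal == 1.0 and d.mean_offdiagonal == 0.0

    def test_two_by_two_arithmetic(self):
        rel = RelationshipMatrix(
            ids=np.array(["a", "b"], dtype=object),
            values=np.array([[2.0, -2.0], [-2.0, 2.0]]), source="markers",
        )
        d = op.scale_diagnostics(rel)
        assert d.mean_diagonal == 2.0 and d.mean_offdiagonal == -2.0

    def test_offdiagonal_identity_for_grm(self):
        geno = op.simulate_hwe_genotypes(60, 200, seed=5)
        G = op.compute_grm(geno)
        d = op.scale_diagnostics(G)
        assert d.mean_offdiagonal == pytest.approx(-d.mean_diagonal / (G.n - 1), abs=1e-8)
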