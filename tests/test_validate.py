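"""Accuracy statistics: closed forms, independent correlation oracle, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovinepred as op
from ovinepred.gblup import PredictionResult


def _pred(ids, gbv, method="GBLUP"):
    return PredictionResult(ids=np.asarray(ids, dtype=object),
                            gbv=np.asarray(gbv, float), method=method)


def _ebv(ids, values):
    return pd.DataFrame({"id": ids, "ebv": values})


def two_pass_corr(x, y):
    """Independent two-pass Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


class TestAccuracy:
    def test_identity_gives_r_and_slope_one(self, rng):
        ids = [f"s{i}" for i in range(20)]
        v = rng.standard_normal(20)
        (res,) = op.accuracy(_pred(ids, v), _ebv(ids, v))
        assert res.r == pytest.approx(1.0)
        assert res.regression_coef == pytest.approx(1.0)

    def test_doubled_prediction_halves_slope(self, rng):
        ids = [f"s{i}" for i in range(20)]
        e = rng.standard_normal(20)
        (res,) = op.accuracy(_pred(ids, 2 * e), _ebv(ids, e))
        assert res.r == pytest.approx(1.0)
        assert res.regression_coef == pytest.approx(0.5)

    def test_se_closed_form(self):
        # r = 0.5, n = 102 -> sqrt(0.75/100)
        rng = np.random.default_rng(1)
        n = 102
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        # force exact r = 0.5 by regression-residual construction
        xr = (x - x.mean()) / x.std()
        resid = y - np.polyval(np.polyfit(xr, y, 1), xr)
        y_exact = 0.5 * xr + np.sqrt(0.75) * (resid - resid.mean()) / resid.std()
        ids = [f"s{i}" for i in range(n)]
        (res,) = op.accuracy(_pred(ids, xr), _ebv(ids, y_exact))
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.75 / 100), abs=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        ids = [f"s{i}" for i in range(40)]
        g = rng.standard_normal(40)
        e = 0.6 * g + rng.standard_normal(40)
        (res,) = op.accuracy(_pred(ids, g), _ebv(ids, e))
        assert res.r == pytest.approx(two_pass_corr(list(g), list(e)), abs=1e-12)

    def test_zero_variance_flagged(self):
        ids = [f"s{i}" for i in range(5)]
        (res,) = op.accuracy(_pred(ids, np.ones(5)), _ebv(ids, np.arange(5.0)))
        assert res.flagged and np.isnan(res.r)

    def test_strain_adjustment_removes_group_means(self, rng):
        """Two strains with a shared mean offset: pooled r is inflated,
        strain-adjusted r reflects the within-strain (zero) signal."""
        n = 60
        ids = [f"s{i}" for i in range(n)]
        strain = {i: ("fine" if k < n // 2 else "strong") for k, i in enumerate(ids)}
        off = np.where(np.arange(n) < n // 2, -2.0, 2.0)
        g = off + rng.standard_normal(n) * 0.3
        e = off + rng.standard_normal(n) * 0.3
        (pooled,) = op.accuracy(_pred(ids, g), _ebv(ids, e))
        (adj,) = op.accuracy(_pred(ids, g), _ebv(ids, e), covariate_adjust=strain)
        assert pooled.r > 0.9
        assert abs(adj.r) < 0.4

    def test_groups_reported_separately(self, rng):
        ids = [f"s{i}" for i in range(30)]
        groups = {i: ("PD" if k < 15 else "WS") for k, i in enumerate(ids)}
        v = rng.standard_normal(30)
        res = op.accuracy(_pred(ids, v), _ebv(ids, v), groups=groups)
        assert {r.group_label for r in res} == {"PD", "WS"}
        assert all(r.n == 15 for r in res)

    @given(st.integers(min_value=5, max_value=500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_se_decreases_in_n_at_fixed_r(self, n):
        se = np.sqrt((1 - 0.5**2) / (n - 2)) if n > 2 else np.inf
        se_next = np.sqrt((1 - 0.5**2) / (n - 1))
        assert se_next < se


class TestStratifiedComparison:
    def test_identical_predictions_give_zero_differences(self, rng):
        ids = [f"s{i}" for i in range(30)]
        v = rng.standard_normal(30)
        e = v + rng.standard_normal(30) * 0.5
        strata = {i: ("high" if k < 15 else "low") for k, i in enumerate(ids)}
        out = op.stratified_comparison(
            {"50k": _pred(ids, v), "HD": _pred(ids, v)}, _ebv(ids, e), strata,
            n_bootstrap=200, seed=1,
        )
        diffs = out.loc[out["comparison"] != "", "diff"]
        assert (diffs.abs() < 1e-12).all()

    def test_bootstrap_interval_covers_point_difference(self, rng):
        ids = [f"s{i}" for i in range(40)]
        e = rng.standard_normal(40)
        g1 = e + rng.standard_normal(40)
        g2 = e + 0.4 * rng.standard_normal(40)
        strata = {i: "all" for i in ids}
        out = op.stratified_comparison(
            {"a": _pred(ids, g1), "b": _pred(ids, g2)}, _ebv(ids, e), strata,
            n_bootstrap=500, seed=2,
        )
        row = out.loc[out["comparison"] == "b - a"].iloc[0]
        assert row["ci_low"] <= row["diff"] <= row["ci_high"]

    def test_small_stratum_flagged(self, rng):
        ids = [f"s{i}" for i in range(12)]
        v = rng.standard_normal(12)
        strata = {i: ("tiny" if k < 4 else "rest") for k, i in enumerate(ids)}
        out = op.stratified_comparison(
            {"a": _pred(ids, v), "b": _pred(ids, v + 0.1)},
            _ebv(ids, v + rng.standard_normal(12)), strata, n_bootstrap=50, seed=3,
        )
        assert out.loc[out["stratum"] == "tiny", "low_n"].all()

    def test_mismatched_ids_rejected(self, rng):
        a = _pred(["x", "y", "z"], rng.standard_normal(3))
        b = _pred(["x", "y", "w"], rng.standard_normal(3))
        with pytest.raises(ValueError, match="same validation ids"):
            op.stratified_comparison(
                {"a": a, "b": b},
                _ebv(["x", "y", "z", "w"], np.arange(4.0)),
                {"x": "s", "y": "s", "z": "s", "w": "s"},
            )


def test_unbiased_blup_regression_near_one():
    """ebv = tbv benchmark: OLS slope of tbv on GBLUP gbv averages ~1 over
    replicates (the BLUP dispersion property)."""
    slopes = []
    for seed in range(10):
        cfg = op.PopulationConfig(
            n_breeds=1, breed_labels=("A",), n_snps_dense=1000, n_reference=400,
            n_founders_per_breed=100, divergence_generations=15, effective_size=80,
            n_qtl=150, var_breed=0.0, n_validation_sires_per_breed=20,
            seed=300 + seed,
        )
        geno, ped, truth = op.simulate_population(cfg)
        design = op.simulate_phenotypes(geno, ped, truth, cfg, seed=400 + seed)
        val = list(ped.table.loc[ped.table["role"] == "validation_sire", "id"])
        dense = op.subset_density(geno, 1.0, seed=1, exclude_snp_ids=truth.qtl_ids)
        G = op.compute_grm(dense.loc_individuals(list(design.animal_ids) + val))
        # marker-based components from REML: the dispersion property needs the
        # variance actually captured by the panel, not the QTL-scale variance
        res = op.fit_reml(design, G)
        pr = op.solve_mme(design, G, res.components, predict_ids=val)
        (res,) = op.accuracy(
            _pred(val, pr.gbv_for(val)),
            _ebv(val, truth.tbv_for(val)),
        )
        slopes.append(res.regression_coef)
    assert abs(np.mean(slopes) - 1.0) < 0.1
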