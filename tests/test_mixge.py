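"""MixGE engine: null fit, burden, variance component, combination, oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytogxe.mixge import (burden_test, combined_test, fit_null_model,
                           mixge_test, permutation_oracle, run_scan,
                           variance_component_test, _interaction_parts)
from cytogxe.synthetic import (GeneSnpSpec, GenotypeSimSpec,
                               simulate_genotypes)


def _instance(n=150, k=4, ld=0.3, seed=0, beta_g=0.1):
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(GenotypeSimSpec(
        n, [GeneSnpSpec("A", k, (0.1, 0.5), ld)], seed=seed + 1)).dosage
    X = rng.standard_normal((n, 3))
    E = rng.normal(8.5, 4.5, n)
    y = X @ np.array([0.3, -0.2, 0.0]) + 0.05 * E \
        + G @ np.full(k, beta_g) + rng.standard_normal(n)
    return y, X, E, G


class TestFitNullModel:
    def test_exact_fit_has_zero_residuals(self):
        y, X, E, G = _instance()
        nf0 = fit_null_model(y, X, E, G)
        y_span = nf0.fitted  # lies exactly in span(Z)
        nf = fit_null_model(y_span, X, E, G)
        assert np.abs(nf.resid).max() < 1e-10

    def test_residual_orthogonality(self):
        y, X, E, G = _instance(seed=3)
        nf = fit_null_model(y, X, E, G)
        assert np.abs(nf.Z.T @ nf.resid).max() < 1e-8 * np.abs(y).max() * len(y)

    def test_duplicated_column_dropped_same_fit(self):
        y, X, E, G = _instance(seed=4)
        nf1 = fit_null_model(y, X, E, G)
        Xdup = np.column_stack([X, X[:, 0]])
        nf2 = fit_null_model(y, Xdup, E, G)
        assert nf2.dropped_cols
        assert np.allclose(nf1.fitted, nf2.fitted, atol=1e-8)

    def test_insufficient_df_raises(self):
        y, X, E, G = _instance(n=8, k=4)
        with pytest.raises(ValueError, match="insufficient df"):
            fit_null_model(y[:8], np.eye(8)[:, :4], E[:8], G[:8])


class TestSingleVariantReduction:
    def test_burden_equals_classical_interaction_t_test(self):
        import statsmodels.api as sm

        y, X, E, G = _instance(k=1, seed=5)
        nf = fit_null_model(y, X, E, G)
        res = burden_test(nf, E, G)
        D = np.column_stack([np.ones_like(y), X, E, G, E * G[:, 0]])
        ref = sm.OLS(y, D).fit()
        assert res["p"] == pytest.approx(ref.pvalues[-1], abs=1e-10)
        assert res["pi_hat"] == pytest.approx(ref.params[-1], abs=1e-10)

    def test_vc_collapses_to_classical_single_term_test(self):
        # the studentized VC null at k=1 is exactly the classical
        # F(1, df-1) = two-sided t interaction test, i.e. the burden p
        y, X, E, G = _instance(k=1, seed=6)
        nf = fit_null_model(y, X, E, G)
        res = variance_component_test(nf, E, G)
        bres = burden_test(nf, E, G)
        assert res["p"] == pytest.approx(bres["p"], abs=1e-10)
        # and approaches the squared-score chi2(1) reference at this n
        b_t, _ = _interaction_parts(nf, E, G)
        z2 = (b_t @ nf.resid) ** 2 / (nf.sigma2 * (b_t @ b_t))
        assert res["p"] == pytest.approx(stats.chi2.sf(z2, 1), abs=5e-3)

    def test_all_three_p_invariant_to_allele_flip(self):
        y, X, E, G = _instance(k=1, seed=7)
        r1 = mixge_test(y, X, E, G, combine_mode="min_p_bonf")
        r2 = mixge_test(y, X, E, 2.0 - G, combine_mode="min_p_bonf")
        assert r1.p_burden == pytest.approx(r2.p_burden, abs=1e-8)
        assert r1.p_vc == pytest.approx(r2.p_vc, abs=1e-8)
        assert r1.p_combined == pytest.approx(r2.p_combined, abs=1e-8)


class TestVarianceComponent:
    def test_zero_environment_degenerate(self):
        y, X, _, G = _instance(seed=8)
        E0 = np.zeros_like(y)
        nf = fit_null_model(y, X, E0, G)
        res = variance_component_test(nf, E0, G)
        assert res["Q"] == 0.0 and res["p"] == 1.0 and res["degenerate"]

    def test_vc_p_invariant_to_any_allele_flips(self):
        y, X, E, G = _instance(k=4, seed=9)
        nf1 = fit_null_model(y, X, E, G)
        G2 = G.copy()
        G2[:, [0, 2]] = 2.0 - G2[:, [0, 2]]
        nf2 = fit_null_model(y, X, E, G2)
        p1 = variance_component_test(nf1, E, G)["p"]
        p2 = variance_component_test(nf2, E, G2)["p"]
        assert p1 == pytest.approx(p2, abs=1e-8)


class TestScaleAndCenteringInvariance:
    def test_rescaling_E_and_Y_leaves_p_unchanged(self):
        y, X, E, G = _instance(seed=10)
        r1 = mixge_test(y, X, E, G, combine_mode="min_p_bonf")
        r2 = mixge_test(3.7 * y, X, 0.2 * E, G, combine_mode="min_p_bonf")
        assert r1.p_burden == pytest.approx(r2.p_burden, rel=1e-9)
        assert r1.p_vc == pytest.approx(r2.p_vc, rel=1e-8)

    def test_centering_E_is_immaterial(self):
        y, X, E, G = _instance(seed=11)
        nf = fit_null_model(y, X, E, G)
        p1 = burden_test(nf, E, G, center_e=True)
        p2 = burden_test(nf, E, G, center_e=False)
        assert p1["p"] == pytest.approx(p2["p"], abs=1e-10)
        assert p1["pi_hat"] == pytest.approx(p2["pi_hat"], abs=1e-10)
        v1 = variance_component_test(nf, E, G, center_e=True)
        v2 = variance_component_test(nf, E, G, center_e=False)
        assert v1["p"] == pytest.approx(v2["p"], abs=1e-8)


class TestCombined:
    def test_min_p_bonf_bounds(self):
        y, X, E, G = _instance(seed=12)
        nf = fit_null_model(y, X, E, G)
        pb = burden_test(nf, E, G)["p"]
        pv = variance_component_test(nf, E, G)["p"]
        pc = combined_test(pb, pv, nf, E, G, mode="min_p_bonf")["p"]
        assert min(pb, pv) <= pc <= 1.0

    def test_too_few_permutations_raise(self):
        y, X, E, G = _instance(seed=13)
        nf = fit_null_model(y, X, E, G)
        with pytest.raises(ValueError):
            combined_test(0.5, 0.5, nf, E, G, n_perm=50)

    def test_fisher_perm_deterministic_given_seed(self):
        y, X, E, G = _instance(seed=14)
        nf = fit_null_model(y, X, E, G)
        pb = burden_test(nf, E, G)["p"]
        pv = variance_component_test(nf, E, G)["p"]
        p1 = combined_test(pb, pv, nf, E, G, n_perm=300, rng=123)["p"]
        p2 = combined_test(pb, pv, nf, E, G, n_perm=300, rng=123)["p"]
        assert p1 == p2


class TestPermutationOracle:
    def test_determinism_and_floor(self):
        y, X, E, G = _instance(seed=15)
        r1 = permutation_oracle(y, X, E, G, n_perm=300, seed=9)
        r2 = permutation_oracle(y, X, E, G, n_perm=300, seed=9)
        assert r1["p_vc"] == r2["p_vc"] and r1["p_combined"] == r2["p_combined"]
        for key in ("p_burden", "p_vc", "p_combined"):
            assert r1[key] >= 1.0 / 301

    def test_agrees_with_analytic_on_small_instances(self):
        for seed, n, k in ((20, 60, 4), (21, 80, 2), (22, 120, 8)):
            y, X, E, G = _instance(n=n, k=k, seed=seed)
            res = permutation_oracle(y, X, E, G, n_perm=4000, seed=1)
            for comp in ("p_burden", "p_vc"):
                p_perm = res[comp]
                p_ana = res["analytic"][comp]
                se = np.sqrt(p_perm * (1 - p_perm) / 4000)
                assert abs(p_ana - p_perm) <= 3 * se + 1e-3


class TestRunScan:
    def _inputs(self, n=120, seed=30):
        rng = np.random.default_rng(seed)
        G = simulate_genotypes(GenotypeSimSpec(
            n, [GeneSnpSpec("G1", 3), GeneSnpSpec("G2", 2),
                GeneSnpSpec("G3", 4), GeneSnpSpec("G4", 2),
                GeneSnpSpec("G5", 3)], seed=seed))
        X = rng.standard_normal((n, 2))
        E = rng.normal(8.5, 4.5, n)
        measures = pd.DataFrame({
            m: rng.standard_normal(n)
            for m in ("HIP_L", "HIP_R", "AMY_L", "AMY_R")})
        gene_map = {"HIP": [("G1", "up", 0.001), ("G2", "down", 0.002)],
                    "AMY": [("G3", "up", 0.001), ("G4", "up", 0.003),
                            ("G5", "down", 0.004)]}
        region_measures = {"HIP": ["HIP_L", "HIP_R"],
                           "AMY": ["AMY_L", "AMY_R"]}
        return gene_map, G, X, E, measures, region_measures

    def test_pair_count(self):
        gm, G, X, E, meas, rm = self._inputs()
        out = run_scan(gm, G, X, E, meas, rm, combine_mode="min_p_bonf")
        assert len(out) == 2 * 2 + 3 * 2 == 10
        assert set(out["hemisphere"]) == {"L", "R"}

    def test_subject_shuffle_invariance(self):
        gm, G, X, E, meas, rm = self._inputs()
        out1 = run_scan(gm, G, X, E, meas, rm, combine_mode="min_p_bonf")
        perm = np.random.default_rng(0).permutation(len(E))
        from dataclasses import replace

        G2 = replace(G, subjects=[G.subjects[i] for i in perm],
                     dosage=G.dosage[perm])
        out2 = run_scan(gm, G2, X[perm], E[perm],
                        meas.iloc[perm].reset_index(drop=True), rm,
                        combine_mode="min_p_bonf")
        assert np.allclose(out1["p_combined"], out2["p_combined"], atol=1e-9)

    def test_unmapped_gene_and_measure_errors(self):
        gm, G, X, E, meas, rm = self._inputs()
        bad = dict(gm)
        bad["HIP"] = bad["HIP"] + [("NOSUCH", "up", 0.001)]
        with pytest.raises(KeyError, match="NOSUCH"):
            run_scan(bad, G, X, E, meas, rm)
        with pytest.raises(KeyError, match="OFC"):
            run_scan({"OFC": [("G1", "up", 0.001)]}, G, X, E, meas,
                     {"OFC": ["OFC_L"]})

    def test_detects_planted_interaction(self):
        gm, G, X, E, meas, rm = self._inputs(n=400, seed=31)
        Gm = G.gene_matrix("G3")
        meas = meas.copy()
        meas["AMY_R"] = (meas["AMY_R"]
                         + 0.02 * (E - E.mean()) * (Gm - Gm.mean(0)).sum(1))
        out = run_scan(gm, G, X, E, meas, rm, n_perm=300, seed=5)
        best = out.sort_values("p_combined").iloc[0]
        assert (best["gene_id"], best["measure"]) == ("G3", "AMY_R")
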