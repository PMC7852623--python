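"""Generators: marginal calibration, determinism, generative/analytic agreement."""

import numpy as np
import pytest
from scipy import stats

from cytogxe.cohort import encode_covariates
from cytogxe.mixge import burden_test, fit_null_model, variance_component_test
from cytogxe.screen import _huber_irls
from cytogxe.synthetic import (ExpressionSimSpec, GeneSnpSpec, GeneTrend,
                               GenotypeSimSpec, OutcomeSimSpec,
                               simulate_cohort, simulate_expression,
                               simulate_genotypes, simulate_outcome)


class TestSimulateExpression:
    def test_noise_free_limit_recovers_slope(self):
        spec = ExpressionSimSpec(
            n_samples=10, genes=[GeneTrend("G1", "AMY", -0.5, intercept=2.0,
                                           noise_sd=1e-300)],
            regions=["AMY"], seed=0)
        X = simulate_expression(spec)
        ages = X.meta["age_pcw"].to_numpy()
        slope, icpt = np.polyfit(ages, X.data["G1"].to_numpy(), 1)
        assert slope == pytest.approx(-0.5, abs=1e-9)
        assert icpt == pytest.approx(2.0, abs=1e-7)

    def test_null_gene_p_uniform_over_seeds(self):
        # beta1 = 0: the screen p-value is Uniform(0,1) across seeds
        ps = []
        ages = np.linspace(8, 26, 100)
        for seed in range(500):
            X = simulate_expression(ExpressionSimSpec(
                n_samples=100, genes=[GeneTrend("G1", "AMY", 0.0)],
                regions=["AMY"], seed=seed))
            _, b1, se, _ = _huber_irls(ages, X.data["G1"].to_numpy())
            ps.append(2 * stats.t.sf(abs(b1 / se), 98))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_determinism(self):
        spec = ExpressionSimSpec(
            n_samples=8, genes=[GeneTrend("G1", "HIP", 0.3,
                                          outlier_fraction=0.2)],
            all_genes=["G1", "G2"], seed=42)
        X1 = simulate_expression(spec)
        X2 = simulate_expression(spec)
        assert X1.data.equals(X2.data) and X1.meta.equals(X2.meta)

    @pytest.mark.parametrize("field,kwargs", [
        ("age_range", dict(age_range=(26.0, 8.0))),
        ("noise_sd", dict(genes=[GeneTrend("G", "AMY", 0.1, noise_sd=0.0)])),
        ("outlier_fraction",
         dict(genes=[GeneTrend("G", "AMY", 0.1, outlier_fraction=0.7)])),
    ])
    def test_invalid_spec_names_field(self, field, kwargs):
        with pytest.raises(ValueError, match=field):
            simulate_expression(ExpressionSimSpec(**kwargs))


class TestSimulateGenotypes:
    def test_hwe_frequencies_at_half(self):
        G = simulate_genotypes(GenotypeSimSpec(
            10000, [GeneSnpSpec("A", 1, (0.5, 0.5), 0.0)], seed=1))
        freqs = [(G.dosage[:, 0] == g).mean() for g in (0, 1, 2)]
        se = np.sqrt(np.array([0.25, 0.5, 0.25])
                     * (1 - np.array([0.25, 0.5, 0.25])) / 10000)
        assert np.all(np.abs(freqs - np.array([0.25, 0.5, 0.25])) < 3 * se)

    def test_ld_within_gene_exceeds_between(self):
        G = simulate_genotypes(GenotypeSimSpec(
            4000, [GeneSnpSpec("A", 5, (0.2, 0.4), 0.9),
                   GeneSnpSpec("B", 5, (0.2, 0.4), 0.9)], seed=2))
        C = np.corrcoef(G.dosage.T)
        within = np.mean([C[i, j] for i in range(5) for j in range(5) if i < j])
        across = np.mean([abs(C[i, j]) for i in range(5) for j in range(5, 10)])
        assert within > 0.4 > across

    def test_no_missing_when_rate_zero(self, small_genotypes):
        assert not np.isnan(small_genotypes.dosage).any()

    def test_missing_rate_and_maf_calibrated(self):
        G = simulate_genotypes(GenotypeSimSpec(
            10000, [GeneSnpSpec("A", 4, (0.3, 0.3), 0.2)],
            missing_rate=0.1, seed=3))
        miss = np.isnan(G.dosage).mean()
        assert abs(miss - 0.1) < 4 * np.sqrt(0.1 * 0.9 / G.dosage.size)
        maf = np.nanmean(G.dosage, axis=0) / 2
        assert np.all(np.abs(maf - 0.3)
                      < 4 * np.sqrt(0.3 * 0.7 / (2 * 10000)) + 0.01)

    def test_determinism_and_validation(self):
        spec = GenotypeSimSpec(100, [GeneSnpSpec("A", 3)], 0.05, seed=9)
        G1, G2 = simulate_genotypes(spec), simulate_genotypes(spec)
        assert np.allclose(G1.dosage, G2.dosage, equal_nan=True)
        with pytest.raises(ValueError):
            simulate_genotypes(GenotypeSimSpec(1, [GeneSnpSpec("A", 2)]))
        with pytest.raises(ValueError):
            simulate_genotypes(GenotypeSimSpec(
                10, [GeneSnpSpec("A", 2, (0.0, 0.4))]))


class TestSimulateCohort:
    def test_epds_marginals(self):
        c = simulate_cohort(10000, seed=4)
        tot = c["epds_total"]
        assert 8.0 <= tot.mean() <= 9.2
        assert abs(tot.std(ddof=1) - 4.5) < 4 * 4.5 / np.sqrt(2 * 10000)
        assert tot.between(0, 30).all()

    def test_no_exclusions_by_default(self):
        from cytogxe.cohort import apply_exclusions

        c = simulate_cohort(300, seed=5)
        kept, audit = apply_exclusions(c)
        assert len(kept) == 300

    def test_determinism(self):
        assert simulate_cohort(50, seed=6).equals(simulate_cohort(50, seed=6))

    def test_ethnicity_proportions(self):
        c = simulate_cohort(20000, seed=7)
        pct = c["ethnicity"].value_counts(normalize=True)
        assert pct["chinese"] == pytest.approx(0.4534, abs=0.02)
        assert pct["malay"] == pytest.approx(0.4162, abs=0.02)


class TestSimulateOutcome:
    def test_noise_free_single_snp_formula(self, small_cohort):
        G = simulate_genotypes(GenotypeSimSpec(
            200, [GeneSnpSpec("A", 1, (0.3, 0.3))], seed=8)).dosage
        spec = OutcomeSimSpec(beta_X=0.0, beta_E=0.2, beta_G=0.5, pi=1.0,
                              tau=0.0, sigma=1e-300, seed=0)
        out, truth = simulate_outcome(G, small_cohort, spec)
        E = small_cohort["epds_total"].to_numpy()
        expect = 0.2 * E + 0.5 * G[:, 0] + 1.0 * E * G[:, 0]
        assert np.allclose(out["y_sim"].to_numpy(), expect, atol=1e-8)

    def test_generative_analytic_pi_agreement(self, small_cohort):
        # tau=0, single SNP, (near) noise-free: burden pi-hat == spec.pi
        G = simulate_genotypes(GenotypeSimSpec(
            200, [GeneSnpSpec("A", 1, (0.3, 0.4))], seed=12)).dosage
        spec = OutcomeSimSpec(beta_X=0.3, beta_E=0.1, beta_G=0.2, pi=0.7,
                              tau=0.0, sigma=1e-12, seed=1)
        out, _ = simulate_outcome(G, small_cohort, spec)
        X = encode_covariates(small_cohort).to_numpy()
        E = small_cohort["epds_total"].to_numpy()
        nf = fit_null_model(out["y_sim"].to_numpy(), X, E, G)
        res = burden_test(nf, E, G)
        assert res["pi_hat"] == pytest.approx(0.7, rel=1e-10)

    def test_null_component_pvalues_uniform(self):
        ps_b, ps_v = [], []
        for rep in range(500):
            cohort = simulate_cohort(150, seed=30000 + rep)
            G = simulate_genotypes(GenotypeSimSpec(
                150, [GeneSnpSpec("A", 4, (0.1, 0.5), 0.3)],
                seed=31000 + rep)).dosage
            out, _ = simulate_outcome(
                G, cohort, OutcomeSimSpec(pi=0.0, tau=0.0, sigma=1.0,
                                          seed=32000 + rep))
            X = encode_covariates(cohort).to_numpy()
            E = cohort["epds_total"].to_numpy()
            nf = fit_null_model(out["y_sim"].to_numpy(), X, E, G)
            ps_b.append(burden_test(nf, E, G)["p"])
            ps_v.append(variance_component_test(nf, E, G)["p"])
        assert stats.kstest(ps_b, "uniform").pvalue > 0.01
        assert stats.kstest(ps_v, "uniform").pvalue > 0.01

    def test_vc_power_under_heterogeneous_effects(self):
        # tau=1, pi=0 at n=500, 10 SNPs, maf 0.3: with an EPDS-scaled E the
        # heterogeneous signal is overwhelming; power is ~1 (frozen by
        # calibration simulation)
        hits = 0
        for rep in range(40):
            cohort = simulate_cohort(500, seed=40000 + rep)
            G = simulate_genotypes(GenotypeSimSpec(
                500, [GeneSnpSpec("A", 10, (0.3, 0.3))],
                seed=41000 + rep)).dosage
            out, _ = simulate_outcome(
                G, cohort, OutcomeSimSpec(pi=0.0, tau=1.0, sigma=1.0,
                                          seed=42000 + rep))
            X = encode_covariates(cohort).to_numpy()
            E = cohort["epds_total"].to_numpy()
            nf = fit_null_model(out["y_sim"].to_numpy(), X, E, G)
            hits += variance_component_test(nf, E, G)["p"] < 0.05
        assert hits / 40 > 0.5

    def test_dimension_mismatch_raises(self, small_cohort):
        with pytest.raises(ValueError):
            simulate_outcome(np.zeros((10, 2)), small_cohort,
                             OutcomeSimSpec())

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            OutcomeSimSpec(tau=-1.0).validate()
        with pytest.raises(ValueError):
            OutcomeSimSpec(sigma=0.0).validate()
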