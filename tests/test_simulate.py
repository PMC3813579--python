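"""Tests of the penetrance models, calibration, sampling and LD tagging."""

import math

import numpy as np
import pytest

from supramult.simulate import (
    DominanceSemiNullModel,
    LplmModel,
    ModelConfigurationError,
    MultiplicativeModel,
    PairwiseSemiNullModel,
    RecessiveModel,
    TaggingConfig,
    assign_modified_weights,
    calibrate_lplm_threshold,
    draw_population_genotypes,
    load_distribution,
    make_tagged_proxies,
    marginal_allelic_effect,
    model_from_config,
    penetrance,
    sample_case_control,
)


class TestHweDraws:
    def test_allele_frequency_within_3se(self):
        q = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        G = draw_population_genotypes(q, 10_000, seed=0)
        qhat = G.values.mean(axis=0) / 2
        se = np.sqrt(q * (1 - q) / (2 * 10_000))
        assert (np.abs(qhat - q) < 3 * se).all()

    def test_genotype_frequencies_near_hwe(self):
        G = draw_population_genotypes([0.5, 0.5], 40_000, seed=1)
        counts = np.array(
            [(G.values[:, 0] == k).mean() for k in (0, 1, 2)]
        )
        np.testing.assert_allclose(counts, [0.25, 0.5, 0.25], atol=0.01)

    def test_near_fixed_allele(self):
        G = draw_population_genotypes([0.999, 0.999], 2000, seed=2)
        assert G.values.mean() > 1.98


class TestPenetranceModels:
    def test_recessive_presets(self):
        m = RecessiveModel.rez_a()
        assert penetrance(m, np.array([2, 2, 2])) == pytest.approx(0.20)
        assert penetrance(m, np.array([2, 2, 1])) == pytest.approx(0.03)
        assert RecessiveModel.rez_b().high_penetrance == 0.70
        assert RecessiveModel.rez_c().q.tolist() == [0.4, 0.5, 0.6]
        assert RecessiveModel.rez_d().high_penetrance == 0.05

    def test_lplm_threshold_boundary(self):
        m = LplmModel.calibrated(30, p1=0.5)
        at = np.full(30, m.threshold / 30)  # load exactly at the threshold
        below = np.full(30, (m.threshold - 1) / 30)
        assert penetrance(m, at) == pytest.approx(m.p1)
        assert penetrance(m, below) == pytest.approx(0.03)

    def test_p1_must_exceed_baseline(self):
        with pytest.raises(ModelConfigurationError):
            LplmModel(q=np.full(10, 0.5), threshold=12, p1=0.01, f0=0.03)

    def test_risk_scale_multiplicative_formula(self):
        m = MultiplicativeModel(
            q=np.array([0.5, 0.5]), allele_rr=np.array([1.3, 1.4]),
            baseline=0.02, scale="risk",
        )
        assert penetrance(m, np.array([1, 2])) == pytest.approx(
            0.02 * 1.3 * 1.4**2
        )
        assert m.prevalence() == pytest.approx(
            0.02 * (0.5 + 0.5 * 1.3) ** 2 * (0.5 + 0.5 * 1.4) ** 2
        )

    def test_odds_scale_null_prevalence_calibration(self):
        model = MultiplicativeModel.draw_null(20, np.random.default_rng(0))
        G = draw_population_genotypes(model.q, 100_000, seed=3)
        prev_mc = model.penetrance(G.values).mean()
        assert prev_mc == pytest.approx(model.prevalence(), abs=3 * 7e-4)


class TestCalibration:
    def test_ten_snps_exact_binomial_tail(self):
        cal = calibrate_lplm_threshold([0.5] * 10)
        assert cal.threshold == 15.0
        assert cal.tail == pytest.approx(21700 / 2**20, rel=1e-12)

    def test_single_snp_reports_best_available(self):
        cal = calibrate_lplm_threshold([0.5])
        assert cal.threshold == 2.0
        assert cal.tail == pytest.approx(0.25)

    def test_weighted_convolution_matches_monte_carlo(self):
        q = np.full(9, 0.4)
        w = assign_modified_weights(9)
        support, probs = load_distribution(q, w)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        cal = calibrate_lplm_threshold(q, w)
        rng = np.random.default_rng(4)
        loads = rng.binomial(2, q, size=(200_000, 9)) @ w
        mc_tail = np.mean(loads >= cal.threshold)
        se = math.sqrt(cal.tail * (1 - cal.tail) / 200_000)
        assert mc_tail == pytest.approx(cal.tail, abs=3 * se)

    def test_frequencies_must_be_interior(self):
        with pytest.raises(ModelConfigurationError, match="frequencies"):
            calibrate_lplm_threshold([0.0, 0.5])


class TestModifiedWeights:
    def test_thirds_for_thirty(self):
        w = assign_modified_weights(30)
        assert (w[:10] == 0.5).all() and (w[10:20] == 1.0).all() and (w[20:] == 2.0).all()
        assert w.sum() == pytest.approx(35.0)

    def test_three_snps(self):
        assert assign_modified_weights(3).tolist() == [0.5, 1.0, 2.0]


class TestSampling:
    def test_quota_exactness_and_reproducibility(self):
        m = RecessiveModel.rez_a()
        rep1 = sample_case_control(m, 500, 700, seed=9)
        rep2 = sample_case_control(m, 500, 700, seed=9)
        assert rep1.n_cases == 500 and rep1.n_controls == 700
        np.testing.assert_array_equal(rep1.genotypes.values, rep2.genotypes.values)
        np.testing.assert_array_equal(rep1.phenotype, rep2.phenotype)

    def test_cases_enriched_for_high_risk_genotype(self):
        rep = sample_case_control(RecessiveModel.rez_a(), 2000, 2000, seed=10)
        hom = (rep.genotypes.values > 1.5).all(axis=1)
        case_frac = hom[rep.phenotype == 1].mean()
        assert case_frac > 2 * 0.0064  # population fraction 0.2^2 * 0.5^2 * 0.8^2

    def test_null_lplm_rejected(self):
        # p1 == f0 is not a valid LPLM: the threshold must raise risk
        with pytest.raises(ModelConfigurationError):
            LplmModel(q=np.full(10, 0.5), threshold=12, p1=0.03, f0=0.03)

    def test_tiny_prevalence_advises_enrichment(self):
        m = RecessiveModel(
            q=np.array([0.01, 0.01, 0.01]), high_penetrance=0.5, f0=0.00005
        )
        with pytest.raises(ModelConfigurationError, match="enrich"):
            sample_case_control(m, 10, 10, seed=0)

    def test_prevalence_conservation_monte_carlo(self):
        for m in (RecessiveModel.rez_c(), LplmModel.calibrated(12, p1=0.3)):
            G = draw_population_genotypes(m.q, 150_000, seed=6)
            mc = m.penetrance(G.values).mean()
            se = math.sqrt(m.prevalence() * (1 - m.prevalence()) / 150_000)
            assert mc == pytest.approx(m.prevalence(), abs=3 * se)


class TestTagging:
    def test_r2_one_reproduces_causal(self):
        G = draw_population_genotypes([0.3, 0.6], 500, seed=12)
        prox = make_tagged_proxies(G, [0.3, 0.6], 1.0, seed=13)
        np.testing.assert_array_equal(prox.values, G.values)

    def test_empirical_r2_matches_target(self):
        q = [0.2, 0.5, 0.7]
        G = draw_population_genotypes(q, 50_000, seed=14)
        prox = make_tagged_proxies(G, q, 0.8, seed=15)
        for j in range(3):
            r = np.corrcoef(G.values[:, j], prox.values[:, j])[0, 1]
            assert r**2 == pytest.approx(0.8, abs=0.01)

    def test_low_r2_near_independence(self):
        G = draw_population_genotypes([0.5, 0.5], 30_000, seed=16)
        prox = make_tagged_proxies(G, [0.5, 0.5], 1e-6, seed=17)
        r = np.corrcoef(G.values[:, 0], prox.values[:, 0])[0, 1]
        assert abs(r) < 0.02

    def test_infeasible_r2_reports_bound(self):
        G = draw_population_genotypes([0.05, 0.05], 100, seed=18)
        cfg = TaggingConfig(r2=0.9, proxy_freqs=np.array([0.9, 0.9]))
        with pytest.raises(ValueError, match="maximum achievable"):
            make_tagged_proxies(G, [0.05, 0.05], cfg, seed=19)


class TestMarginalEffects:
    def test_rez_printed_ranges(self):
        """Exact enumeration brackets the published allelic RR ranges (+-0.01)."""
        printed = {
            "rez_a": (1.05, 1.19),
            "rez_b": (1.03, 1.06),
            "rez_c": (1.05, 1.08),
            "rez_d": (1.10, 1.13),
        }
        for name, (lo, hi) in printed.items():
            m = getattr(RecessiveModel, name)()
            vals = [
                marginal_allelic_effect(m, i).relative_risk for i in range(3)
            ]
            assert min(vals) >= lo - 0.01 and max(vals) <= hi + 0.01

    def test_rez_a_strongest_snp(self):
        eff = marginal_allelic_effect(RecessiveModel.rez_a(), 0)
        assert eff.relative_risk == pytest.approx(1.181, abs=0.005)
        assert eff.odds_ratio == pytest.approx(1.188, abs=0.005)

    def test_unit_relative_risks_under_no_effect(self):
        m = MultiplicativeModel(
            q=np.array([0.3, 0.7]), allele_rr=np.array([1.0, 1.0]),
            baseline=0.05, scale="risk",
        )
        eff = marginal_allelic_effect(m, 0)
        assert eff.relative_risk == pytest.approx(1.0)
        assert eff.odds_ratio == pytest.approx(1.0)

    def test_lplm_marginal_shrinks_with_set_size(self):
        small = LplmModel.calibrated(10, p1=0.5)
        large = LplmModel.calibrated(40, p1=0.5)
        rr_small = marginal_allelic_effect(small, 0).relative_risk
        rr_large = marginal_allelic_effect(large, 0).relative_risk
        assert rr_large < rr_small


class TestModelFromConfig:
    def test_presets_and_factories(self):
        assert isinstance(model_from_config({"variant": "rez-a"}), RecessiveModel)
        lplm = model_from_config({"variant": "lplm", "n_snps": 10, "p1": 0.5})
        assert isinstance(lplm, LplmModel) and lplm.weights is None
        wl = model_from_config({"variant": "wlplm", "n_snps": 9, "p1": 0.5})
        assert wl.variant == "weighted_lplm"
        factory = model_from_config({"variant": "null", "n_snps": 5})
        model = factory(np.random.default_rng(0))
        assert isinstance(model, MultiplicativeModel)
        b1 = model_from_config({"variant": "b1", "hom_rr": 2.0, "n_snps": 8,
                                "n_recessive": 4})(np.random.default_rng(1))
        assert isinstance(b1, DominanceSemiNullModel)
        b2 = model_from_config({"variant": "b2", "pair_rr": 3.0, "n_snps": 8,
                                "n_pairs": 2})(np.random.default_rng(2))
        assert isinstance(b2, PairwiseSemiNullModel)

    def test_semi_null_effect_sizes_required(self):
        with pytest.raises((ModelConfigurationError, TypeError)):
            model_from_config({"variant": "b1", "n_snps": 8})(
                np.random.default_rng(0)
            )
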