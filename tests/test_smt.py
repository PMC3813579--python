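"""Tests of the allele load, threshold scan and Bonferroni correction."""

import numpy as np
import pytest

from supramult.regression import CollinearityError
from supramult.simulate import RecessiveModel, sample_case_control
from supramult.smt import (
    GenotypeMatrix,
    RiskAlleleSpec,
    _two_by_two,
    adjusted_smt,
    compute_allele_load,
    orient_to_risk_alleles,
    smt_test,
    threshold_profile,
    valid_thresholds,
)


class TestAlleleLoad:
    def test_maximum_load_all_homozygous(self):
        G = GenotypeMatrix(np.full((3, 10), 2.0), tuple(f"s{i}" for i in range(10)))
        spec = RiskAlleleSpec.from_lists(G.snp_ids, ["A"] * 10)
        assert compute_allele_load(G, spec).tolist() == [20.0, 20.0, 20.0]

    def test_orientation_flip_minor_counted(self):
        # file counts the minor allele; count 0 with risk = major -> 2
        G = GenotypeMatrix(
            np.array([[0.0, 1.0]]),
            ("rs1", "rs2"),
            counted_alleles=(("T", "C"), ("A", "G")),
            oriented=False,
        )
        spec = RiskAlleleSpec.from_lists(["rs1", "rs2"], ["C", "A"])
        L = compute_allele_load(G, spec)
        assert L.tolist() == [3.0]  # flipped 0 -> 2, plus unflipped 1

    def test_weighted_load(self):
        G = GenotypeMatrix(np.array([[2.0, 1.0, 1.0]]), ("a", "b", "c"))
        spec = RiskAlleleSpec.from_lists(["a", "b", "c"], "AAA", [0.5, 1.0, 2.0])
        assert compute_allele_load(G, spec).tolist() == [4.0]

    def test_missing_snp_in_spec_errors(self):
        G = GenotypeMatrix(np.zeros((2, 2)), ("a", "b"))
        spec = RiskAlleleSpec.from_lists(["a"], ["A"])
        with pytest.raises(KeyError, match="b"):
            compute_allele_load(G, spec)

    def test_unknown_risk_allele_errors(self, toy_genotypes):
        G, _ = toy_genotypes
        bad = RiskAlleleSpec.from_lists(["rs1", "rs2", "rs3"], ["A", "X", "G"])
        with pytest.raises(ValueError, match="rs2"):
            compute_allele_load(G, bad)

    def test_orientation_idempotent(self, toy_genotypes):
        G, spec = toy_genotypes
        once = orient_to_risk_alleles(G, spec)
        twice = orient_to_risk_alleles(once, spec)
        np.testing.assert_array_equal(once.values, twice.values)


class TestValidThresholds:
    def test_consecutive_integer_loads(self):
        assert valid_thresholds(np.array([0, 1, 2, 3, 4])).tolist() == [1, 2, 3, 4]

    def test_degenerate_all_equal(self):
        assert valid_thresholds(np.array([5.0, 5.0, 5.0])).size == 0

    def test_each_threshold_splits_sample(self):
        rng = np.random.default_rng(3)
        L = rng.choice([0.0, 0.5, 1.0, 2.5, 4.0], size=50)
        for T in valid_thresholds(L):
            assert (L >= T).any() and (L < T).any()


class TestTwoByTwo:
    def test_closed_form_odds_ratio(self):
        # cases 40/60 above/below, controls 20/80
        above = np.array([True] * 40 + [False] * 60 + [True] * 20 + [False] * 80)
        cases = np.array([True] * 100 + [False] * 100)
        or_, se, flag = _two_by_two(above, cases)
        assert or_ == pytest.approx((40 * 80) / (60 * 20), rel=1e-12)
        assert se == pytest.approx(np.sqrt(1 / 40 + 1 / 60 + 1 / 20 + 1 / 80))
        assert flag == ""

    def test_haldane_correction_on_zero_cell(self):
        above = np.array([True] * 5 + [False] * 15)
        cases = np.array([True] * 10 + [False] * 10)  # no controls above
        or_, se, flag = _two_by_two(above, cases)
        assert flag == "haldane"
        assert np.isfinite(or_) and np.isfinite(se)

    def test_equal_frequencies_give_unit_odds_ratio(self):
        above = np.array([True, False] * 20)
        cases = np.array([True] * 20 + [False] * 20)
        or_, _, _ = _two_by_two(above, cases)
        assert or_ == pytest.approx(1.0)


class TestSmtTest:
    def test_bonferroni_identity_and_profile_shape(self, rez_a_replicate):
        rep = rez_a_replicate
        res = smt_test(rep.genotypes, rep.phenotype, rep.spec)
        prof = res.profile.data
        assert res.v == len(prof)
        assert res.p_final == pytest.approx(
            min(1.0, res.v * prof["p_value"].min())
        )
        assert res.p_final >= prof["p_value"].min()
        t = prof["threshold"].to_numpy()
        assert (np.diff(t) > 0).all()

    def test_published_scan_arithmetic(self):
        """Nine valid thresholds, minimum clean p 9.16e-4 -> corrected 8.24e-3."""
        clean_p = [2.23e-2, 9.16e-4, 3.20e-1, 2.72e-2, 1.51e-1]
        v = 9
        assert min(1.0, v * min(clean_p)) == pytest.approx(8.244e-3)

    def test_permutation_invariance(self, rez_a_replicate):
        rep = rez_a_replicate
        res1 = smt_test(rep.genotypes, rep.phenotype, rep.spec)
        rng = np.random.default_rng(5)
        perm = rng.permutation(rep.genotypes.n_individuals)
        G2 = GenotypeMatrix(
            rep.genotypes.values[perm], rep.genotypes.snp_ids
        )
        res2 = smt_test(G2, rep.phenotype[perm], rep.spec)
        assert res1.p_final == pytest.approx(res2.p_final, rel=1e-9)
        assert res1.v == res2.v
        assert res1.best_threshold == res2.best_threshold

    def test_degenerate_loads_give_p_one(self):
        G = GenotypeMatrix(np.ones((40, 2)), ("a", "b"))
        spec = RiskAlleleSpec.from_lists(["a", "b"], "AA")
        y = np.array([0.0, 1.0] * 20)
        with pytest.warns(UserWarning, match="identical allele load"):
            res = smt_test(G, y, spec)
        assert res.p_final == 1.0
        assert res.v == 0 and "no_valid_thresholds" in res.flags

    def test_indicator_collinear_with_covariate(self, rez_a_replicate):
        rep = rez_a_replicate
        L = compute_allele_load(rep.genotypes, rep.spec)
        T = np.unique(L)[2]
        ind = (L >= T).astype(float)
        with pytest.raises(CollinearityError, match="threshold"):
            smt_test(
                rep.genotypes,
                rep.phenotype,
                rep.spec,
                extra_covariates={"known_indicator": ind},
            )

    def test_set_size_cap(self):
        G = GenotypeMatrix(np.zeros((4, 501)), tuple(f"s{i}" for i in range(501)))
        spec = RiskAlleleSpec.from_lists(G.snp_ids, ["A"] * 501)
        with pytest.raises(ValueError, match="maximum"):
            smt_test(G, np.array([0, 1, 0, 1.0]), spec)

    def test_wald_inference_mode_runs(self, rez_a_replicate):
        rep = rez_a_replicate
        res = smt_test(rep.genotypes, rep.phenotype, rep.spec, inference="wald")
        assert 0.0 <= res.p_final <= 1.0


class TestThresholdProfile:
    def test_profile_equals_smt_profile(self, rez_a_replicate):
        rep = rez_a_replicate
        prof = threshold_profile(rep.genotypes, rep.phenotype, rep.spec)
        res = smt_test(rep.genotypes, rep.phenotype, rep.spec)
        np.testing.assert_allclose(
            prof.data["p_value"], res.profile.data["p_value"]
        )

    def test_frequencies_are_above_threshold_rates(self, rez_a_replicate):
        rep = rez_a_replicate
        prof = threshold_profile(rep.genotypes, rep.phenotype, rep.spec).data
        L = compute_allele_load(rep.genotypes, rep.spec)
        y = rep.phenotype
        row = prof.iloc[2]
        T = row["threshold"]
        assert row["freq_cases"] == pytest.approx(np.mean(L[y == 1] >= T))
        assert row["freq_controls"] == pytest.approx(np.mean(L[y == 0] >= T))


class TestAdjustedSmt:
    def test_empty_adjustment_is_noop(self, rez_a_replicate):
        rep = rez_a_replicate
        plain = smt_test(rep.genotypes, rep.phenotype, rep.spec)
        adj = adjusted_smt(rep.genotypes, rep.phenotype, rep.spec)
        assert adj.p_final == pytest.approx(plain.p_final, rel=1e-10)

    def test_duplicate_adjustment_rejected(self, rez_a_replicate):
        rep = rez_a_replicate
        ids = rep.genotypes.snp_ids
        with pytest.raises(ValueError, match="duplicate"):
            adjusted_smt(
                rep.genotypes, rep.phenotype, rep.spec,
                interaction_pairs=[(ids[0], ids[1]), (ids[1], ids[0])],
            )

    def test_dominance_adjustment_changes_null_model(self, rez_a_replicate):
        rep = rez_a_replicate
        plain = smt_test(rep.genotypes, rep.phenotype, rep.spec)
        adj = adjusted_smt(
            rep.genotypes, rep.phenotype, rep.spec,
            dominance_snps=rep.genotypes.snp_ids,
        )
        assert adj.v == plain.v
        assert adj.p_final != plain.p_final
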