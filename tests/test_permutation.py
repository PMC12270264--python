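"""Permutation null, normalization, p-values, BH, determinism."""

import numpy as np
import pytest

from gbnea import (DataValidationError, GeneSetCollection, PermutationConfig,
                   RegressionConfig, bh_correction, normalize_scores,
                   null_distribution, permutation_pvalue, permute_labels,
                   run_enrichment)
from conftest import make_dataset
from oracles import bh_stepup, tail_count_pvalue

FAST_REG = RegressionConfig(cd_max_sweeps=30)


class TestPermuteLabels:
    def test_two_samples_give_both_orders(self):
        seen = {permute_labels(("C", "N"), np.random.default_rng(s))
                for s in range(40)}
        assert seen == {("C", "N"), ("N", "C")}

    def test_multiset_preserved(self, rng):
        labels = ("C",) * 7 + ("N",) * 4
        permuted = permute_labels(labels, rng)
        assert sorted(permuted) == sorted(labels)

    def test_seeded_reproducibility(self):
        a = permute_labels(("C",) * 5 + ("N",) * 5,
                           np.random.default_rng(11))
        b = permute_labels(("C",) * 5 + ("N",) * 5,
                           np.random.default_rng(11))
        assert a == b

    def test_single_level_rejected(self, rng):
        with pytest.raises(DataValidationError, match="two phenotype"):
            permute_labels(("C", "C", "C"), rng)


class TestNormalizeScores:
    def test_positive_rescaling_arithmetic(self):
        nes, nes_null = normalize_scores(
            {"pw": 0.6}, {"pw": np.array([0.3, 0.4, 0.2, -0.5])})
        assert nes["pw"] == pytest.approx(0.6 / 0.3)

    def test_self_normalization_to_one(self):
        null = np.full(10, 0.4)
        nes, nes_null = normalize_scores({"pw": 0.4}, {"pw": null})
        assert nes["pw"] == pytest.approx(1.0)
        np.testing.assert_allclose(nes_null["pw"], 1.0)

    def test_sign_preserved(self, rng):
        null = rng.standard_normal(50)
        for obs in (-0.7, -0.1, 0.0, 0.2, 0.9):
            nes, _ = normalize_scores({"pw": obs}, {"pw": null})
            assert np.sign(nes["pw"]) == np.sign(obs)

    def test_missing_same_sign_yields_nan(self):
        nes, _ = normalize_scores({"pw": 0.5},
                                  {"pw": np.array([-0.1, -0.2])})
        assert np.isnan(nes["pw"])


class TestPermutationPvalue:
    def test_observed_beyond_all_permutations_gives_zero(self, rng):
        null = rng.uniform(-1, 1, 200)
        assert permutation_pvalue(null.max() + 1.0, null) == 0.0

    def test_median_position_gives_half(self):
        null = np.linspace(0.01, 2.0, 200)
        p = permutation_pvalue(np.median(null), null)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_counting_matches_oracle(self, rng):
        for _ in range(200):
            null = rng.standard_normal(int(rng.integers(5, 80)))
            obs = float(rng.standard_normal())
            assert permutation_pvalue(obs, null) == pytest.approx(
                tail_count_pvalue(obs, null), abs=1e-15)
            assert permutation_pvalue(obs, null, conservative=True) == \
                pytest.approx(tail_count_pvalue(obs, null, True), abs=1e-15)

    def test_resolution_is_one_over_n_perm(self, rng):
        null = rng.uniform(0.1, 1.0, 50)
        obs = null.max() - 1e-9  # exceeded by exactly one permutation
        assert permutation_pvalue(obs, null) == pytest.approx(1 / 50)

    def test_empty_null_rejected(self):
        with pytest.raises(DataValidationError, match="empty"):
            permutation_pvalue(0.5, np.array([]))


class TestBhCorrection:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_correction([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        assert bh_correction([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(bh_correction([1.0, 1.0, 1.0]),
                                      [1.0, 1.0, 1.0])

    def test_matches_independent_stepup(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_correction(p), bh_stepup(p),
                                       atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_correction(p), ref, atol=1e-12)

    def test_domain_checked(self):
        with pytest.raises(DataValidationError):
            bh_correction([0.5, 1.5])


class TestNullDistribution:
    def test_deterministic_under_seed(self, rng):
        data = make_dataset(rng, n_genes=6, n_per_group=6)
        sets = GeneSetCollection({"pw": {"g0", "g1", "g2"}})
        kwargs = dict(config=FAST_REG,
                      perm_config=PermutationConfig(n_perm=3, seed=5),
                      gene_sets=sets, stat_name="Wd1")
        first = null_distribution(data, **kwargs)
        second = null_distribution(data, **kwargs)
        np.testing.assert_array_equal(first["pw"], second["pw"])
        assert first["pw"].shape == (3,)

    def test_worker_count_does_not_change_results(self, rng):
        data = make_dataset(rng, n_genes=6, n_per_group=6)
        sets = GeneSetCollection({"pw": {"g0", "g1", "g2"}})
        serial = null_distribution(
            data, FAST_REG, PermutationConfig(n_perm=4, seed=9), sets)
        parallel = null_distribution(
            data, FAST_REG,
            PermutationConfig(n_perm=4, seed=9, n_workers=2), sets)
        np.testing.assert_array_equal(serial["pw"], parallel["pw"])

    def test_no_overlap_pathway_excluded(self, rng):
        data = make_dataset(rng, n_genes=5, n_per_group=6)
        sets = GeneSetCollection({"pw": {"g0", "g1"},
                                  "alien": {"x1", "x2"}})
        null = null_distribution(
            data, FAST_REG, PermutationConfig(n_perm=2, seed=1), sets)
        assert "alien" not in null and "pw" in null


class TestRunEnrichment:
    def test_identical_labels_rejected(self, noise_dataset):
        sets = GeneSetCollection({"pw": {"g0", "g1"}})
        with pytest.raises(DataValidationError, match="differ"):
            run_enrichment(noise_dataset, sets, labels=("C", "C"))

    def test_result_table_contract(self, rng):
        data = make_dataset(rng, n_genes=7, n_per_group=8)
        sets = GeneSetCollection({"pw1": {"g0", "g1", "g2"},
                                  "pw2": {"g3", "g4"},
                                  "alien": {"nope"}})
        res = run_enrichment(
            data, sets, labels=("C", "N"), stat_name="Wd1",
            reg_config=FAST_REG,
            perm_config=PermutationConfig(n_perm=6, seed=2))
        frame = res.to_frame()
        assert set(frame["pathway"]) == {"pw1", "pw2"}
        assert res.skipped_pathways == ("alien",)
        assert ((frame["p_value"] >= 0) & (frame["p_value"] <= 1)).all()
        assert ((frame["fdr_q"] >= 0) & (frame["fdr_q"] <= 1)).all()
        # conservative p-value is the add-one count
        assert (frame["p_conservative"] >
                frame["p_value"] - 1e-12).all()
        assert (frame["significant"] ==
                (frame["p_conservative"] < 0.05)).all()
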