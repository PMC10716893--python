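"""Distribution-learning metrics, rank test, drug-likeness rules, projection."""

import itertools

import numpy as np
import pytest

from moltreegen.chem_graph import ConfigurationError
from moltreegen.evaluation import (
    chemical_space_map,
    continuous_kl,
    discrete_kl,
    distribution_benchmark,
    druglike_filter,
    fingerprint_matrix,
    histogram_kl,
    kl_score,
    mann_whitney_bonferroni,
)


class TestDistributionBenchmark:
    def test_generated_equals_reference(self, fixture_smiles):
        report = distribution_benchmark(fixture_smiles, fixture_smiles)
        assert report.novelty == 0.0
        assert report.validity == 1.0
        assert report.uniqueness == 1.0

    def test_disjoint_all_valid_distinct(self):
        generated = ["CCO", "CCN", "CCC", "CCCl"]
        reference = ["c1ccccc1", "CC(=O)O"]
        report = distribution_benchmark(generated, reference)
        assert (report.validity, report.uniqueness, report.novelty) == (1, 1, 1)

    def test_duplicate_halves_uniqueness(self):
        report = distribution_benchmark(["CCO", "CCO"], ["CCC"])
        assert report.uniqueness == 0.5

    def test_count_monotonicity_with_adversarial_input(self, fixture_smiles):
        generated = ["bad(", "CCO", "CCO", "OCC", fixture_smiles[0], "xx"]
        report = distribution_benchmark(generated, fixture_smiles)
        assert report.n_novel <= report.n_unique <= report.n_valid \
            <= report.n_generated
        assert report.n_valid == 4  # two unparseable strings dropped

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            distribution_benchmark([], ["C"])


class TestKlScore:
    def test_hand_computed_two_bin_case(self):
        # KL((0.5,0.5)||(0.9,0.1)) = 0.5*ln(5/9) + 0.5*ln(5) (hand summation)
        assert histogram_kl([5, 5], [9, 1]) == pytest.approx(0.5108256237659907,
                                                             abs=1e-6)

    def test_identical_sets_score_near_one(self, fixture_smiles):
        assert kl_score(fixture_smiles, fixture_smiles) > 0.99

    def test_score_in_unit_interval(self, fixture_smiles):
        s = kl_score(fixture_smiles[:25], fixture_smiles[25:])
        assert 0.0 < s <= 1.0

    def test_order_invariance(self, fixture_smiles):
        a = kl_score(fixture_smiles[:20], fixture_smiles[20:])
        b = kl_score(fixture_smiles[:20][::-1], fixture_smiles[20:][::-1])
        assert a == pytest.approx(b)

    def test_bootstrap_of_reference_scores_high(self):
        """A resample of the reference set must look like the reference."""
        from moltreegen import make_fixture_set
        ref = make_fixture_set(400, seed=3)
        rng = np.random.default_rng(0)
        boot = [ref[i] for i in rng.integers(0, len(ref), size=len(ref))]
        assert kl_score(boot, ref) > 0.9

    def test_requires_ten_molecules(self):
        with pytest.raises(ConfigurationError):
            kl_score(["CCO"] * 5, ["CCC"] * 20)

    def test_degenerate_descriptor_no_blowup(self):
        # single-valued descriptors (e.g. identical molecules) stay finite
        assert continuous_kl([1.0] * 10, [1.0] * 10) == 0.0
        assert np.isfinite(discrete_kl([2] * 10, [2] * 10))


def _exact_mann_whitney_p(a, b):
    """Exhaustive rank-permutation null for small tie-free samples."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_obs = min(u_obs, n_a * len(b) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        r = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        u = min(r, n_a * len(b) - r)
        count += u <= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    @pytest.mark.parametrize("n_a,n_b,seed", [(3, 3, 0), (4, 4, 1), (5, 4, 2),
                                              (5, 5, 3), (2, 5, 4)])
    def test_matches_exhaustive_permutation_oracle(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_a)
        b = rng.normal(loc=0.5, size=n_b)
        _, p_raw, _ = mann_whitney_bonferroni(a, b)
        assert p_raw == pytest.approx(_exact_mann_whitney_p(a, b), abs=1e-12)

    def test_identical_samples(self):
        a = np.arange(6.0)
        u, p_raw, p_adj = mann_whitney_bonferroni(a, a)
        # symmetric null: U at its mean n^2/2, p = 1
        assert u == 6 * 6 / 2
        assert p_raw == p_adj == 1.0

    def test_all_tied_degenerate_samples(self):
        with pytest.warns(UserWarning):
            u, p_raw, p_adj = mann_whitney_bonferroni(np.ones(5), np.ones(5))
        assert (u, p_raw, p_adj) == (12.5, 1.0, 1.0)

    def test_bonferroni_clamped_to_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        _, p_raw, p_adj = mann_whitney_bonferroni(a, b, n_comparisons=1000)
        assert p_adj == min(1.0, p_raw * 1000)
        assert p_adj <= 1.0

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=900), rng.normal(0.3, size=900)
        r1 = mann_whitney_bonferroni(a, b, subsample_size=500, seed=7)
        r2 = mann_whitney_bonferroni(a, b, subsample_size=500, seed=7)
        assert r1 == r2

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney_bonferroni([], [1.0])


class TestDruglikeFilter:
    def test_benzene_passes(self):
        survivors, failures = druglike_filter(["c1ccccc1"])
        assert survivors == ["c1ccccc1"]
        assert sum(failures.values()) == 0

    def test_cyclooctane_fails_ring_rule(self):
        survivors, failures = druglike_filter(["C1CCCCCCC1"])
        assert survivors == []
        assert failures["ring_size"] == 1

    def test_heavy_molecule_fails_lipinski(self):
        heavy = "C" * 40  # MW > 500 and logP > 5
        survivors, failures = druglike_filter([heavy])
        assert survivors == []
        assert failures["lipinski"] == 1
        assert failures["logp"] == 1


class TestChemicalSpaceMap:
    def test_identical_structures_identical_fingerprints(self):
        fps = fingerprint_matrix(["CCO", "OCC"])
        assert np.array_equal(fps[0], fps[1])
        assert fps.shape == (2, 2048)

    def test_projection_contract(self, fixture_smiles):
        coords = chemical_space_map(fixture_smiles[:30], seed=0)
        assert coords.shape == (30, 2)
        again = chemical_space_map(fixture_smiles[:30], seed=0)
        assert np.allclose(coords, again)

    def test_too_few_molecules(self):
        with pytest.raises(ConfigurationError):
            chemical_space_map(["C", "CC"], seed=0)
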