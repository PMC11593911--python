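"""The diploid copying HMM: transitions, emissions, posteriors, calling."""

import math

import numpy as np
import pytest

import snpimpute as si
from snpimpute.imputation_engine import (
    SOURCE_IMPUTED,
    SOURCE_OBSERVED,
    HMMParams,
    PosteriorField,
    align_to_panel,
    emission_probability,
    genotype_predictive_table,
)
from snpimpute.types import MISSING

from helpers import brute_force_posteriors, make_obs, make_panel, random_small_instance


class TestSwitchProbability:
    def test_zero_distance_gives_zero(self):
        assert si.switch_probability(0.0, 1e4, 100) == 0.0

    def test_limit_at_large_distance(self):
        assert si.switch_probability(1e9, 1e4, 100) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # 1 - exp(-4 * 10000 * (0.01/100) / 100) = 1 - exp(-0.04)
        assert si.switch_probability(0.01, 10_000, 100) == pytest.approx(
            1 - math.exp(-0.04), abs=1e-12
        )

    def test_monotone_in_distance(self):
        taus = [si.switch_probability(d, 5e3, 50) for d in (0.0, 0.01, 0.1, 1.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            si.switch_probability(-0.1, 1e4, 10)


class TestEmission:
    def test_exact_match_probability_one_at_zero_eps(self):
        assert emission_probability(1, 0, 1, 0.0) == pytest.approx(1.0)

    def test_double_miscopy_is_eps_squared(self):
        assert emission_probability(0, 1, 1, 1e-3) == pytest.approx(1e-6)

    def test_missing_emits_one(self):
        assert emission_probability(MISSING, 0, 1, 0.1) == 1.0

    def test_emissions_normalize_over_genotypes(self):
        for eps in (0.0, 1e-3, 0.2):
            t = genotype_predictive_table(eps)
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            emission_probability(3, 0, 1, 0.01)


class TestForwardBackward:
    def test_degenerate_identical_panel_no_data(self):
        h = np.array([1, 0, 1, 1, 0], np.uint8)
        panel = make_panel(np.tile(h, (5, 1)))
        obs = make_obs(panel.sites, np.full(5, MISSING))
        gmap = si.GeneticMap(panel.sites.pos.astype(float), panel.sites.cm)
        post = si.forward_backward(panel, obs, gmap, HMMParams(eps=1e-12))
        assert np.allclose(post.p[np.arange(5), 2 * h], 1.0, atol=1e-6)

    def test_matches_exhaustive_enumeration(self, rng):
        worst = 0.0
        for _ in range(25):
            alleles, g_obs, pos, ne, eps = random_small_instance(rng)
            panel = make_panel(alleles, positions=pos)
            obs = make_obs(panel.sites, g_obs)
            gmap = si.GeneticMap(pos.astype(float), panel.sites.cm)
            post = si.forward_backward(panel, obs, gmap, HMMParams(ne=ne, eps=eps))
            ref = brute_force_posteriors(alleles, g_obs, panel.sites.cm, ne, eps)
            worst = max(worst, float(np.abs(post.p - ref).max()))
        assert worst < 1e-9

    def test_perfect_copy_small_instance(self, rng):
        founders = si.simulate_founders(20, 200, 0.05, seed=55)
        gmap = si.make_genetic_map(founders.sites.pos, 1.0)
        g = founders.alleles[3].astype(np.int8) + founders.alleles[11].astype(np.int8)
        truth = si.TruthGenotypes(founders.sites, g)
        obs = si.prune_to_panel(truth, 100, seed=56)
        post = si.forward_backward(founders, obs, gmap, HMMParams(eps=1e-4))
        miss = obs.g_obs == MISSING
        assert np.array_equal(post.argmax_genotype[miss], g[miss])

    def test_haplotype_permutation_invariance(self, rng):
        alleles, g_obs, pos, ne, eps = random_small_instance(rng, k_max=4, l_max=5)
        panel = make_panel(alleles, positions=pos)
        perm = rng.permutation(alleles.shape[0])
        panel_perm = make_panel(alleles[perm], positions=pos)
        obs = make_obs(panel.sites, g_obs)
        gmap = si.GeneticMap(pos.astype(float), panel.sites.cm)
        a = si.forward_backward(panel, obs, gmap, HMMParams(ne=ne, eps=eps))
        b = si.forward_backward(panel_perm, obs, gmap, HMMParams(ne=ne, eps=eps))
        assert np.allclose(a.p, b.p, atol=1e-12)

    def test_observation_pins_its_own_site(self, small_panel):
        """Adding an observed genotype makes its own posterior ~1 - O(eps)."""
        panel, gmap = small_panel
        ind = si.sample_truth_individual(panel, seed=57, recombine=True)
        ref = panel.exclude_rows(ind.panel_rows)
        obs0 = si.prune_to_panel(ind.genotypes, 0, seed=58)
        g1 = obs0.g_obs.copy()
        g1[10] = ind.genotypes.g[10]
        obs1 = si.ObservedGenotypes(panel.sites, g1, truth=ind.genotypes.g)
        p0 = si.forward_backward(ref, obs0, gmap)
        p1 = si.forward_backward(ref, obs1, gmap)
        true_g = ind.genotypes.g[10]
        assert p1.p[10, true_g] >= p0.p[10, true_g] - 1e-12
        assert p1.p[10, true_g] > 0.99

    def test_posterior_field_invariants(self, small_panel):
        panel, gmap = small_panel
        ind = si.sample_truth_individual(panel, seed=59)
        ref = panel.exclude_rows(ind.panel_rows)
        obs = si.prune_to_panel(ind.genotypes, 150, seed=60)
        post = si.forward_backward(ref, obs, gmap)
        assert np.abs(post.p.sum(axis=1) - 1).max() < 1e-9
        assert np.all(post.gp >= 1 / 3 - 1e-12) and np.all(post.gp <= 1 + 1e-12)
        assert np.all(post.dosage >= 0) and np.all(post.dosage <= 2)
        assert np.isfinite(post.loglik)

    def test_small_panel_rejected(self):
        panel = make_panel(np.zeros((1, 4), np.uint8))
        obs = make_obs(panel.sites, np.zeros(4))
        gmap = si.GeneticMap(panel.sites.pos.astype(float), panel.sites.cm)
        with pytest.raises(ValueError):
            si.forward_backward(panel, obs, gmap)

    def test_site_list_mismatch_rejected(self):
        panel = make_panel(np.zeros((4, 6), np.uint8))
        other = make_panel(np.zeros((4, 5), np.uint8))
        obs = make_obs(other.sites, np.zeros(5))
        gmap = si.GeneticMap(panel.sites.pos.astype(float), panel.sites.cm)
        with pytest.raises(ValueError):
            si.forward_backward(panel, obs, gmap)


class TestCallImputed:
    def _post_obs(self):
        p = np.array(
            [[0.96, 0.03, 0.01], [0.2, 0.5, 0.3], [0.01, 0.04, 0.95], [0.1, 0.8, 0.1]]
        )
        post = PosteriorField(p)
        sites = make_panel(np.zeros((2, 4), np.uint8)).sites
        g_obs = np.array([MISSING, MISSING, MISSING, 1], np.int8)
        return post, make_obs(sites, g_obs)

    def test_threshold_zero_calls_everything(self):
        post, obs = self._post_obs()
        called = si.call_imputed(post, obs, 0.0)
        assert not np.any(called.genotype == MISSING)

    def test_threshold_one_only_certain_calls(self):
        post, obs = self._post_obs()
        called = si.call_imputed(post, obs, 1.0)
        imputed = called.source == SOURCE_IMPUTED
        assert imputed.sum() == 0  # no gp == 1 in the fixture

    def test_inclusive_boundary(self):
        """A site at exactly the threshold is called ("met or exceeded")."""
        post, obs = self._post_obs()
        called = si.call_imputed(post, obs, 0.95)
        assert called.genotype[2] == 2 and called.source[2] == SOURCE_IMPUTED
        assert called.genotype[0] == 0  # gp 0.96 > 0.95
        assert called.genotype[1] == MISSING  # gp 0.5 < 0.95

    def test_observed_pass_through(self):
        post, obs = self._post_obs()
        called = si.call_imputed(post, obs, 0.5)
        assert called.genotype[3] == 1 and called.source[3] == SOURCE_OBSERVED
        assert called.gp[3] == 1.0

    def test_argmax_tie_breaks_to_lower_code(self):
        p = np.array([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4]])
        post = PosteriorField(p)
        assert list(post.argmax_genotype) == [0, 1]


class TestAlignment:
    def test_target_sites_absent_from_panel_flagged_unimputable(self):
        panel = make_panel(np.zeros((2, 5), np.uint8), positions=[10, 20, 30, 40, 50])
        target = make_panel(np.zeros((2, 3), np.uint8), positions=[20, 35, 50])
        obs = make_obs(target.sites, [1, 2, 0])
        aligned, unimputable = align_to_panel(obs, panel)
        assert list(unimputable) == [False, True, False]
        assert aligned.g_obs[1] == 1 and aligned.g_obs[4] == 0
        assert aligned.g_obs[0] == MISSING
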