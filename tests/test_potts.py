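"""Multiclass Ising core: conditionals, joint density, Gibbs sampling."""

import itertools

import numpy as np
import pytest

import zili
from zili.potts import (
    PottsParameters,
    conditional_state_probs,
    gibbs_sample,
    log_unnormalized_density,
)


def enumerate_distribution(theta):
    """Brute-force Boltzmann distribution over all K^p states."""
    states = list(itertools.product(range(theta.K), repeat=theta.p))
    logw = np.array([log_unnormalized_density(theta, z) for z in states])
    w = np.exp(logw - logw.max())
    return states, w / w.sum()


class TestConditionals:
    def test_zero_parameters_give_uniform(self):
        theta = PottsParameters(p=4, K=3)
        probs = conditional_state_probs(theta, 1, [0, 2, 1])
        np.testing.assert_allclose(probs, np.full(3, 1 / 3), atol=1e-12)

    def test_two_taxon_closed_form(self):
        # log-odds-ratio log 2 and active neighbor: P(Z_1=1) = 2/(1+2)
        theta = PottsParameters(p=2, K=2, pairwise={(0, 1): [[np.log(2)]]})
        probs = conditional_state_probs(theta, 0, [1])
        np.testing.assert_allclose(probs, [1 / 3, 2 / 3], atol=1e-12)

    def test_all_zero_neighbors_reduce_to_intercepts(self):
        theta = PottsParameters(
            p=3, K=3, main_effects=[[0.4, -1.0]] * 3,
            pairwise={(0, 1): np.ones((2, 2))},
        )
        probs = conditional_state_probs(theta, 0, [0, 0])
        logits = np.array([0.0, 0.4, -1.0])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_probabilities_sum_to_one(self, chain_theta):
        probs = conditional_state_probs(chain_theta, 2, [1, 0])
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_matches_enumerated_joint_conditionals(self):
        rng = np.random.default_rng(3)
        theta = PottsParameters(
            p=3, K=3,
            main_effects=rng.normal(size=(3, 2)),
            pairwise={(0, 1): rng.normal(size=(2, 2)),
                      (2, 1): rng.normal(size=(2, 2))},
        )
        states, pi = enumerate_distribution(theta)
        pi = dict(zip(states, pi))
        for rest in itertools.product(range(3), repeat=2):
            joint = np.array([pi[(l, rest[0], rest[1])] for l in range(3)])
            expected = joint / joint.sum()
            got = conditional_state_probs(theta, 0, np.array(rest))
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_zeroing_pair_removes_dependence(self):
        rng = np.random.default_rng(4)
        block = rng.normal(size=(2, 2))
        theta = PottsParameters(p=3, K=3, pairwise={(0, 2): block})
        with_dep = [conditional_state_probs(theta, 0, [0, h]) for h in range(3)]
        assert not np.allclose(with_dep[0], with_dep[2])
        theta_zero = PottsParameters(p=3, K=3, pairwise={(0, 2): np.zeros((2, 2))})
        without = [conditional_state_probs(theta_zero, 0, [0, h]) for h in range(3)]
        for probs in without[1:]:
            np.testing.assert_allclose(probs, without[0], atol=1e-12)

    def test_invalid_inputs_raise(self):
        theta = PottsParameters(p=3, K=3)
        with pytest.raises(ValueError):
            conditional_state_probs(theta, 5, [0, 0])
        with pytest.raises(ValueError):
            conditional_state_probs(theta, 0, [0, 7])


class TestLogDensity:
    def test_zero_parameters(self):
        theta = PottsParameters(p=3, K=3)
        for z in itertools.product(range(3), repeat=3):
            assert log_unnormalized_density(theta, z) == 0.0

    def test_direct_substitution(self):
        a, b = 0.7, -1.3
        theta = PottsParameters(
            p=2, K=2, main_effects=[[a], [0.0]], pairwise={(0, 1): [[b]]}
        )
        assert log_unnormalized_density(theta, [1, 1]) == pytest.approx(a + b)
        assert log_unnormalized_density(theta, [1, 0]) == pytest.approx(a)
        assert log_unnormalized_density(theta, [0, 0]) == 0.0
        assert log_unnormalized_density(theta, [0, 1]) == 0.0


class TestGibbs:
    def test_saturated_main_effect_forces_state(self):
        theta = PottsParameters(p=4, K=2, main_effects=np.full((4, 1), 20.0))
        sm = gibbs_sample(theta, n=500, sweeps=5, seed=0)
        assert np.all(sm.values == 1)

    def test_independence_marginals_match_softmax(self):
        logits = np.array([0.8, -0.4])
        theta = PottsParameters(p=2, K=3, main_effects=np.tile(logits, (2, 1)))
        n = 20000
        sm = gibbs_sample(theta, n=n, sweeps=3, seed=1)
        full = np.concatenate([[0.0], logits])
        expected = np.exp(full) / np.exp(full).sum()
        for j in range(2):
            freq = np.bincount(sm.values[:, j], minlength=3) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(freq - expected) < 3.5 * se)

    def test_joint_matches_enumeration(self, chain_theta):
        n = 20000
        sm = gibbs_sample(chain_theta, n=n, sweeps=100, seed=2)
        states, pi = enumerate_distribution(chain_theta)
        idx = sm.values @ np.array([4, 2, 1])
        emp = np.bincount(idx, minlength=8) / n
        ref = np.array(
            [pi[states.index(s)] for s in itertools.product(range(2), repeat=3)]
        )
        tv = 0.5 * np.abs(emp - ref).sum()
        assert tv < 0.03

    def test_seeded_reproducibility(self, chain_theta):
        a = gibbs_sample(chain_theta, n=50, sweeps=20, seed=9)
        b = gibbs_sample(chain_theta, n=50, sweeps=20, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestSerialization:
    def test_flat_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        theta = PottsParameters(
            p=4, K=3,
            main_effects=rng.normal(size=(4, 2)),
            pairwise={(1, 0): rng.normal(size=(2, 2)),
                      (3, 2): rng.normal(size=(2, 2))},
        )
        path = tmp_path / "theta.tsv"
        theta.save(path)
        loaded = zili.PottsParameters.load(path, p=4, K=3)
        np.testing.assert_array_equal(loaded.main_effects, theta.main_effects)
        assert set(loaded.pairwise) == set(theta.pairwise)
        for key in theta.pairwise:
            np.testing.assert_array_equal(loaded.pairwise[key], theta.pairwise[key])

    def test_group_accessor_layout(self):
        block = np.array([[1.0, 2.0], [3.0, 4.0]])
        theta = PottsParameters(p=2, K=3, pairwise={(0, 1): block})
        np.testing.assert_array_equal(theta.group(0, 1), [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(theta.group(1, 0), np.zeros(4))
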