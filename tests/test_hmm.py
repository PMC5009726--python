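"""Two-state Gaussian HMM: oracle equivalence, EM behavior, domain calls.

The independent oracle is exhaustive path enumeration: for short
sequences the likelihood, posteriors and best path are computed by
summing/maximizing over all 2^T state paths with plain mixture algebra.
"""

from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

from replidamage import hmm
from replidamage.coverage import bin_genome
from replidamage.hmm import (
    GaussianHMMParams,
    baum_welch,
    call_domains,
    forward_backward,
    forward_log,
    initialize_params,
    positive_domains,
    segment,
    viterbi,
)

# ---------------------------------------------------------------- oracles


def brute_force(obs, params):
    """Enumerate all 2^T paths: total likelihood, per-path probabilities."""
    T = len(obs)
    paths = list(product([0, 1], repeat=T))
    probs = []
    for path in paths:
        p = params.initial[path[0]]
        for a, b in zip(path, path[1:]):
            p *= params.transitions[a, b]
        for s, x in zip(path, obs):
            p *= norm.pdf(x, params.means[s], np.sqrt(params.variances[s]))
        probs.append(p)
    return paths, np.asarray(probs)


def brute_loglik(obs, params):
    _, probs = brute_force(obs, params)
    return float(np.log(probs.sum()))


def brute_posteriors(obs, params):
    paths, probs = brute_force(obs, params)
    total = probs.sum()
    gamma = np.zeros((len(obs), 2))
    for path, p in zip(paths, probs):
        for t, s in enumerate(path):
            gamma[t, s] += p
    return gamma / total


def brute_viterbi(obs, params):
    paths, probs = brute_force(obs, params)
    return np.asarray(paths[int(np.argmax(probs))])


def random_instance(rng, T):
    pi = rng.dirichlet([1, 1])
    A = rng.dirichlet([1, 1], size=2)
    params = GaussianHMMParams(
        initial=pi,
        transitions=A,
        means=np.sort(rng.normal(0, 1, 2)),
        variances=rng.uniform(0.1, 2.0, 2),
    )
    return rng.normal(0, 1.5, T), params


# ------------------------------------------------------------ unit tests


class TestInitialize:
    def test_median_split_means(self):
        p = initialize_params([0.0, 0.0, 1.0, 1.0])
        np.testing.assert_allclose(p.means, [0.0, 1.0])

    def test_rows_are_stochastic(self):
        p = initialize_params([0.0, 1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(p.transitions.sum(axis=1), 1.0)
        np.testing.assert_allclose(p.initial.sum(), 1.0)

    def test_separated_components_recovered_within_3_se(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.2, 500)
        b = rng.normal(3.0, 0.2, 500)
        p = initialize_params(np.concatenate([a, b]))
        se = 0.2 / np.sqrt(500)
        assert abs(p.means[0] - a.mean()) < 3 * se + 1e-9
        assert abs(p.means[1] - b.mean()) < 3 * se + 1e-9

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="identical"):
            initialize_params([2.0, 2.0, 2.0, 2.0])


class TestForward:
    def test_single_obs_identical_states_is_normal_density(self):
        p = GaussianHMMParams(
            [0.3, 0.7], [[0.5, 0.5], [0.5, 0.5]], [1.0, 1.0], [0.4, 0.4]
        )
        x = 1.7
        assert forward_log([x], p) == pytest.approx(
            norm.logpdf(x, 1.0, np.sqrt(0.4)), abs=1e-12
        )

    def test_T2_matches_four_path_enumeration(self):
        rng = np.random.default_rng(1)
        obs, p = random_instance(rng, 2)
        assert forward_log(obs, p) == pytest.approx(
            brute_loglik(obs, p), abs=1e-10
        )

    def test_appending_observation_bounded_by_max_emission(self):
        rng = np.random.default_rng(2)
        obs, p = random_instance(rng, 6)
        ll_short = forward_log(obs[:-1], p)
        x = obs[-1]
        max_em = max(
            norm.logpdf(x, p.means[s], np.sqrt(p.variances[s])) for s in (0, 1)
        )
        assert forward_log(obs, p) <= ll_short + max_em + 1e-9

    def test_nonfinite_observation_reports_position(self):
        p = GaussianHMMParams(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [0.0, 1.0], [1.0, 1.0]
        )
        with pytest.raises(ValueError, match="position 2"):
            forward_log([0.0, 1.0, np.nan], p)


class TestForwardBackward:
    def test_T1_symmetric_params_gives_half_half(self):
        p = GaussianHMMParams(
            [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [-1.0, 1.0], [1.0, 1.0]
        )
        gamma, _ = forward_backward([0.0], p)
        np.testing.assert_allclose(gamma, [[0.5, 0.5]], atol=1e-12)

    def test_T3_matches_eight_path_enumeration(self):
        rng = np.random.default_rng(3)
        obs, p = random_instance(rng, 3)
        gamma, ll = forward_backward(obs, p)
        np.testing.assert_allclose(gamma, brute_posteriors(obs, p), atol=1e-10)
        assert ll == pytest.approx(brute_loglik(obs, p), abs=1e-9)

    def test_separated_states_give_confident_posteriors(self):
        p = GaussianHMMParams(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [0.0, 10.0], [0.25, 0.25]
        )
        obs = np.array([10.1, 9.9, 10.3, 9.8])
        gamma, _ = forward_backward(obs, p)
        assert np.all(gamma[:, 1] > 0.99)
        np.testing.assert_allclose(gamma, brute_posteriors(obs, p), atol=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(4)
        obs, p = random_instance(rng, 50)
        gamma, _ = forward_backward(obs, p)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestViterbi:
    def test_T1_argmax_of_initial_times_emission(self):
        rng = np.random.default_rng(5)
        obs, p = random_instance(rng, 1)
        scores = [
            np.log(p.initial[s])
            + norm.logpdf(obs[0], p.means[s], np.sqrt(p.variances[s]))
            for s in (0, 1)
        ]
        assert viterbi(obs, p)[0] == int(np.argmax(scores))

    def test_T3_matches_enumeration(self):
        rng = np.random.default_rng(6)
        obs, p = random_instance(rng, 3)
        np.testing.assert_array_equal(viterbi(obs, p), brute_viterbi(obs, p))

    def test_dominant_state_wins_everywhere(self):
        p = GaussianHMMParams(
            [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [0.0, 5.0], [1.0, 1.0]
        )
        obs = np.full(10, 20.0)  # far above both means; state 1 dominates
        np.testing.assert_array_equal(viterbi(obs, p), np.ones(10, dtype=int))

    def test_exact_tie_breaks_to_lower_state(self):
        p = GaussianHMMParams(
            [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [-1.0, 1.0], [1.0, 1.0]
        )
        np.testing.assert_array_equal(viterbi([0.0, 0.0], p), [0, 0])

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            obs, p = random_instance(rng, int(rng.integers(1, 9)))
            np.testing.assert_array_equal(
                viterbi(obs, p), brute_viterbi(obs, p)
            )
            assert forward_log(obs, p) == pytest.approx(
                brute_loglik(obs, p), abs=1e-9
            )


class TestBaumWelch:
    def test_parameter_recovery_on_simulated_chain(self):
        rng = np.random.default_rng(8)
        states = [0]
        for _ in range(4999):
            states.append(
                states[-1] if rng.random() < 0.97 else 1 - states[-1]
            )
        states = np.asarray(states)
        obs = rng.normal(np.where(states == 0, 0.0, 1.0), 0.3)
        params, trace, converged = baum_welch(
            [obs], initialize_params(obs)
        )
        assert converged
        assert abs(params.means[0] - 0.0) < 0.05
        assert abs(params.means[1] - 1.0) < 0.05

    def test_single_em_step_matches_posterior_weighted_means(self):
        obs = np.array(
            [0.1, 0.2, 1.9, 2.2, -0.1, 0.3, 2.1, 1.8, 0.0, 2.4, 0.2, 1.7]
        )
        init = GaussianHMMParams(
            [0.5, 0.5], [[0.8, 0.2], [0.2, 0.8]], [0.0, 2.0], [0.5, 0.5]
        )
        params, _, _ = baum_welch([obs], init, max_iter=1)
        gamma = brute_posteriors(obs, init)
        expected = (gamma * obs[:, None]).sum(axis=0) / gamma.sum(axis=0)
        np.testing.assert_allclose(params.means, np.sort(expected), atol=1e-9)

    def test_refit_from_optimum_is_a_fixed_point(self):
        rng = np.random.default_rng(9)
        obs = np.concatenate(
            [rng.normal(0, 0.3, 500), rng.normal(1, 0.3, 500)]
        )
        fitted, _, _ = baum_welch([obs], initialize_params(obs))
        _, trace, converged = baum_welch([obs], fitted, max_iter=5)
        assert converged
        assert len(trace) == 2  # relative change below tol at iteration 1
        assert abs(trace[1] - trace[0]) <= 1e-6 * max(1.0, abs(trace[0]))

    def test_loglik_nondecreasing_over_random_inits(self):
        rng = np.random.default_rng(10)
        obs = rng.normal(
            np.where(rng.random(800) < 0.4, 0.0, 1.2), 0.4
        )
        for _ in range(10):
            init = GaussianHMMParams(
                initial=rng.dirichlet([1, 1]),
                transitions=rng.dirichlet([1, 1], size=2),
                means=np.sort(rng.normal(0.5, 1, 2)),
                variances=rng.uniform(0.05, 1, 2),
            )
            _, trace, _ = baum_welch([obs], init, max_iter=20)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_multi_sequence_training_pools_information(self):
        rng = np.random.default_rng(11)
        seqs = [
            rng.normal(np.where(rng.random(300) < 0.5, 0.0, 2.0), 0.3)
            for _ in range(3)
        ]
        params, _, _ = baum_welch(seqs, initialize_params(np.concatenate(seqs)))
        assert abs(params.means[0]) < 0.15
        assert abs(params.means[1] - 2.0) < 0.15

    def test_label_permutation_invariance_of_domains(self):
        rng = np.random.default_rng(12)
        states = np.repeat([0, 1, 0, 1, 0], 40)
        obs = rng.normal(np.where(states == 0, 0.0, 1.5), 0.3)
        bins = bin_genome({"c": 5000 * len(obs)}, 5000, 5000)
        base = GaussianHMMParams(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [0.0, 1.5], [0.09, 0.09]
        )
        flipped = GaussianHMMParams(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [1.5, 0.0], [0.09, 0.09]
        )
        doms_a = call_domains(segment({"c": obs}, init=base), bins)
        doms_b = call_domains(segment({"c": obs}, init=flipped), bins)
        key = lambda ds: [(d.chrom, d.start, d.end, d.state) for d in ds]
        assert key(doms_a) == key(doms_b)

    def test_hmmlearn_cross_check(self):
        """Independent implementation agreement on likelihood and decoding."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(13)
        obs, p = random_instance(rng, 200)
        model = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="diag", init_params="", params=""
        )
        model.startprob_ = p.initial
        model.transmat_ = p.transitions
        model.means_ = p.means[:, None]
        model.covars_ = p.variances[:, None]
        X = obs[:, None]
        assert forward_log(obs, p) == pytest.approx(model.score(X), abs=1e-8)
        _, ref_path = model.decode(X, algorithm="viterbi")
        np.testing.assert_array_equal(viterbi(obs, p), ref_path)


class TestCallDomains:
    def _result(self, path, obs=None, chrom="c"):
        path = np.asarray(path)
        obs = np.asarray(obs if obs is not None else path, dtype=float)
        return hmm.SegmentationResult(
            state_paths={chrom: path},
            positive_posteriors={chrom: path.astype(float)},
            observations={chrom: obs},
            log_likelihood=0.0,
            n_iterations=1,
            params=GaussianHMMParams(
                [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [0.0, 1.0], [1.0, 1.0]
            ),
            converged=True,
        )

    def test_run_merging_coordinates(self):
        bins = bin_genome({"c": 35_000}, 5000, 5000)
        doms = call_domains(self._result([0, 0, 1, 1, 1, 0, 0]), bins)
        pos = positive_domains(doms)
        assert len(pos) == 1
        assert (pos[0].start, pos[0].end) == (10_000, 25_000)
        assert pos[0].n_bins == 3
        states = [d.state for d in doms]
        assert states == ["negative", "positive", "negative"]

    def test_all_negative_path_yields_no_positive_domains(self):
        bins = bin_genome({"c": 25_000}, 5000, 5000)
        doms = call_domains(self._result([0] * 5), bins)
        assert positive_domains(doms) == []
        assert len(doms) == 1

    def test_chromosome_boundary_always_breaks_domains(self):
        bins = bin_genome({"a": 10_000, "b": 10_000}, 5000, 5000)
        res_a = self._result([0, 1], chrom="a")
        res_b = self._result([1, 0], chrom="b")
        res = hmm.SegmentationResult(
            state_paths={**res_a.state_paths, **res_b.state_paths},
            positive_posteriors={
                **res_a.positive_posteriors, **res_b.positive_posteriors
            },
            observations={**res_a.observations, **res_b.observations},
            log_likelihood=0.0,
            n_iterations=1,
            params=res_a.params,
            converged=True,
        )
        pos = positive_domains(call_domains(res, bins))
        assert [(d.chrom, d.start, d.end) for d in pos] == [
            ("a", 5000, 10_000),
            ("b", 0, 5000),
        ]

    def test_min_bins_reassigns_short_positive_runs(self):
        bins = bin_genome({"c": 45_000}, 5000, 5000)
        path = [0, 1, 0, 1, 1, 1, 0, 1, 0]
        doms = call_domains(self._result(path), bins, min_bins=3)
        pos = positive_domains(doms)
        assert [(d.start, d.end) for d in pos] == [(15_000, 30_000)]
        # reassigned bins merge with their negative neighbours
        assert [d.state for d in doms] == ["negative", "positive", "negative"]

    def test_path_bin_length_mismatch_raises(self):
        bins = bin_genome({"c": 20_000}, 5000, 5000)
        with pytest.raises(ValueError, match="bins"):
            call_domains(self._result([0, 1]), bins)
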