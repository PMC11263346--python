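"""Unit and property tests for the latent-cause inference engine."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcnet.lci import (
    SCRPParams,
    LatentCauseRegistry,
    infer_step,
    lc_likelihoods,
    lc_posterior_map,
    sample_context_vector,
    scrp_prior,
    traces_to_frame,
    update_registry,
)


def scrp_oracle(counts, prev_lc, alpha, lam):
    """Hand-enumerated sticky-CRP probabilities using exact rationals."""
    mass = [Fraction(c) for c in counts]
    if prev_lc is not None:
        mass[prev_lc] += Fraction(lam)
    mass.append(Fraction(alpha))
    total = sum(mass)
    return [float(m / total) for m in mass]


class TestContextVectors:
    def test_deterministic_under_seed(self):
        a = sample_context_vector(3, np.random.default_rng(7))
        b = sample_context_vector(3, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_standard_normal_moments(self, rng):
        draws = np.array([sample_context_vector(128, rng) for _ in range(2000)])
        assert np.abs(draws.mean(axis=0)).max() < 0.1
        assert np.abs(draws.var(axis=0) - 1).max() < 0.2

    def test_high_dim_near_orthogonal(self, rng):
        # |cos| between independent 256-d Gaussians concentrates near 0
        cosines = []
        for _ in range(200):
            a = sample_context_vector(256, rng)
            b = sample_context_vector(256, rng)
            cosines.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert np.quantile(np.abs(cosines), 0.95) < 0.2

    def test_invalid_dim(self, rng):
        with pytest.raises(ValueError):
            sample_context_vector(0, rng)


class TestSCRPPrior:
    def test_empty_registry_opens_new(self, rng):
        reg = LatentCauseRegistry(4, rng)
        assert np.allclose(scrp_prior(reg, SCRPParams(0.7, 1.0)), [1.0])

    def test_printed_example(self, rng):
        # counts=[2], prev active, alpha=0.5, lambda=1 -> [6/7, 1/7]
        reg = LatentCauseRegistry(4, rng)
        update_registry(reg, 0, rng)
        update_registry(reg, 0, rng)
        prior = scrp_prior(reg, SCRPParams(alpha=0.5, stickiness=1.0))
        assert np.allclose(prior, [6 / 7, 1 / 7])

    def test_zero_stickiness_reduces_to_crp(self, rng):
        # exhaustive over count vectors with total <= 5 and K <= 3
        for K in (1, 2, 3):
            for counts in itertools.product(range(1, 6), repeat=K):
                if sum(counts) > 5:
                    continue
                for prev in range(K):
                    reg = LatentCauseRegistry(2, rng)
                    for k, c in enumerate(counts):
                        for _ in range(c):
                            update_registry(reg, min(k, reg.K), rng)
                    reg.prev_lc = prev
                    got = scrp_prior(reg, SCRPParams(alpha=1.0, stickiness=0.0))
                    want = scrp_oracle(list(counts), None, 1.0, 0.0)  # plain CRP
                    assert np.allclose(got, want, atol=1e-12)

    def test_sticky_matches_oracle(self, rng):
        for K in (1, 2, 3):
            for counts in itertools.product(range(1, 4), repeat=K):
                if sum(counts) > 5:
                    continue
                reg = LatentCauseRegistry(2, rng)
                for k, c in enumerate(counts):
                    for _ in range(c):
                        update_registry(reg, min(k, reg.K), rng)
                reg.prev_lc = K - 1
                got = scrp_prior(reg, SCRPParams(alpha=0.5, stickiness=1.5))
                want = scrp_oracle(list(counts), K - 1, 0.5, 1.5)
                assert np.allclose(got, want, atol=1e-12)

    def test_stickiness_monotone_for_prev(self, rng):
        reg = LatentCauseRegistry(2, rng)
        for k in (0, 1, 1, 0, 0):
            update_registry(reg, min(k, reg.K), rng)
        prev = reg.prev_lc
        probs = [scrp_prior(reg, SCRPParams(0.5, lam))[prev] for lam in (0, 0.5, 1, 2, 5)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_degenerate_prior_raises(self, rng):
        reg = LatentCauseRegistry(2, rng)
        with pytest.raises(ValueError):
            scrp_prior(reg, SCRPParams(alpha=0.0, stickiness=1.0))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SCRPParams(alpha=-1.0)
        with pytest.raises(ValueError):
            SCRPParams(stickiness=-0.1)


class TestLikelihood:
    def _registry(self, rng, K):
        reg = LatentCauseRegistry(3, rng)
        for _ in range(K):
            update_registry(reg, reg.K, rng)
        return reg

    def test_equal_losses_give_uniform(self, rng):
        reg = self._registry(rng, 2)
        lik, losses = lc_likelihoods(
            lambda xp, c: np.zeros(4), reg, np.zeros(4), np.ones(4), temperature=1.0
        )
        assert np.allclose(lik, 1 / 3)
        assert np.allclose(losses, 1.0)

    def test_extreme_loss_gap(self, rng):
        # losses [0, 100] at temperature 1 -> softmax ~ [1, 3.7e-44]
        reg = self._registry(rng, 1)
        preds = {reg.context_vectors[0].tobytes(): np.zeros(1)}

        def predict(xp, c):
            return preds.get(np.asarray(c).tobytes(), np.full(1, 10.0))

        lik, losses = lc_likelihoods(predict, reg, np.zeros(1), np.zeros(1), 1.0)
        assert np.allclose(losses, [0.0, 100.0])
        assert lik[0] == pytest.approx(1.0, abs=1e-12)
        assert lik[1] == pytest.approx(np.exp(-100), rel=1e-9)

    def test_matches_softmax_oracle(self, rng):
        reg = self._registry(rng, 2)
        x_prev, x_curr = rng.standard_normal(5), rng.standard_normal(5)
        predict = lambda xp, c: np.tanh(c[:5].sum() * xp)  # noqa: E731
        lik, losses = lc_likelihoods(predict, reg, x_prev, x_curr, temperature=0.37)
        # brute-force oracle: recompute each elementwise MSE and softmax
        want_losses = []
        for c in [*reg.context_vectors, reg.candidate_vector]:
            pred = predict(x_prev, c)
            want_losses.append(sum((p - t) ** 2 for p, t in zip(pred, x_curr)) / 5)
        e = np.exp(-np.asarray(want_losses) / 0.37)
        assert np.allclose(losses, want_losses, atol=1e-12)
        assert np.allclose(lik, e / e.sum(), atol=1e-12)

    def test_empty_registry_single_entry(self, rng):
        reg = LatentCauseRegistry(3, rng)
        lik, losses = lc_likelihoods(lambda xp, c: np.zeros(2), reg, np.zeros(2), np.ones(2))
        assert np.allclose(lik, [1.0])
        assert losses.shape == (1,)

    def test_bad_temperature(self, rng):
        reg = self._registry(rng, 1)
        with pytest.raises(ValueError):
            lc_likelihoods(lambda xp, c: np.zeros(2), reg, np.zeros(2), np.ones(2), 0.0)


class TestPosterior:
    def test_uniform_prior_passes_likelihood(self):
        post, k = lc_posterior_map([0.5, 0.5], [0.9, 0.1])
        assert np.allclose(post, [0.9, 0.1])
        assert k == 0

    def test_prior_support_restriction(self):
        post, k = lc_posterior_map([1.0, 0.0], [0.4, 0.6])
        assert k == 0
        assert post[1] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_product_oracle(self, seed):
        r = np.random.default_rng(seed)
        prior = r.dirichlet(np.ones(4))
        lik = r.dirichlet(np.ones(4))
        post, k = lc_posterior_map(prior, lik)
        want = prior * lik
        want = want / want.sum()
        assert np.allclose(post, want, atol=1e-12)
        assert k == int(np.argmax(want))

    def test_tie_breaks_to_lowest_index(self):
        post, k = lc_posterior_map([0.5, 0.5], [0.5, 0.5])
        assert k == 0

    def test_disjoint_mass_raises(self):
        with pytest.raises(FloatingPointError):
            lc_posterior_map([1.0, 0.0], [0.0, 1.0])


class TestRegistry:
    def test_first_spawn_bookkeeping(self, rng):
        reg = LatentCauseRegistry(4, rng)
        update_registry(reg, 0, rng)
        assert reg.K == 1 and reg.counts == [1] and reg.prev_lc == 0

    def test_existing_increment(self, rng):
        reg = LatentCauseRegistry(4, rng)
        update_registry(reg, 0, rng)
        update_registry(reg, 1, rng)
        update_registry(reg, 0, rng)
        update_registry(reg, 0, rng)
        update_registry(reg, 1, rng)
        assert reg.counts == [3, 2] and reg.prev_lc == 1 and reg.K == 2

    def test_counts_conserved_over_100_updates(self, rng):
        reg = LatentCauseRegistry(4, rng)
        for _ in range(100):
            update_registry(reg, int(rng.integers(0, reg.K + 1)), rng)
        assert sum(reg.counts) == 100

    def test_vectors_never_change_after_creation(self, rng):
        reg = LatentCauseRegistry(4, rng)
        update_registry(reg, 0, rng)
        frozen = reg.context_vectors[0].copy()
        for _ in range(20):
            update_registry(reg, int(rng.integers(0, reg.K + 1)), rng)
        assert np.array_equal(reg.context_vectors[0], frozen)

    def test_candidate_adopted_verbatim(self, rng):
        reg = LatentCauseRegistry(4, rng)
        cand = reg.candidate_vector.copy()
        update_registry(reg, 0, rng)
        assert np.array_equal(reg.context_vectors[0], cand)
        assert not np.array_equal(reg.candidate_vector, cand)

    def test_out_of_range_index(self, rng):
        reg = LatentCauseRegistry(4, rng)
        with pytest.raises(ValueError):
            update_registry(reg, 1, rng)


class _SegmentOracle:
    """Running-mean prototype predictor keyed by context vector; the
    not-yet-created LC predicts zeros (an uncommitted guess)."""

    def __init__(self, dim):
        self.dim = dim
        self.protos = {}

    def __call__(self, xp, c):
        entry = self.protos.get(np.asarray(c).tobytes())
        if entry is None:
            return np.zeros(self.dim)
        s, n = entry
        return s / n

    def update(self, c, obs):
        s, n = self.protos.get(np.asarray(c).tobytes(), (np.zeros(self.dim), 0))
        self.protos[np.asarray(c).tobytes()] = (s + obs, n + 1)


class TestInferStep:
    def test_first_step_spawns(self, rng):
        reg = LatentCauseRegistry(4, rng)
        tr = infer_step(lambda xp, c: np.zeros(2), reg, SCRPParams(), np.zeros(2),
                        np.ones(2), rng, t=0)
        assert tr.spawned_new and tr.map_lc == 0 and reg.K == 1

    def test_disabled_step_carries_prev(self, rng):
        reg = LatentCauseRegistry(4, rng)
        for k in (0, 1, 1):
            update_registry(reg, min(k, reg.K), rng)
        tr = infer_step(lambda xp, c: np.zeros(2), reg, SCRPParams(), np.zeros(2),
                        np.ones(2), rng, inference_enabled=False)
        assert tr.map_lc == 1 and not tr.spawned_new and tr.posterior is None
        assert reg.counts == [1, 3]  # carried LC's count still increments

    def test_disabled_without_prev_raises(self, rng):
        reg = LatentCauseRegistry(4, rng)
        with pytest.raises(RuntimeError):
            infer_step(lambda xp, c: np.zeros(2), reg, SCRPParams(), np.zeros(2),
                       np.ones(2), rng, inference_enabled=False)

    def test_three_segment_stream_perfect_purity(self, rng):
        # three segments with distant means and near-zero noise: inferred
        # assignments must be a pure relabeling of the segments
        from lcnet.metrics import cluster_purity

        dim = 8
        means = 4.0 * np.eye(dim)[:3]
        labels = np.repeat([0, 1, 2], 30)
        obs = means[labels] + 0.01 * rng.standard_normal((90, dim))
        reg = LatentCauseRegistry(4, rng)
        oracle = _SegmentOracle(dim)
        assigned = []
        for t, x in enumerate(obs):
            xp = obs[t - 1] if t else np.zeros(dim)
            tr = infer_step(oracle, reg, SCRPParams(alpha=1.0, stickiness=1.0),
                            xp, x, rng, t=t, temperature=0.1)
            oracle.update(reg.context_vectors[tr.map_lc], x)
            assigned.append(tr.map_lc)
        assert cluster_purity(np.array(assigned), labels) == 1.0

    def test_trajectory_bit_reproducible(self, rng):
        def trajectory(seed):
            r = np.random.default_rng(seed)
            reg = LatentCauseRegistry(4, r)
            oracle = _SegmentOracle(3)
            out = []
            for t in range(40):
                x = np.sin(np.arange(3) + t // 10)
                xp = np.sin(np.arange(3) + (t - 1) // 10) if t else np.zeros(3)
                tr = infer_step(oracle, reg, SCRPParams(), xp, x, r, t=t)
                oracle.update(reg.context_vectors[tr.map_lc], x)
                out.append((tr.map_lc, tuple(tr.posterior)))
            return out

        assert trajectory(99) == trajectory(99)

    def test_posterior_proportional_to_prior_times_likelihood(self, rng):
        reg = LatentCauseRegistry(3, rng)
        oracle = _SegmentOracle(3)
        for t in range(25):
            x = rng.standard_normal(3)
            xp = rng.standard_normal(3)
            prior = scrp_prior(reg, SCRPParams()) if reg.K else None
            tr = infer_step(oracle, reg, SCRPParams(), xp, x, rng, t=t)
            oracle.update(reg.context_vectors[tr.map_lc], x)
            if prior is not None:
                want = tr.prior * tr.likelihood
                assert np.allclose(tr.posterior, want / want.sum(), atol=1e-9)
                assert abs(tr.posterior.sum() - 1) < 1e-9


def test_traces_to_frame_schema(rng):
    reg = LatentCauseRegistry(3, rng)
    traces = [
        infer_step(lambda xp, c: np.zeros(2), reg, SCRPParams(), np.zeros(2),
                   rng.standard_normal(2), rng, t=t)
        for t in range(5)
    ]
    df = traces_to_frame(traces)
    assert list(df.columns) == ["t", "map_lc", "spawned_new", "K", "inference_enabled", "posterior"]
    assert len(df) == 5 and df.loc[0, "spawned_new"]
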