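"""Plain-integer reference engine against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgbnet.reference_engine import (
    Beat,
    Direction,
    FoldedUnitParams,
    binarize_thresholded,
    conv1d_valid,
    fold_bn,
    maxpool,
    pseudo_softmax_argmax,
    reference_forward,
)

from conftest import random_beat, small_spec


def conv_loop_oracle(inp, weights):
    """Three-nested-loop valid convolution, written independently."""
    cout, cin, k = weights.shape
    lout = inp.shape[1] - k + 1
    out = np.zeros((cout, lout), dtype=np.int64)
    for f in range(cout):
        for x in range(lout):
            s = 0
            for c in range(cin):
                for kk in range(k):
                    s += int(inp[c, x + kk]) * int(weights[f, c, kk])
            out[f, x] = s
    return out


class TestConv1dValid:
    def test_constant_input_all_plus_taps(self):
        inp = np.ones((1, 180), dtype=np.int64)
        w = np.ones((1, 1, 7), dtype=np.int8)
        assert (conv1d_valid(inp, w) == 7).all()

    def test_constant_input_mixed_taps_gives_tap_sum(self):
        inp = np.ones((1, 180), dtype=np.int64)
        w = np.array([[[1, 1, 1, 1, -1, -1, -1]]], dtype=np.int8)
        assert (conv1d_valid(inp, w) == 1).all()

    def test_matches_loop_oracle_on_random_pm1(self):
        rng = np.random.default_rng(42)
        inp = rng.choice([-1, 1], size=(64, 20)).astype(np.int64)
        w = rng.choice([-1, 1], size=(3, 64, 7)).astype(np.int8)
        np.testing.assert_array_equal(conv1d_valid(inp, w),
                                      conv_loop_oracle(inp, w))

    def test_matches_loop_oracle_on_signed_8bit_input(self):
        rng = np.random.default_rng(7)
        inp = rng.integers(-128, 128, size=(2, 15)).astype(np.int64)
        w = rng.choice([-1, 1], size=(4, 2, 5)).astype(np.int8)
        np.testing.assert_array_equal(conv1d_valid(inp, w),
                                      conv_loop_oracle(inp, w))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            conv1d_valid(np.ones((3, 10)), np.ones((2, 4, 3)))


class TestMaxpool:
    def test_pairwise_example(self):
        np.testing.assert_array_equal(maxpool(np.array([3, 9, -2, 5]), 2),
                                      [9, 5])

    def test_constant_map_halves_length(self):
        out = maxpool(np.full((4, 10), 3), 2)
        assert out.shape == (4, 5) and (out == 3).all()

    def test_matches_pairwise_oracle_on_random_map(self):
        rng = np.random.default_rng(0)
        acc = rng.integers(-1000, 1000, size=156)
        expected = [max(acc[2 * i], acc[2 * i + 1]) for i in range(78)]
        np.testing.assert_array_equal(maxpool(acc, 2), expected)

    def test_non_divisible_length_raises(self):
        with pytest.raises(ValueError, match="not divisible"):
            maxpool(np.arange(7), 2)


class TestFoldBn:
    def test_identity_bn_is_sign_function(self):
        assert fold_bn(1, 0, 0, 1) == (0, Direction.GE)

    def test_negative_gain_flips_comparator(self):
        assert fold_bn(-1, 0, 0, 1) == (0, Direction.LE)

    def test_zero_gain_constant_channels(self):
        assert fold_bn(0, 2.0, 5, 1)[1] == Direction.CONST_POS
        assert fold_bn(0, -2.0, 5, 1)[1] == Direction.CONST_NEG
        assert fold_bn(0, 0.0, 5, 1)[1] == Direction.CONST_POS  # sign(0) = +1

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            fold_bn(1, 0, 0, 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(gamma=st.floats(-5, 5, allow_nan=False),
           beta=st.floats(-20, 20, allow_nan=False),
           mu=st.floats(-500, 500, allow_nan=False),
           sigma=st.floats(0.01, 100, allow_nan=False))
    def test_threshold_equals_direct_bn_sign_over_sweep(self, gamma, beta,
                                                        mu, sigma):
        """Integer thresholding must agree with the real-valued BN sign for
        every accumulator in an exhaustive sweep."""
        tau, direction = fold_bn(gamma, beta, mu, sigma)
        a = np.arange(-1000, 1001, dtype=np.int64)
        direct = gamma * (a - mu) / sigma + beta >= 0
        folded = binarize_thresholded(
            a[np.newaxis, :], np.array([tau]),
            np.array([int(direction)]))[0] == 1
        np.testing.assert_array_equal(folded, direct)


class TestPseudoSoftmax:
    def test_argmax_and_tie_rule(self):
        assert pseudo_softmax_argmax([0.1, 3.2, -1.0]) == 1
        assert pseudo_softmax_argmax([5, 5]) == 0  # tie -> lowest index

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pseudo_softmax_argmax([])

    def test_equals_argmax_of_softmax(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(50)
        soft = np.exp(scores) / np.exp(scores).sum()
        assert pseudo_softmax_argmax(scores) == int(np.argmax(soft))


def _identity_affine(n):
    return dict(gamma=np.ones(n), beta=np.zeros(n), mu=np.zeros(n),
                sigma=np.ones(n))


class TestReferenceForward:
    def test_all_zero_beat_with_positive_thresholds_gives_class_zero(self):
        spec = small_spec(n_units=2)
        rng = np.random.default_rng(0)
        conv_u, fc_u = spec.units
        params = [
            FoldedUnitParams(
                rng.choice([-1, 1], size=(64, 1, 3)).astype(np.int8),
                thresholds=np.full(64, 5, dtype=np.int64),
                directions=np.full(64, Direction.GE, dtype=np.uint8)),
            FoldedUnitParams(
                rng.choice([-1, 1], size=(4, fc_u.in_channels)).astype(np.int8),
                **_identity_affine(4)),
        ]
        beat = Beat(np.zeros(180, dtype=np.int8))
        cls, scores, traces = reference_forward(spec, params, beat,
                                                return_trace=True)
        # zero accumulators fall below every positive GE threshold, so the
        # hidden map is uniformly -1; the fc accumulators are then forced.
        assert (traces[0] == 0).all()
        expected_fc = -params[1].weights.astype(np.int64).sum(axis=1)
        np.testing.assert_array_equal(traces[1][:, 0], expected_fc)
        assert cls == pseudo_softmax_argmax(expected_fc)

    def test_dominant_affine_bias_wins(self):
        spec = small_spec(n_units=2)
        rng = np.random.default_rng(1)
        k = 2
        beta = np.zeros(4)
        beta[k] = 1e6
        params = [
            FoldedUnitParams(
                rng.choice([-1, 1], size=(64, 1, 3)).astype(np.int8),
                thresholds=np.zeros(64, dtype=np.int64),
                directions=np.full(64, Direction.GE, dtype=np.uint8)),
            FoldedUnitParams(
                rng.choice([-1, 1],
                           size=(4, spec.units[1].in_channels)).astype(np.int8),
                gamma=np.ones(4), beta=beta, mu=np.zeros(4),
                sigma=np.ones(4)),
        ]
        cls, _ = reference_forward(spec, params, random_beat(rng))
        assert cls == k

    def test_class_permutation_equivariance(self):
        from ecgbnet.synthetic import random_params
        spec = small_spec(n_units=3, n_classes=5)
        params = random_params(spec, seed=9)
        rng = np.random.default_rng(5)
        beat = random_beat(rng)
        cls, scores = reference_forward(spec, params, beat)
        perm = rng.permutation(5)
        last = params[-1]
        permuted = params[:-1] + [FoldedUnitParams(
            last.weights[perm], gamma=last.gamma[perm], beta=last.beta[perm],
            mu=last.mu[perm], sigma=last.sigma[perm])]
        cls_p, scores_p = reference_forward(spec, permuted, beat)
        np.testing.assert_allclose(scores_p, scores[perm])
        assert perm[cls_p] == cls

    def test_hidden_arithmetic_is_integer(self):
        from ecgbnet.synthetic import random_params
        spec = small_spec(n_units=3)
        params = random_params(spec, seed=2)
        _, _, traces = reference_forward(
            spec, params, random_beat(np.random.default_rng(0)),
            return_trace=True)
        assert all(np.issubdtype(t.dtype, np.integer) for t in traces)

    def test_param_shape_mismatch_raises(self):
        spec = small_spec(n_units=2)
        from ecgbnet.synthetic import random_params
        params = random_params(spec, seed=0)
        with pytest.raises(ValueError):
            reference_forward(spec, params[:1],
                              random_beat(np.random.default_rng(0)))


class TestBeat:
    def test_length_and_range_validation(self):
        with pytest.raises(ValueError):
            Beat(np.zeros(179, dtype=np.int8))
        with pytest.raises(ValueError):
            Beat(np.full(180, 300))
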