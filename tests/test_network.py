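"""Cascade network: convolution, hashing, histograms, fit/transform."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ccanet_ecg.filters import PendingMatrix
from ccanet_ecg.network import (
    NetworkParams, convolve_same, binarize, decimal_encode, block_histogram,
    block_count, block_starts, feature_length, fit, transform, transform_many,
    save_model, load_model, _conv_bank_batch,
)
from ccanet_ecg.filters import FilterBank
from oracles import enumerate_blocks, cca_svd_oracle


class TestConvolveSame:
    def test_delta_filter_is_identity(self, rng):
        mat = rng.normal(size=(6, 7))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(convolve_same(mat, delta), mat)

    def test_ones_filter_zero_padding(self):
        out = convolve_same(np.ones((4, 4)), np.ones((3, 3)))
        assert out[1, 1] == out[2, 2] == 9
        assert out[0, 0] == out[0, 3] == out[3, 0] == out[3, 3] == 4

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, alpha, beta):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(2, 5, 5))
        W = rng.normal(size=(3, 3))
        np.testing.assert_allclose(
            convolve_same(alpha * A + beta * B, W),
            alpha * convolve_same(A, W) + beta * convolve_same(B, W),
            atol=1e-9)

    def test_even_filter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            convolve_same(np.zeros((5, 5)), np.zeros((2, 3)))

    def test_oversized_filter_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            convolve_same(np.zeros((3, 3)), np.zeros((5, 5)))

    def test_batched_path_matches_public_op(self, rng):
        maps = rng.normal(size=(4, 8, 8))
        filters = rng.normal(size=(3, 5, 5))
        bank = FilterBank(filters, layer=1, mode="rand")
        batched = _conv_bank_batch(maps, bank)
        for b in range(4):
            for l in range(3):
                np.testing.assert_allclose(
                    batched[b, l], convolve_same(maps[b], filters[l]),
                    atol=1e-10)


class TestHashing:
    def test_binarize_sign_cases(self):
        mat = np.array([[1.5, -2.0], [0.0, 3.0]])
        np.testing.assert_array_equal(binarize(mat), [[1, 0], [0, 1]])
        np.testing.assert_array_equal(binarize(np.zeros((2, 2))),
                                      np.zeros((2, 2), dtype=int))

    def test_decimal_encode_binary_weighting(self):
        maps = np.zeros((3, 1, 1), dtype=int)
        maps[0, 0, 0], maps[2, 0, 0] = 1, 1  # bits (1, 0, 1) -> 1 + 4
        assert decimal_encode(maps)[0, 0] == 5

    def test_decimal_encode_extremes(self):
        ones = np.ones((9, 4, 4), dtype=int)
        np.testing.assert_array_equal(decimal_encode(ones), 511)
        np.testing.assert_array_equal(decimal_encode(np.zeros((9, 4, 4))), 0)


class TestBlockHistogram:
    def test_non_overlapping_blocks(self):
        T = np.zeros((4, 4), dtype=int)
        hist = block_histogram(T, 2, 2, R=0.5, L2=2)
        # R=0.5 with u=2 -> stride 1 -> 9 blocks of 4 zeros
        assert block_count(4, 4, 2, 2, 0.5) == 9
        assert hist.shape == (4 * 9,)
        np.testing.assert_array_equal(hist.reshape(9, 4)[:, 0], 4)

    def test_r_zero_like_stride(self):
        # overlap below 1/u gives the non-overlapping stride
        assert len(block_starts(4, 2, R=0.01)) == 2
        T = np.zeros((4, 4), dtype=int)
        hist = block_histogram(T, 2, 2, R=0.01, L2=2)
        assert hist.size == 4 * 4
        np.testing.assert_array_equal(hist.reshape(4, 4)[:, 0], 4)

    def test_stride_rounds_half_up(self):
        # u=7, R=0.5 -> stride round(3.5) = 4
        np.testing.assert_array_equal(block_starts(16, 7, 0.5), [0, 4, 8])
        np.testing.assert_array_equal(block_starts(32, 7, 0.5),
                                      [0, 4, 8, 12, 16, 20, 24])

    @pytest.mark.parametrize("rows, cols, u1, u2, R", [
        (16, 32, 7, 7, 0.5), (18, 40, 7, 7, 0.5), (16, 16, 4, 4, 0.25),
        (10, 12, 3, 5, 0.7),
    ])
    def test_block_count_matches_enumeration_oracle(self, rows, cols, u1, u2, R):
        assert block_count(rows, cols, u1, u2, R) == \
            len(enumerate_blocks(rows, cols, u1, u2, R))

    def test_histogram_mass_conservation(self, rng):
        T = rng.integers(0, 8, size=(12, 20))
        hist = block_histogram(T, 5, 7, R=0.5, L2=3)
        B = block_count(12, 20, 5, 7, 0.5)
        assert hist.sum() == B * 5 * 7

    def test_block_larger_than_map_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            block_histogram(np.zeros((4, 4), dtype=int), 5, 2, 0.5, 2)


class TestFit:
    def test_two_identical_leads_unit_correlations(self, tiny_matrices):
        dup = np.stack([tiny_matrices[0], tiny_matrices[0]])
        params = NetworkParams(n_leads=2, t1=3, t2=3, L1=2, L2=2,
                               u1=4, u2=4, m=8, n=8)
        model = fit(dup, params)
        for bank in model.layer1_banks + model.layer2_banks:
            np.testing.assert_allclose(bank.correlations, 1.0, atol=1e-6)

    def test_three_lead_bank_structure(self, rng):
        beats = rng.normal(size=(3, 6, 8, 8))
        params = NetworkParams(n_leads=3, t1=3, t2=3, L1=3, L2=2,
                               u1=4, u2=4, m=8, n=8)
        model = fit(beats, params)
        assert len(model.layer1_banks) == 3 and len(model.layer2_banks) == 3
        assert all(b.n_filters == 3 for b in model.layer1_banks)
        assert all(b.n_filters == 2 for b in model.layer2_banks)

    def test_tiny_fit_matches_svd_oracle(self, rng):
        from ccanet_ecg.filters import build_pending_matrix
        beats = rng.normal(size=(2, 3, 4, 4))
        params = NetworkParams(n_leads=2, t1=3, t2=3, L1=2, L2=2,
                               u1=2, u2=2, m=4, n=4)
        model = fit(beats, params)
        X1 = build_pending_matrix(beats[0], 3, 3).data
        X2 = build_pending_matrix(beats[1], 3, 3).data
        _, _, rho = cca_svd_oracle(X1, X2, 2)
        np.testing.assert_allclose(model.layer1_banks[0].correlations, rho,
                                   atol=1e-8)

    def test_lead_count_mismatch_rejected(self, rng):
        params = NetworkParams(n_leads=3, t1=3, t2=3, m=8, n=8,
                               L1=2, L2=2, u1=4, u2=4)
        with pytest.raises(ValueError, match="leads"):
            fit(rng.normal(size=(2, 5, 8, 8)), params)

    @pytest.mark.parametrize("mode", ["pca", "rand"])
    def test_baseline_modes_single_lead(self, tiny_matrices, mode):
        params = NetworkParams(n_leads=1, t1=3, t2=3, L1=2, L2=2,
                               u1=4, u2=4, m=8, n=8, mode=mode)
        model = fit(tiny_matrices[:1], params)
        assert model.layer1_banks[0].mode == mode
        assert model.layer1_banks[0].correlations.size == 0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(3)
    beats = rng.normal(size=(2, 8, 16, 16))
    params = NetworkParams()  # published defaults, 16x16
    return params, beats, fit(beats, params)


class TestTransform:

    def test_feature_length_formula(self, fitted):
        params, beats, model = fitted
        # decimal maps are 16 x 32; defaults give B = 3 * 7 = 21
        assert params.decimal_shape == (16, 32)
        B = block_count(16, 32, 7, 7, 0.5)
        assert B == len(enumerate_blocks(16, 32, 7, 7, 0.5)) == 21
        feats = transform_many(model, beats[:, :2])
        assert feats.shape == (2, 2 ** 9 * 9 * 21)
        assert feature_length(params) == feats.shape[1]

    def test_histogram_mass_invariant(self, fitted):
        params, beats, model = fitted
        feats = transform_many(model, beats[:, :3])
        B = block_count(*params.decimal_shape, params.u1, params.u2, params.R)
        expected = params.L1 * B * params.u1 * params.u2
        np.testing.assert_array_equal(feats.sum(axis=1), expected)

    def test_determinism_and_single_beat_path(self, fitted):
        params, beats, model = fitted
        f1 = transform_many(model, beats[:, :2])
        f2 = transform_many(model, beats[:, :2])
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(transform(model, beats[:, 0]), f1[0])

    def test_shape_mismatch_rejected(self, fitted, rng):
        _, _, model = fitted
        with pytest.raises(ValueError, match="expects"):
            transform_many(model, rng.normal(size=(2, 2, 8, 8)))

    def test_model_persistence_preserves_features(self, tmp_path, fitted):
        params, beats, model = fitted
        save_model(model, str(tmp_path / "model.npz"))
        loaded = load_model(str(tmp_path / "model.npz"))
        np.testing.assert_array_equal(transform_many(loaded, beats[:, :2]),
                                      transform_many(model, beats[:, :2]))


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs, match", [
        (dict(mode="cnn"), "mode"),
        (dict(mode="cca", n_leads=1), "leads"),
        (dict(t1=4), "odd"),
        (dict(R=0.0), "overlap"),
        (dict(L1=50), "L1"),
        (dict(t1=17, m=16), "exceeds"),
    ])
    def test_invalid_params(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            NetworkParams(**kwargs)
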