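"""Bilinear convolution network: projections, conv block, descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emofuse import autodiff as ad
from emofuse.autodiff import Tensor
from emofuse.bcn import (
    BCN,
    DescriptorConfig,
    build_feature_matrix,
    conv1d_pool_activate,
    grid_keypoints,
    left_project,
    right_project,
)
from emofuse.nn import gradcheck


def loop_left(x, h):
    # x: (C_l, M, N); h: (N_l, C_l, M', M)
    n_l, c_l, m_out, _ = h.shape
    out = np.zeros((n_l, m_out, x.shape[-1]))
    for t in range(n_l):
        for j in range(c_l):
            out[t] += h[t, j] @ x[j]
    return out


def loop_right(x, h):
    # x: (C_r, M', N); h: (N_r, C_r, N, N')
    n_r, c_r, _, n_out = h.shape
    out = np.zeros((n_r, x.shape[1], n_out))
    for t in range(n_r):
        for j in range(c_r):
            out[t] += x[j] @ h[t, j]
    return out


class TestProjections:
    def test_left_identity_single_channel(self, rng):
        x = rng.normal(size=(1, 1, 4, 5))
        h = np.eye(4)[None, None]
        np.testing.assert_allclose(
            left_project(Tensor(x), Tensor(h)).data, x, atol=1e-15
        )

    def test_left_two_identity_channels_sum(self, rng):
        x = rng.normal(size=(1, 2, 4, 5))
        h = np.stack([np.stack([np.eye(4), np.eye(4)])])
        np.testing.assert_allclose(
            left_project(Tensor(x), Tensor(h)).data[0, 0], x[0].sum(axis=0), atol=1e-14
        )

    def test_left_matches_loop_oracle(self, rng):
        x = rng.normal(size=(3, 4, 5))
        h = rng.normal(size=(2, 3, 6, 4))
        got = left_project(Tensor(x[None]), Tensor(h)).data[0]
        np.testing.assert_allclose(got, loop_left(x, h), atol=1e-10)

    def test_right_identity(self, rng):
        x = rng.normal(size=(1, 1, 4, 5))
        h = np.eye(5)[None, None]
        np.testing.assert_allclose(
            right_project(Tensor(x), Tensor(h)).data, x, atol=1e-15
        )

    def test_right_ones_vector_gives_row_sums(self, rng):
        x = rng.normal(size=(1, 1, 4, 5))
        h = np.ones((1, 1, 5, 1))
        got = right_project(Tensor(x), Tensor(h)).data[0, 0, :, 0]
        np.testing.assert_allclose(got, x[0, 0].sum(axis=1), atol=1e-12)

    def test_right_matches_loop_oracle(self, rng):
        x = rng.normal(size=(3, 4, 5))
        h = rng.normal(size=(2, 3, 5, 2))
        got = right_project(Tensor(x[None]), Tensor(h)).data[0]
        np.testing.assert_allclose(got, loop_right(x, h), atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            left_project(Tensor(np.zeros((1, 2, 4, 5))), Tensor(np.zeros((2, 3, 4, 4))))
        with pytest.raises(ValueError):
            right_project(Tensor(np.zeros((1, 2, 4, 5))), Tensor(np.zeros((2, 2, 4, 2))))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(scale=st.floats(-3.0, 3.0))
    def test_projection_linearity(self, scale):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=(1, 2, 4, 5))
        x2 = rng.normal(size=(1, 2, 4, 5))
        h = rng.normal(size=(3, 2, 4, 4))
        lhs = left_project(Tensor(scale * x1 + x2), Tensor(h)).data
        rhs = scale * left_project(Tensor(x1), Tensor(h)).data + left_project(
            Tensor(x2), Tensor(h)
        ).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestConvBlock:
    def test_zero_input_zero_bias_gives_zero(self):
        f = conv1d_pool_activate(
            Tensor(np.zeros((2, 3, 4, 8))), Tensor(np.zeros((2, 3, 3))),
            Tensor(np.zeros(2)), pool_size=2,
        )
        assert np.allclose(f.data, 0.0)

    def test_tanh_bound(self, rng):
        f = conv1d_pool_activate(
            Tensor(rng.normal(size=(2, 3, 4, 8))),
            Tensor(rng.normal(size=(2, 3, 3))),
            Tensor(rng.normal(size=2)), pool_size=2,
        )
        assert (np.abs(f.data) < 1.0).all()

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=(1, 2, 3, 7))
        w = rng.normal(size=(2, 2, 3))
        b = rng.normal(size=2)
        got = conv1d_pool_activate(Tensor(x), Tensor(w), Tensor(b), pool_size=2).data
        resp_len = 7 - 3 + 1
        for m in range(3):
            for o in range(2):
                resp = [
                    sum(x[0, c, m, i + k] * w[o, c, k] for c in range(2) for k in range(3))
                    for i in range(resp_len)
                ]
                pooled = [max(resp[0:2]), max(resp[2:4])]
                expected = np.tanh(b[o] + np.asarray(pooled))
                np.testing.assert_allclose(got[0, o, m], expected, atol=1e-10)

    def test_pool_window_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            conv1d_pool_activate(
                Tensor(np.zeros((1, 1, 2, 6))), Tensor(np.zeros((1, 1, 3))),
                Tensor(np.zeros(1)), pool_size=5,
            )


class TestBCNForward:
    def test_posteriors_sum_to_one(self, rng):
        net = BCN(6, 10, n_out=8, filter_len=3, n_classes=3,
                  rng=np.random.default_rng(0))
        _, post = net.forward(rng.normal(size=(4, 6, 10)), return_posteriors=True)
        np.testing.assert_allclose(post.data.sum(axis=-1), 1.0, atol=1e-8)

    def test_zero_input_zero_bias_gives_zero_features(self):
        net = BCN(4, 8, n_out=6, filter_len=3, rng=np.random.default_rng(0))
        feat = net.forward(np.zeros((2, 4, 8)))
        # tanh(0)=0 propagates through conv block and FC stack
        assert np.allclose(feat.data, 0.0)

    def test_backprop_matches_finite_differences(self, rng):
        """Criterion-level gradient check on a 4x6 input."""
        net = BCN(4, 6, n_left=2, m_out=3, n_right=2, n_out=4, conv_channels=2,
                  filter_len=3, pool_size=2, fc_hidden=5, feature_dim=3,
                  n_classes=2, rng=np.random.default_rng(1))
        x = rng.normal(size=(2, 1, 4, 6))
        y = np.array([0, 1])

        def loss():
            feat, post = net.forward(Tensor(x), return_posteriors=True)
            onehot = np.eye(2)[y]
            return -(ad.log(post + 1e-12) * onehot).sum()

        params = list(net.params.values())
        assert gradcheck(loss, params, max_elems=20,
                         rng=np.random.default_rng(2)) < 1e-4

    def test_end_to_end_trainability(self, rng):
        """200 Adam steps on a separable 2-class set cut the loss >=50%."""
        from emofuse.nn import Adam

        net = BCN(4, 6, n_out=4, filter_len=3, fc_hidden=8, feature_dim=4,
                  n_classes=2, rng=np.random.default_rng(3))
        pattern = rng.normal(size=(2, 4, 6))
        labels = rng.integers(0, 2, 40)
        X = pattern[labels] + 0.05 * rng.normal(size=(40, 4, 6))
        onehot = np.eye(2)[labels]
        opt = Adam(list(net.params.values()), lr=5e-3)

        def loss_value():
            _, post = net.forward(Tensor(X), return_posteriors=True)
            return -(ad.log(post + 1e-12) * onehot).sum() * (1.0 / len(X))

        first = loss_value().item()
        for _ in range(200):
            L = loss_value()
            opt.zero_grad()
            L.backward()
            opt.step()
        assert loss_value().item() <= 0.5 * first


class TestDescriptors:
    def test_constant_image_gives_zero_rows(self):
        desc = build_feature_matrix(np.full((2, 32, 32), 3.0))
        assert np.allclose(desc, 0.0)

    def test_deterministic(self, rng):
        img = rng.normal(size=(32, 32))
        a = build_feature_matrix(img)
        b = build_feature_matrix(img)
        assert np.array_equal(a, b)

    def test_shape_contract(self, rng):
        cfg = DescriptorConfig(grid=5, support=8, subcells=4, orientations=8)
        desc = build_feature_matrix(rng.normal(size=(3, 32, 32)), cfg)
        assert desc.shape == (3, 25, 128)

    def test_keypoint_out_of_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_matrix(
                rng.normal(size=(16, 16)), keypoints=np.array([[1, 8]])
            )

    def test_rotation_permutes_orientation_bins(self):
        """Brute-force oracle: rotating an oriented-edge patch by 90 deg
        shifts the dominant orientation bin by a quarter turn."""
        cfg = DescriptorConfig(grid=1, support=8, subcells=1, orientations=8)
        img = np.tile(np.linspace(0.0, 1.0, 16), (16, 1))  # horizontal ramp
        kp = np.array([[8, 8]])
        d0 = build_feature_matrix(img, cfg, keypoints=kp)[0]
        d90 = build_feature_matrix(np.rot90(img).copy(), cfg, keypoints=kp)[0]
        shift = cfg.orientations // 4
        assert (np.argmax(d90) - np.argmax(d0)) % cfg.orientations in (
            shift, cfg.orientations - shift,
        )

    def test_grid_keypoints_inside_support(self):
        kps = grid_keypoints(32, 32, DescriptorConfig())
        assert kps.min() >= 4 and kps.max() <= 27
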