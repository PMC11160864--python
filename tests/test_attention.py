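"""Feature-level distillation: attention operator and UFD/IFD losses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from hlfd import (DistillConfig, attention_map, flfd_loss, flfd_terms,
                  ifd_loss, normalized_attention, ufd_loss, unify_mids)
from hlfd.networks import FeatureMap, RepBundle

SQRT2 = np.sqrt(2.0)

finite_features = arrays(
    float, st.tuples(st.integers(1, 4), st.integers(1, 6), st.integers(1, 6)),
    elements=st.floats(-10, 10))


class TestAttentionMap:
    def test_hand_example_exponent_one(self):
        f = np.array([[[1.0, -1.0], [0.0, 2.0]],
                      [[-1.0, 1.0], [0.0, 0.0]]])
        out = attention_map(f, exponent=1.0)
        np.testing.assert_allclose(out.data, [[2.0, 2.0], [0.0, 2.0]])

    def test_zero_map_and_nonnegativity(self, rng):
        assert np.all(attention_map(np.zeros((3, 4, 4))).data == 0)
        f = rng.normal(size=(5, 6, 7))
        assert np.all(attention_map(f, exponent=2.0).data >= 0)

    def test_rejects_non_finite(self):
        f = np.zeros((1, 2, 2))
        f[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            attention_map(f)


class TestUnifyMids:
    def test_concat_at_smallest_size(self, rng):
        mids = [rng.normal(size=(8, 32, 32)), rng.normal(size=(16, 16, 16))]
        out = unify_mids(mids)
        assert out.values.shape == (24, 16, 16)

    def test_single_mid_identity(self, rng):
        m = rng.normal(size=(4, 8, 8))
        out = unify_mids([m])
        np.testing.assert_array_equal(out.values.data, m)

    def test_constant_preserved_by_interpolation(self):
        mids = [np.full((2, 12, 12), 3.5), np.full((1, 6, 6), -1.25)]
        out = unify_mids(mids)
        np.testing.assert_allclose(out.values.data[:2], 3.5)
        np.testing.assert_allclose(out.values.data[2], -1.25)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            unify_mids([])


class TestNormalizedAttention:
    def test_closed_form_three_four(self):
        # single channel 1x2 map [3, 4] -> unit vector [0.6, 0.8]
        f = np.array([[[3.0, 4.0]]])
        v = normalized_attention(f).values
        np.testing.assert_allclose(v.data, [0.6, 0.8], atol=1e-12)

    def test_constant_upscale_stays_unit(self):
        f = np.full((1, 1, 1), 5.0)
        v = normalized_attention(f, target_shape=(2, 2)).values
        np.testing.assert_allclose(v.data, [0.5] * 4, atol=1e-12)

    @given(f=finite_features, c=st.floats(0.1, 100))
    def test_scale_invariance(self, f, c):
        v1 = normalized_attention(f).values.data
        v2 = normalized_attention(c * f).values.data
        np.testing.assert_allclose(v1, v2, atol=1e-6)

    @given(f=finite_features)
    def test_unit_norm_or_zero(self, f):
        v = normalized_attention(f).values.data
        n = np.linalg.norm(v)
        assert abs(n - 1.0) < 1e-6 or n < 1e-6  # zero-map guard

    def test_zero_map_returns_zero_vector(self):
        v = normalized_attention(np.zeros((2, 3, 3))).values.data
        np.testing.assert_array_equal(v, np.zeros(9))


class TestUfdIfd:
    def test_identity_gives_zero(self, rng):
        f = rng.normal(size=(4, 8, 8))
        assert float(ufd_loss(f, f)) < 1e-6

    def test_orthogonal_attention_gives_sqrt2(self):
        # attention vectors [1,0] vs [0,1]
        s = np.array([[[2.0, 0.0]]])
        t = np.array([[[0.0, 3.0]]])
        assert float(ufd_loss(s, t)) == pytest.approx(SQRT2, abs=1e-9)

    def test_ifd_sums_over_layers(self):
        s = np.array([[[2.0, 0.0]]])
        t = np.array([[[0.0, 3.0]]])
        # each mid contributes sqrt(2); two mids -> 2*sqrt(2)
        assert float(ifd_loss([s, s], t)) == pytest.approx(2 * SQRT2, abs=1e-9)

    def test_ifd_empty_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            ifd_loss([], rng.normal(size=(2, 4, 4)))

    def test_ufd_matches_oracle_with_resampling(self, rng):
        for _ in range(30):
            s = rng.normal(size=(3, 8, 8))
            t = rng.normal(size=(5, 4, 4))
            assert float(ufd_loss(s, t)) == pytest.approx(
                oracles.ufd(s, t), abs=1e-6)

    def test_term_symmetric_in_normalized_arguments(self, rng):
        a = rng.normal(size=(2, 4, 4))
        b = rng.normal(size=(2, 4, 4))
        assert float(ufd_loss(a, b)) == pytest.approx(float(ufd_loss(b, a)),
                                                      abs=1e-9)

    @given(f=finite_features, g=finite_features)
    def test_term_bounded_by_two(self, f, g):
        g2 = np.resize(g, f.shape)  # same spatial size, arbitrary content
        assert float(ufd_loss(f, g2)) <= 2.0 + 1e-9

    def test_l1_norm_option(self, rng):
        s = rng.normal(size=(2, 4, 4))
        t = rng.normal(size=(2, 4, 4))
        cfg = DistillConfig(diff_norm="l1")
        vs = oracles.attention_vector(s, (4, 4))
        vt = oracles.attention_vector(t)
        assert float(ufd_loss(s, t, cfg)) == pytest.approx(
            np.abs(vs - vt).sum(), abs=1e-9)


class TestFlfd:
    def _bundle(self, rng, chans, sizes):
        fms = [FeatureMap(rng.normal(size=(c, s, s))) for c, s in zip(chans, sizes)]
        return RepBundle(early=fms[0], mids=fms[1:-1], late=fms[-1])

    def test_zero_when_attention_vectors_coincide(self):
        # constant maps at every tap -> every attention vector is uniform,
        # so both cross-layer terms vanish
        fms = [FeatureMap(np.full((c, s, s), 2.0))
               for c, s in zip([2, 3, 4, 5], [16, 8, 4, 2])]
        b = RepBundle(early=fms[0], mids=fms[1:-1], late=fms[-1])
        assert float(flfd_loss(b, b)) < 1e-6

    def test_additivity(self, rng):
        b = self._bundle(rng, [2, 3, 4, 5], [16, 8, 4, 2])
        bs = self._bundle(rng, [2, 3, 4, 5], [16, 8, 4, 2])
        ufd, ifd = flfd_terms(bs, b)
        assert float(flfd_loss(bs, b)) == pytest.approx(
            float(ufd) + float(ifd), abs=1e-12)
        assert float(flfd_loss(bs, b)) >= max(float(ufd), float(ifd)) >= 0

    def test_scale_invariance_of_losses(self, rng):
        bs = self._bundle(rng, [2, 3, 4], [8, 4, 2])
        bt = self._bundle(rng, [3, 2, 6], [8, 4, 2])
        base = float(flfd_loss(bs, bt))
        bs2 = RepBundle(
            early=FeatureMap(7.0 * bs.early.values.data),
            mids=[FeatureMap(0.01 * m.values.data) for m in bs.mids],
            late=FeatureMap(bs.late.values.data))
        assert float(flfd_loss(bs2, bt)) == pytest.approx(base, abs=1e-6)
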