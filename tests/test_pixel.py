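"""Pixel-level distillation: predictive maps and UPD/IPD KL losses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from hlfd import (DistillConfig, Tensor, ipd_loss, kl_pixelwise, plfd_loss,
                  plfd_terms, teacher_pred_maps, unify_teacher_mid_probs,
                  upd_loss, validate_probmap)
from hlfd.networks import StudentAux, PredBundle

LN2 = np.log(2.0)


def _simplex(rng, k, h, w):
    return oracles.random_simplex_map(rng, k, h, w)


class TestUnifyTeacherMidProbs:
    def test_idempotent_on_identical_maps(self, rng):
        p = _simplex(rng, 2, 4, 4)
        out = unify_teacher_mid_probs([p, p], (4, 4))
        np.testing.assert_allclose(out.data, p, atol=1e-12)

    def test_mean_of_onehots(self):
        a = np.zeros((2, 1, 1)); a[0] = 1.0
        b = np.zeros((2, 1, 1)); b[1] = 1.0
        out = unify_teacher_mid_probs([a, b], (1, 1))
        np.testing.assert_allclose(out.data[:, 0, 0], [0.5, 0.5])

    def test_output_is_valid_probmap(self, rng):
        mids = [_simplex(rng, 3, 8, 8), _simplex(rng, 3, 4, 4)]
        out = unify_teacher_mid_probs(mids, (4, 4))
        validate_probmap(out)

    def test_class_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="class-count"):
            unify_teacher_mid_probs([_simplex(rng, 2, 4, 4),
                                     _simplex(rng, 3, 4, 4)], (4, 4))


class TestKlPixelwise:
    def test_identity_is_zero(self, rng):
        p = _simplex(rng, 3, 5, 5)
        assert float(kl_pixelwise(p, p)) == pytest.approx(0.0, abs=1e-12)

    def test_onehot_vs_uniform_is_ln2(self):
        ps = np.array([1.0, 0.0]).reshape(2, 1, 1)
        pt = np.array([0.5, 0.5]).reshape(2, 1, 1)
        assert float(kl_pixelwise(ps, pt)) == pytest.approx(LN2, abs=1e-6)

    def test_matches_oracle_and_nonnegative(self, rng):
        for _ in range(30):
            ps = _simplex(rng, 2, 3, 4)
            pt = _simplex(rng, 2, 3, 4)
            val = float(kl_pixelwise(ps, pt))
            assert val >= -1e-9
            assert val == pytest.approx(oracles.kl_pixelwise(ps, pt), abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kl_pixelwise(_simplex(rng, 2, 3, 3), _simplex(rng, 2, 4, 4))


class TestUpdIpd:
    def test_zero_when_student_matches_teacher(self, rng):
        logits = rng.normal(size=(2, 4, 4))
        pt = oracles.softmax_np(logits, axis=0)
        assert float(upd_loss(logits, pt)) == pytest.approx(0.0, abs=1e-9)
        assert float(ipd_loss([logits, logits], pt)) == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_on_fixed_inputs(self, rng):
        logits = rng.normal(size=(2, 3, 3))
        pt = _simplex(rng, 2, 6, 6)
        assert float(upd_loss(logits, pt)) == float(upd_loss(logits, pt))

    def test_ipd_averages_not_sums(self):
        # one-hot student logits vs uniform teacher: each layer KL = ln 2
        logits = np.zeros((2, 1, 1)); logits[0] = 50.0
        pt = np.full((2, 1, 1), 0.5)
        one = float(ipd_loss([logits], pt))
        two = float(ipd_loss([logits, logits], pt))
        assert one == pytest.approx(LN2, rel=1e-5)
        assert two == pytest.approx(one, abs=1e-9)  # mean, not sum

    def test_sum_vs_average_asymmetry_against_feature_level(self):
        """The feature-level layer loss sums; the pixel-level one averages."""
        from hlfd import ifd_loss
        s = np.array([[[2.0, 0.0]]])
        t = np.array([[[0.0, 3.0]]])
        assert float(ifd_loss([s, s], t)) == pytest.approx(
            2.0 * float(ifd_loss([s], t)), abs=1e-9)
        logits = np.zeros((2, 1, 1)); logits[0] = 50.0
        pt = np.full((2, 1, 1), 0.5)
        assert float(ipd_loss([logits, logits], pt)) == pytest.approx(
            float(ipd_loss([logits], pt)), abs=1e-9)

    def test_matches_oracle_with_resampling(self, rng):
        for _ in range(30):
            logits = rng.normal(size=(2, 4, 4))
            pt = _simplex(rng, 2, 8, 8)
            assert float(upd_loss(logits, pt)) == pytest.approx(
                oracles.upd(logits, pt), abs=1e-6)
            mids = [rng.normal(size=(2, 4, 4)), rng.normal(size=(2, 2, 2))]
            assert float(ipd_loss(mids, pt)) == pytest.approx(
                oracles.ipd(mids, pt), abs=1e-6)

    @given(shift=st.floats(-30, 30))
    def test_softmax_shift_invariance(self, shift):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(3, 4, 4))
        pt = _simplex(rng, 3, 4, 4)
        base = float(upd_loss(logits, pt))
        assert float(upd_loss(logits + shift, pt)) == pytest.approx(base, abs=1e-7)

    def test_classic_direction_config(self, rng):
        logits = rng.normal(size=(2, 4, 4))
        pt = _simplex(rng, 2, 4, 4)
        ps = oracles.softmax_np(logits, axis=0)
        cfg = DistillConfig(kl_direction="classic")
        assert float(upd_loss(logits, pt, cfg)) == pytest.approx(
            oracles.kl_pixelwise(pt, ps), abs=1e-9)

    def test_empty_mid_list_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            ipd_loss([], _simplex(rng, 2, 4, 4))


class TestTeacherPredMaps:
    def test_probmaps_and_mid_count(self, tiny_pair, rng):
        teacher, _ = tiny_pair
        x = Tensor(rng.random((1, 1, 16, 16)))
        reps = teacher.encode(x)
        bundle = teacher_pred_maps(teacher, reps)
        for m in [bundle.early, *bundle.mids, bundle.late]:
            validate_probmap(m)
            assert m.shape[1] == teacher.spec.num_classes
        assert len(bundle.mids) == teacher.spec.n_mid

    def test_frozen_teacher_repeatable(self, tiny_pair, rng):
        teacher, _ = tiny_pair
        x = Tensor(rng.random((1, 1, 16, 16)))
        b1 = teacher_pred_maps(teacher, teacher.encode(x))
        b2 = teacher_pred_maps(teacher, teacher.encode(x))
        np.testing.assert_array_equal(b1.late.data, b2.late.data)


class TestPlfd:
    def test_additivity_and_perfect_mimicry(self, rng):
        pt_mids = [_simplex(rng, 2, 4, 4), _simplex(rng, 2, 2, 2)]
        pt_late = _simplex(rng, 2, 8, 8)
        bundle = PredBundle(early=Tensor(_simplex(rng, 2, 2, 2)),
                            mids=[Tensor(m) for m in pt_mids],
                            late=Tensor(pt_late))
        aux = StudentAux(early=Tensor(rng.normal(size=(2, 8, 8))),
                         mids=[Tensor(rng.normal(size=(2, 4, 4)))])
        upd, ipd = plfd_terms(aux, bundle)
        total = plfd_loss(aux, bundle)
        assert float(total) == pytest.approx(float(upd) + float(ipd), abs=1e-12)
        assert float(total) >= 0.0
        # student logits matching the teacher's terminal map give IPD ~ 0
        match = StudentAux(
            early=aux.early,
            mids=[Tensor(np.log(pt_late + 1e-12))])
        _, ipd2 = plfd_terms(match, bundle)
        assert float(ipd2) == pytest.approx(0.0, abs=1e-6)
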