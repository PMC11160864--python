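"""Reference networks: taps, determinism, freezing, export, checkpoints."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlfd import (ConfigError, NetworkSpec, Tensor, build_student,
                  build_teacher, default_student_spec, default_teacher_spec,
                  freeze, load_checkpoint, save_checkpoint)
from hlfd.autodiff import Adam
from hlfd.networks import FeatureMap, RepBundle


def _params_snapshot(net):
    return [p.data.copy() for p in net.parameters()]


class TestSpecs:
    def test_teacher_requires_deep_supervision(self):
        with pytest.raises(ConfigError, match="deep_supervision"):
            NetworkSpec(role="teacher", deep_supervision=False)

    def test_too_few_stages_rejected(self):
        # 2 stages leave no middle tap (N = 0)
        with pytest.raises(ConfigError, match="3 stages"):
            NetworkSpec(role="teacher", stage_channels=[8, 16])

    def test_tap_plan_must_be_distinct_and_sized(self):
        with pytest.raises(ConfigError, match="distinct"):
            NetworkSpec(role="student", stage_channels=[4, 8, 12],
                        deep_supervision=False, tap_plan=["a", "a", "b"])
        with pytest.raises(ConfigError, match="tap_plan"):
            NetworkSpec(role="student", stage_channels=[4, 8, 12],
                        deep_supervision=False, tap_plan=["a", "b"])

    def test_role_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="teacher"):
            build_teacher(default_student_spec(), 0)
        with pytest.raises(ConfigError, match="student"):
            build_student(default_teacher_spec(), 0)


class TestTeacher:
    def test_tap_spatial_plan(self, rng):
        teacher = build_teacher(default_teacher_spec(), 0)
        reps, preds = teacher.forward(Tensor(rng.random((1, 1, 64, 64))))
        assert reps.early.spatial == (64, 64)
        assert [m.spatial for m in reps.mids] == [(32, 32), (16, 16)]
        assert reps.late.spatial == (8, 8)
        # one class-logit map per decoder tap: early, mid_j, late
        assert len(preds.mids) == teacher.spec.n_mid
        assert preds.late.shape[-2:] == (64, 64)
        assert preds.early.shape[1] == teacher.spec.num_classes

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = build_teacher(default_teacher_spec(), 42)
        b = build_teacher(default_teacher_spec(), 42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_teacher(default_teacher_spec(), 43)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.parameters(), c.parameters()))


class TestStudent:
    def test_aux_heads_have_class_channels(self, rng):
        student = build_student(default_student_spec(), 1)
        reps, logits, aux = student.forward(Tensor(rng.random((2, 1, 32, 32))))
        assert logits.shape[1] == 2
        assert aux.early.shape[1] == 2
        assert all(m.shape[1] == 2 for m in aux.mids)
        assert len(aux.mids) == student.spec.n_mid

    def test_student_smaller_than_teacher_by_default(self):
        t = build_teacher(default_teacher_spec(), 0)
        s = build_student(default_student_spec(), 0)
        assert s.n_parameters() < t.n_parameters()

    def test_export_drops_aux_and_preserves_output(self, rng):
        student = build_student(default_student_spec(), 2)
        x = Tensor(rng.random((1, 1, 32, 32)))
        _, logits, aux = student.forward(x)
        assert aux is not None
        exported = student.export_for_inference()
        _, logits2, aux2 = exported.forward(x)
        assert aux2 is None
        assert exported.aux_early is None and exported.aux_mids == []
        np.testing.assert_array_equal(logits.data, logits2.data)
        assert exported.n_parameters() < student.n_parameters()


class TestFreeze:
    def test_frozen_teacher_untouched_by_a_distillation_step(self, tiny_pair, rng):
        from hlfd.pipeline import TrainConfig, _distill_step

        teacher, student = tiny_pair
        freeze(teacher)
        before = _params_snapshot(teacher)
        x = rng.random((2, 1, 16, 16))
        y = (rng.random((2, 16, 16)) < 0.3).astype(np.uint8)
        opt = Adam(student.parameters())
        s_before = _params_snapshot(student)
        bd = _distill_step(student, teacher, x, y, TrainConfig(epochs=1))
        opt.zero_grad()
        bd.total.backward()
        opt.step()
        for p, old in zip(teacher.parameters(), before):
            np.testing.assert_array_equal(p.data, old)
        assert all(p.grad is None for p in teacher.parameters())
        # the student did move
        assert any(np.abs(p.data - old).max() > 0
                   for p, old in zip(student.parameters(), s_before))

    def test_frozen_forward_is_repeatable(self, tiny_teacher, rng):
        freeze(tiny_teacher)
        x = Tensor(rng.random((1, 1, 32, 32)))
        _, p1 = tiny_teacher.forward(x)
        _, p2 = tiny_teacher.forward(x)
        np.testing.assert_array_equal(p1.late.data, p2.late.data)


class TestRepBundle:
    @given(st.integers(2, 4), st.integers(1, 3))
    def test_spatial_monotonicity_holds_for_valid_inputs(self, depth_pow, n_mid):
        size = 2 ** (depth_pow + n_mid + 1)
        spec = NetworkSpec(role="teacher",
                           stage_channels=[2] * (n_mid + 2))
        teacher = build_teacher(spec, 0)
        x = Tensor(np.zeros((1, 1, size, size)))
        reps, _ = teacher.forward(x)
        sizes = ([reps.early.spatial] + [m.spatial for m in reps.mids]
                 + [reps.late.spatial])
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_increasing_sizes_rejected(self, rng):
        small = FeatureMap(rng.random((2, 4, 4)))
        big = FeatureMap(rng.random((2, 8, 8)))
        with pytest.raises(ValueError, match="non-increasing"):
            RepBundle(early=small, mids=[big], late=small)

    def test_needs_a_middle_tap(self, rng):
        f = FeatureMap(rng.random((2, 4, 4)))
        with pytest.raises(ValueError, match="middle"):
            RepBundle(early=f, mids=[], late=f)


class TestCheckpoints:
    def test_roundtrip_teacher_and_student(self, tmp_path, rng):
        x = Tensor(rng.random((1, 1, 32, 32)))
        for build, spec in ((build_teacher, default_teacher_spec()),
                            (build_student, default_student_spec())):
            net = build(spec, 9)
            save_checkpoint(net, tmp_path / spec.role)
            back = load_checkpoint(tmp_path / spec.role)
            for pa, pb in zip(net.parameters(), back.parameters()):
                np.testing.assert_array_equal(pa.data, pb.data)
            if spec.role == "teacher":
                np.testing.assert_array_equal(
                    net.forward(x)[1].late.data, back.forward(x)[1].late.data)
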