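import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_teacher():
    """A small 3-stage teacher (N=1 middle tap) shared across tests."""
    from hlfd import NetworkSpec, build_teacher

    spec = NetworkSpec(role="teacher", stage_channels=[4, 8, 12])
    return build_teacher(spec, seed=7)


@pytest.fixture(scope="session")
def tiny_pair():
    """Matching 4-stage teacher/student pair for distillation tests."""
    from hlfd import NetworkSpec, build_student, build_teacher

    t = build_teacher(NetworkSpec(role="teacher", stage_channels=[4, 8, 12, 16]),
                      seed=3)
    s = build_student(NetworkSpec(role="student", stage_channels=[4, 6, 8, 12],
                                  deep_supervision=False), seed=5)
    return t, s


@pytest.fixture(scope="session")
def tiny_dataset():
    """32 easy 32x32 phantoms used by fast training tests."""
    from hlfd import generate_phantoms

    return generate_phantoms(32, size=32, organ="kidney", difficulty="easy",
                             seed=99)
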