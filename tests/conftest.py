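import pytest

from vocalvote import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_spec():
    """Compact study: 12 subjects, 4 tests, 6 features, strong signal on test 2."""
    return SyntheticSpec(
        n_subjects=12,
        n_tests=4,
        n_features=6,
        informative_tests=frozenset({2}),
        informative_features=frozenset({1, 2}),
        effect=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_table(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def study_table():
    """Full-size study conditions: 40 subjects, 26 tests x 26 features."""
    return generate(SyntheticSpec(seed=3))
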