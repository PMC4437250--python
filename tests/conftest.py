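import numpy as np
import pytest

from fscop import LabeledMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_matrix() -> LabeledMatrix:
    """3 features x 4 samples, two classes of two samples each."""
    return LabeledMatrix(
        feature_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [
                [1.0, 3.0, 7.0, 9.0],
                [3.0, 5.0, 2.0, 4.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
        labels=("A", "A", "B", "B"),
    )


@pytest.fixture
def strong_synthetic():
    """Well-separated two-class dataset with 2 informative + 48 noise features."""
    spec = SyntheticSpec(
        n_per_class=(30, 30), p_informative=2, p_noise=48,
        effect_size=10.0, noise_sd=1.0, seed=7,
    )
    return generate(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
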