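import numpy as np
import pytest

from a2isite import (
    BaseLearnerSpec,
    RnaSequence,
    StackingConfig,
    SyntheticDatasetSpec,
    default_signal,
    generate_dataset,
    planted_feature_matrix,
)


def random_sequence(rng: np.random.Generator, length: int) -> RnaSequence:
    return RnaSequence("r", "".join(rng.choice(list("ACGU"), size=length)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fast_config():
    """Compact two-learner stack for protocol tests: small forests, 3 OOF folds."""
    return StackingConfig(
        base=(
            BaseLearnerSpec("ET", {"n_estimators": 40}, seed=11),
            BaseLearnerSpec("LR", seed=12),
        ),
        meta=BaseLearnerSpec("LR", seed=13),
        oof_folds=3,
    )


@pytest.fixture(scope="session")
def separable_matrix():
    """Planted matrix with a large class separation (effectively separable)."""
    return planted_feature_matrix(n=160, n_informative=4, n_noise=6, effect=3.0, seed=5)


@pytest.fixture(scope="session")
def strong_dataset():
    """Synthetic 51-nt windows with a strong positional editing signal."""
    spec = SyntheticDatasetSpec(
        n_pos=60, n_neg=60, window_length=51, signal=default_signal(51, 1.0), seed=7
    )
    return generate_dataset(spec)
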