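import numpy as np
import pytest

from jointcal import FeatureTable, SimConfig, TrainConfig, generate_two_batches
from jointcal.losses import KernelConfig, LossWeights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng) -> FeatureTable:
    """A 12-sample, 4-feature labeled batch with replicate structure."""
    values = rng.uniform(1.0, 9.0, (12, 4))
    subjects = [f"s{i // 2}" for i in range(12)]
    return FeatureTable(
        values, [f"f{j}" for j in range(4)],
        [f"smp{i}" for i in range(12)], subjects, "batchA",
        labels=np.array([0, 0, 1, 1] * 3),
    )


@pytest.fixture
def tiny_sim():
    """A fast, strongly separable two-batch simulation for training tests."""
    cfg = SimConfig(n_features=8, n_subjects_per_batch=60,
                    replicates_per_subject=(1, 2), signal_fraction=0.5,
                    class_effect=1.5, batch_shift=1.0, batch_scale=0.3,
                    nonlinear_warp=0.5, noise_sd=0.4, subject_sd=0.3, seed=7)
    return generate_two_batches(cfg)


@pytest.fixture
def fast_cfg():
    """A short training configuration for unit tests."""
    return TrainConfig(weights=LossWeights(1.0, 1.0, 1.0),
                       kernel=KernelConfig(), epochs=15, minibatch_size=32,
                       learning_rate=1e-3, seed=3)
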