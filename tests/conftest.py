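import numpy as np
import pytest

from cardiofreq.pipeline import ExperimentConfig, build_dataset, one_hot, streams_to_features
from cardiofreq.spectral_features import N_SECTIONS

FEAT_COLS = [f"r{j + 1}" for j in range(N_SECTIONS)]


@pytest.fixture(scope="session")
def small_feature_tables():
    """A reduced-scale synthetic dataset: 60 train / 30 eval streams per class."""
    cfg = ExperimentConfig(train_per_class=60, eval_per_class=30, master_seed=11)
    train_streams, eval_streams = build_dataset(cfg)
    train_df, _, _ = streams_to_features(train_streams)
    eval_df, _, _ = streams_to_features(eval_streams)
    return train_df, eval_df


@pytest.fixture(scope="session")
def small_training_arrays(small_feature_tables):
    train_df, eval_df = small_feature_tables
    return (
        train_df[FEAT_COLS].to_numpy(),
        one_hot(train_df["label"].tolist()),
        eval_df[FEAT_COLS].to_numpy(),
        eval_df["label"].tolist(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
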