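import numpy as np
import pytest

import seminalomics as so


def make_table(
    n_study=64,
    batch_sizes=(32, 32),  # 5 QC/dQC pairs per batch at interval 8
    n_features=20,
    noise_cv=0.0,
    drift_amplitude=0.0,
    batch_offset_step=0.0,
    n_discriminant=0,
    effect_log2=1.0,
    dilution_factor=0.5,
    missing_rate=0.0,
    seed=0,
):
    """Synthetic feature table plus its ground truth (shared helper)."""
    ids = [f"s{i:03d}" for i in range(n_study)]
    seq = so.generate_injection_sequence(ids, list(batch_sizes), qc_interval=8,
                                         n_conditioning=2)
    truth = so.make_ground_truth(
        seq,
        n_features,
        drift_amplitude=drift_amplitude,
        batch_offset_step=batch_offset_step,
        n_discriminant=n_discriminant,
        effect_log2=effect_log2,
        dilution_factor=dilution_factor,
        noise_cv=noise_cv,
        missing_rate=missing_rate,
        seed=seed,
    )
    table = so.generate_feature_table(seq, truth, n_features, seed=seed + 1)
    return table, truth


@pytest.fixture
def clean_table():
    """Noise-free, drift-free two-batch table (exact oracles hold)."""
    return make_table()


@pytest.fixture
def drifty_table():
    """Two batches with 30% drift, offsets and 5% noise."""
    return make_table(noise_cv=0.05, drift_amplitude=0.3, batch_offset_step=0.5,
                      n_features=60, seed=3)


def two_class_data(n_per_class=20, n_informative=5, n_features=30, d=2.0, seed=0):
    """Spherical two-class matrix with a planted mean shift."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array(["low"] * n_per_class + ["high"] * n_per_class)
    X = rng.standard_normal((n, n_features))
    X[y == "high", :n_informative] += d
    return X, y
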