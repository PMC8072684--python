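import numpy as np
import pytest

from gaitceds import (
    ModelConfig,
    SegmentationConfig,
    SyntheticConfig,
    TrainConfig,
    build_classifier,
    fit,
    make_classification_arrays,
)

# Study conditions of the seeded end-to-end fixtures.  The easy task is
# a 10-subject recognition problem with low sensor noise and ~200
# windows per subject; the hard task keeps the subjects but raises the
# noise well above the signal's harmonic amplitudes and shortens the
# recordings.
EASY_SYNTH = dict(
    n_subjects=10, stream_seconds_per_subject=325.0, rate_hz=50.0,
    n_harmonics=4, noise_sd=0.05,
)
HARD_SYNTH = dict(
    n_subjects=10, stream_seconds_per_subject=100.0, rate_hz=50.0,
    n_harmonics=4, noise_sd=1.5,
)
SEGMENTATION = dict(mode="fixed_length", window_len=128, overlap_fraction=0.5)
# Small-fixture training protocol: reference learning rate, batch scaled
# to the fixture size, validation accuracy monitored, bounded epochs.
FIT_KW = dict(learning_rate=1e-4, batch_size=128, monitor="val_accuracy")


def run_task(synth_kw, seed, attention, max_epochs):
    """Generate, segment, train and return (net, history, test set)."""
    cfg = SyntheticConfig(seed=seed, **synth_kw)
    seg = SegmentationConfig(**SEGMENTATION)
    x_tr, y_tr, x_te, y_te = make_classification_arrays(cfg, seg)
    net = build_classifier(
        ModelConfig(n_classes=synth_kw["n_subjects"], attention=attention), seed=seed
    )
    tcfg = TrainConfig(seed=seed, max_epochs=max_epochs, **FIT_KW)
    net, history = fit(net, x_tr[..., None], y_tr, tcfg)
    return dict(
        net=net, history=history, tcfg=tcfg,
        x_train=x_tr, y_train=y_tr, x_test=x_te, y_test=y_te,
    )


@pytest.fixture(scope="session")
def easy_task():
    """One seeded end-to-end run of the attention model on the easy task."""
    return run_task(EASY_SYNTH, seed=1, attention="ceds", max_epochs=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
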