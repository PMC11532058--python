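import numpy as np
import pytest

import fqrs


@pytest.fixture(scope="session")
def templates():
    return fqrs.default_templates()


@pytest.fixture(scope="session")
def clean_record(templates):
    """Zero-noise 10 s record at 250 Hz with 10 known R peaks."""
    return fqrs.generate_ecg12(
        templates, noise=fqrs.NoiseParams.none(), duration=10.0, fs=250.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    return fqrs.detect_r_peaks(clean_record)


@pytest.fixture(scope="session")
def random_segments():
    """100 random finite segments of length 128 for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    return [rng.standard_normal(128) for _ in range(100)]


@pytest.fixture(scope="session")
def small_training_table():
    """Small end-to-end feature table shared by classifier-level tests.

    Uses a sharp annotator panel so enough leads reach full agreement at
    this reduced scale.
    """
    sharp = fqrs.AnnotatorModel(
        sensitivities=(0.95, 0.92, 0.94, 0.96, 0.93),
        specificities=(0.97, 0.96, 0.98, 0.97, 0.96),
    )
    return fqrs.make_training_dataset(
        14, 14, severity_range=(0.6, 1.0), annotators=sharp, seed=7
    )
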