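import numpy as np
import pytest

import ramanclass as rc


@pytest.fixture(scope="session")
def two_class_pp():
    """Preprocessed default two-class cohort (seed 42), shared read-only."""
    return rc.preprocess(rc.default_two_class(42))


@pytest.fixture(scope="session")
def four_group_pp():
    """Preprocessed default four-group cohort (seed 42), shared read-only."""
    return rc.preprocess(rc.default_four_group(42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_set(rng, n_spectra=6, n_points=40, classes=("A", "B")):
    """Small random spectra set with alternating classes."""
    w = np.linspace(900.0, 1800.0, n_points)
    X = rng.normal(1.0, 0.1, (n_spectra, n_points)) + 0.5
    labels = [classes[i % len(classes)] for i in range(n_spectra)]
    return rc.SpectraSet(
        wavenumbers=w,
        intensities=X,
        spectrum_ids=[f"s{i}" for i in range(n_spectra)],
        subject_ids=[f"subj{i // 2}" for i in range(n_spectra)],
        class_labels=labels,
    )
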