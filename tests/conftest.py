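import numpy as np
import pytest

from modnet.estimators import TimeSeries
from modnet.synthetic import ModularCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_ts(rng):
    """A 30 x 6 standardized time series."""
    return TimeSeries.from_raw(rng.standard_normal((30, 6)))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced high-SNR modular cohort: 20 ROIs, 4 modules, 8+10 subjects x 2 scans."""
    spec = ModularCohortSpec(
        n_rois=20,
        n_timepoints=137,
        k_true=4,
        n_subjects_per_class=(8, 10),
        scans_per_subject=2,
        n_discriminative_edges=5,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def scan_116():
    """One full-size synthetic scan: 116 ROIs, 137 time points, 8 modules."""
    spec = ModularCohortSpec(seed=11)
    rng = np.random.default_rng(11)
    from modnet.synthetic import generate_scan

    ts, partition = generate_scan(spec, class_label=0, rng=rng)
    return ts, partition
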