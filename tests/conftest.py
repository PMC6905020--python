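import numpy as np
import pytest

from ionseg import SimConfig, extract_all_windows, make_worked_example, simulate_dataset


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def worked_segments(worked_example):
    return extract_all_windows(worked_example, 5)


@pytest.fixture(scope="session")
def labeled_dataset():
    """Mid-size strong-signal dataset for model-level tests."""
    records = simulate_dataset(SimConfig(n_proteins=20, length_range=(60, 100), seed=42))
    segments = extract_all_windows(records, 9)
    labels = np.array([1 if s.label else -1 for s in segments])
    return records, segments, labels
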