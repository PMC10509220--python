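import numpy as np
import pytest
from hypothesis import settings

from dynaquery import Dataset, Label, Sample, SyntheticConfig, generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """36-sample synthetic dataset (24 included / 12 excluded), easy task."""
    return generate_dataset(
        SyntheticConfig(n_included=24, n_excluded=12, difficulty=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def medium_dataset() -> Dataset:
    """Default-shaped dataset: 120/62 at difficulty 0.4."""
    return generate_dataset(SyntheticConfig(seed=42))


def make_dummy_dataset(n_included: int, n_excluded: int, seed: int = 0) -> Dataset:
    """Label-structure-only dataset with 1x1 images, for split/pool tests."""
    rng = np.random.default_rng(seed)
    samples, labels = [], {}
    for i in range(n_included + n_excluded):
        sid = f"d{i:05d}"
        samples.append(
            Sample(sample_id=sid, image=np.zeros((1, 1)), metadata_raw=rng.normal(size=3))
        )
        labels[sid] = Label.INCLUDED if i < n_included else Label.EXCLUDED
    return Dataset(samples, labels)
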