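import numpy as np
import pytest

from fracsel import LabeledDataset, SynthSpec, generate, min_max_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_csv(tmp_path):
    """3x2 matrix with a named label column."""
    path = tmp_path / "tiny.csv"
    path.write_text("f1,f2,label\n1,2,A\n3,4,A\n5,6,B\n")
    return path


@pytest.fixture
def small_dataset(rng):
    values = rng.uniform(size=(20, 5))
    return LabeledDataset(
        values=values,
        feature_ids=[f"f{j}" for j in range(5)],
        instance_ids=[f"i{i}" for i in range(20)],
        labels=np.array(["A"] * 12 + ["B"] * 8),
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The reference synthetic scenario, normalized, with its ground truth."""
    dataset, informative = generate(SynthSpec())
    return min_max_normalize(dataset), informative
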