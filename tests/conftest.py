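import numpy as np
import pytest

from bioumixer import ModelConfig, RegressionSample, SceneParams, generate_dataset, load_dataset


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_samples(n: int, seed: int, size: int = 64, label_range=(300.0, 3000.0)):
    """Plain random-noise samples: enough for plumbing tests that do not need
    a learnable image→label signal."""
    r = np.random.default_rng(seed)
    return [
        RegressionSample(
            image=r.random((size, size, 3)),
            label=float(r.uniform(*label_range)),
            name=f"s{i}",
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """A small rendered dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("scenes")
    manifest = generate_dataset(60, SceneParams(), seed=7, out_dir=out)
    train = load_dataset(out / "manifest.csv", out, split="train")
    test = load_dataset(out / "manifest.csv", out, split="test")
    return {"dir": out, "manifest": manifest, "train": train, "test": test}
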