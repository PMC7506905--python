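import numpy as np
import pytest

from alcube import (
    HyperCube,
    ReferenceClassifier,
    SampleManifest,
    Stage,
    SynthConfig,
    scaled_preprocess_config,
)
from alcube.experiments import prepare_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube():
    """A 4x4x6 raw cube with wavelengths, for I/O round trips."""
    rng = np.random.default_rng(7)
    return HyperCube(
        pixels=rng.uniform(0, 5000, size=(4, 4, 6)).astype(np.float32),
        sample_id="fixture_cube",
        wavelengths=np.linspace(400, 900, 6),
    )


@pytest.fixture
def normalized_cube():
    """A 12x12x5 cube at the per-channel-standardized stage."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=(12, 12, 5))
    x = (x - x.mean(axis=(0, 1))) / x.std(axis=(0, 1))
    return HyperCube(pixels=x.astype(np.float32), sample_id="norm", stage=Stage.NORMALIZED)


def tiny_manifest_frame():
    import pandas as pd

    rows = []
    for i in range(16):
        rows.append(dict(sample_id=f"t{i:02d}", file_path=f"t{i:02d}", label=i % 2, split="train"))
    for i in range(4):
        rows.append(dict(sample_id=f"s{i:02d}", file_path=f"s{i:02d}", label=i % 2, split="test"))
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_manifest():
    return SampleManifest(tiny_manifest_frame())


@pytest.fixture(scope="session")
def bench_dataset():
    """Small preprocessed synthetic dataset (augmented train split) shared
    across loop/classifier tests: 2 classes x 10 samples, 6x-augmented."""
    synth = SynthConfig(
        n_per_class=10,
        height=(40, 50),
        width=(40, 50),
        n_channels=120,
        seed=11,
    )
    pcfg = scaled_preprocess_config(synth.n_channels)
    manifest, cubes = prepare_benchmark(synth, pcfg)
    return manifest, cubes


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated, low-heterogeneity dataset (no augmentation)."""
    synth = SynthConfig.separable(
        n_per_class=30, height=(40, 50), width=(40, 50), n_channels=120, seed=5
    )
    pcfg = scaled_preprocess_config(synth.n_channels)
    manifest, cubes = prepare_benchmark(synth, pcfg, augment=False)
    return manifest, cubes


@pytest.fixture(scope="session")
def reference_backend():
    return ReferenceClassifier()
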