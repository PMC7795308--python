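import numpy as np
import pytest

from dbnscreen import ActivityClassSpec, FingerprintMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_matrix() -> FingerprintMatrix:
    """Four molecules, six binary features, two activity classes."""
    values = np.array([
        [1, 0, 0, 1, 1, 0],
        [1, 1, 0, 1, 0, 0],
        [0, 0, 1, 0, 1, 1],
        [0, 1, 1, 0, 0, 1],
    ], dtype=float)
    ids = ["m1", "m2", "m3", "m4"]
    labels = {"m1": "A", "m2": "A", "m3": "B", "m4": "B"}
    return FingerprintMatrix("toy", ids, labels, values)


@pytest.fixture
def planted_dataset():
    """Default desk-scale synthetic dataset with its ground-truth manifest."""
    spec = SyntheticSpec(seed=42)
    matrices, manifest = generate(spec)
    return spec, matrices, manifest


def planted_single(seed: int, **overrides):
    """One-descriptor planted dataset for parameter-recovery runs."""
    kw = dict(
        class_specs=(ActivityClassSpec("A", 100), ActivityClassSpec("B", 100)),
        n_features=64, n_descriptors=1, signal_bits_per_class=8,
        n_outlier_features=8, seed=seed,
    )
    kw.update(overrides)
    spec = SyntheticSpec(**kw)
    matrices, manifest = generate(spec)
    fp = matrices[0]
    info = manifest["descriptors"][fp.descriptor_name]
    signal = sorted(int(i) for v in info["signal_bits"].values() for i in v)
    outliers = [int(i) for i in info["outlier_features"]]
    return fp, signal, outliers
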