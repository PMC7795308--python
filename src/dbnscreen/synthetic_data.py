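"""Synthetic multi-descriptor fingerprint datasets with planted structure.

The licensed MDDR benchmark cannot be redistributed, so this module emulates
the statistical structure the reweighting method exploits: several activity
classes of chosen sizes, a block of class-correlated "signal" bits per class
(on with high probability inside the class, background rate elsewhere),
uninformative background bits, and a controllable set of outlier features
whose bits flip independently with probability 0.5 regardless of class —
maximally non-reconstructible noise.

Each descriptor shares the molecules and labels but draws independent signal
bit positions, mimicking complementary fingerprint types.  Generation is
fully deterministic given the seed; a ground-truth manifest records the
planted indices per descriptor for downstream recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fingerprint_io import ActivityClassSpec, FingerprintMatrix

__all__ = ["SyntheticSpec", "generate", "write_dataset"]

#: study-condition defaults for desk-scale experiments
DEFAULT_CLASSES = (
    ActivityClassSpec("classA", 100),
    ActivityClassSpec("classB", 100),
)


@dataclass
class SyntheticSpec:
    """Parameters of a planted-signal multi-descriptor dataset.

    Attributes
    ----------
    class_specs:
        Activity classes and their sizes.
    n_features:
        Feature count M per descriptor.
    n_descriptors:
        Number of descriptors (shared molecules, independent signal bits).
    signal_bits_per_class:
        Number of class-correlated bits planted per class per descriptor.
    p_signal_on:
        Probability a signal bit is set for molecules of its own class.
    p_background_on:
        Probability any non-signal (and out-of-class signal) bit is set.
    n_outlier_features:
        Number of outlier columns per descriptor, drawn disjoint from
        signal bits and flipped on with probability 0.5 for every molecule.
    outlier_features:
        Optional explicit outlier column indices (shared by all
        descriptors); overrides ``n_outlier_features``.  Signal bits are
        then drawn from the remaining columns so the sets stay disjoint.
    seed:
        Mandatory seed; all randomness derives from it.
    """

    class_specs: tuple[ActivityClassSpec, ...] = DEFAULT_CLASSES
    n_features: int = 64
    n_descriptors: int = 3
    signal_bits_per_class: int = 8
    p_signal_on: float = 0.9
    p_background_on: float = 0.15
    n_outlier_features: int = 8
    outlier_features: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_specs = tuple(self.class_specs)
        if not self.class_specs:
            raise ValueError("at least one activity class is required")
        if self.outlier_features is not None:
            self.outlier_features = tuple(int(i) for i in self.outlier_features)
            if any(i < 0 or i >= self.n_features for i in self.outlier_features):
                raise ValueError("outlier_features out of range")
            self.n_outlier_features = len(self.outlier_features)
        if not (0.0 <= self.p_background_on < self.p_signal_on <= 1.0):
            raise ValueError(
                "require 0 <= p_background_on < p_signal_on <= 1, got "
                f"{self.p_background_on} and {self.p_signal_on}"
            )
        needed = (len(self.class_specs) * self.signal_bits_per_class
                  + self.n_outlier_features)
        if needed > self.n_features:
            raise ValueError(
                f"{needed} signal+outlier features do not fit in M={self.n_features}"
            )
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    @property
    def n_molecules(self) -> int:
        return sum(c.class_size for c in self.class_specs)


def generate(spec: SyntheticSpec) -> tuple[list[FingerprintMatrix], dict]:
    """Draw the dataset: one binary matrix per descriptor plus a manifest.

    Returns
    -------
    matrices:
        One :class:`FingerprintMatrix` per descriptor.  All share
        ``molecule_ids`` and ``activity_labels``.
    manifest:
        ``{"seed", "classes", "descriptors": {name: {"signal_bits":
        {class_id: [indices]}, "outlier_features": [indices]}}}``.
    """
    rng_root = np.random.default_rng(spec.seed)

    molecule_ids: list[str] = []
    labels: dict[str, str] = {}
    class_of_row: list[str] = []
    for cs in spec.class_specs:
        for i in range(cs.class_size):
            mid = f"{cs.class_id}_{i:04d}"
            molecule_ids.append(mid)
            labels[mid] = cs.class_id
            class_of_row.append(cs.class_id)
    row_class = np.asarray(class_of_row)
    n = len(molecule_ids)

    matrices: list[FingerprintMatrix] = []
    manifest: dict = {
        "seed": spec.seed,
        "classes": {c.class_id: c.class_size for c in spec.class_specs},
        "descriptors": {},
    }

    for d in range(spec.n_descriptors):
        rng = np.random.default_rng(rng_root.integers(2**31))
        name = f"FP{d}"
        # disjoint draws: signal blocks per class first, then outliers
        n_signal = len(spec.class_specs) * spec.signal_bits_per_class
        if spec.outlier_features is not None:
            outliers = np.sort(np.asarray(spec.outlier_features, dtype=int))
            pool = np.setdiff1d(np.arange(spec.n_features), outliers)
            special = rng.choice(pool, size=n_signal, replace=False)
        else:
            special = rng.choice(
                spec.n_features,
                size=n_signal + spec.n_outlier_features,
                replace=False,
            )
            outliers = np.sort(special[n_signal:])
        signal_bits: dict[str, np.ndarray] = {}
        for ci, cs in enumerate(spec.class_specs):
            lo = ci * spec.signal_bits_per_class
            signal_bits[cs.class_id] = np.sort(
                special[lo:lo + spec.signal_bits_per_class]
            )

        p = np.full((n, spec.n_features), spec.p_background_on)
        for cs in spec.class_specs:
            rows = row_class == cs.class_id
            p[np.ix_(rows, signal_bits[cs.class_id])] = spec.p_signal_on
        p[:, outliers] = 0.5
        values = (rng.random((n, spec.n_features)) < p).astype(float)

        matrices.append(FingerprintMatrix(
            descriptor_name=name,
            molecule_ids=list(molecule_ids),
            activity_labels=dict(labels),
            values=values,
        ))
        manifest["descriptors"][name] = {
            "signal_bits": {c: sig.tolist() for c, sig in signal_bits.items()},
            "outlier_features": outliers.tolist(),
        }

    return matrices, manifest


def write_dataset(matrices: list[FingerprintMatrix], manifest: dict,
                  outdir: str | Path) -> list[Path]:
    """Write one dense matrix file per descriptor plus ``manifest.json``."""
    from .fingerprint_io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fp in matrices:
        p = outdir / f"{fp.descriptor_name}.csv"
        write_matrix(fp, p)
        paths.append(p)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths.append(mpath)
    return paths
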