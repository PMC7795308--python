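"""Reading, validating and writing molecular fingerprint matrices.

A fingerprint matrix holds one row per molecule and one column per (folded)
fingerprint feature, together with a molecule identifier and a bioactivity
class label per row.  Two plain-text layouts are supported:

* ``dense`` — one CSV/TSV row per molecule: ``molecule_id, activity_class,
  v_0, ..., v_{M-1}``.
* ``sparse`` — one whitespace-separated row per molecule: ``molecule_id
  activity_class i_1 i_2 ...`` listing the 0-based indices of set bits; the
  total feature count ``n_features`` must be supplied when reading.

Feature indices are 0-based throughout the package.  Count fingerprints
(e.g. ECFC variants) are mapped onto {0, 1} with :func:`binarize` before
Bernoulli RBM training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FingerprintMatrix",
    "ActivityClassSpec",
    "FingerprintFormatError",
    "read_fingerprints",
    "write_matrix",
    "binarize",
]


class FingerprintFormatError(ValueError):
    """Raised when a fingerprint file or matrix violates the format contract."""


@dataclass(frozen=True)
class ActivityClassSpec:
    """An activity class and how many active molecules it contains."""

    class_id: str
    class_size: int

    def __post_init__(self) -> None:
        if self.class_size < 1:
            raise ValueError(f"class_size must be >= 1, got {self.class_size}")


@dataclass
class FingerprintMatrix:
    """Molecules x features matrix with identifiers and activity labels.

    Parameters
    ----------
    descriptor_name:
        Opaque label for the fingerprint type (e.g. ``"ECFC4"``).
    molecule_ids:
        Unique molecule identifiers, one per row, order matching ``values``.
    activity_labels:
        Mapping ``molecule_id -> activity class`` covering every molecule.
    values:
        ``(N, M)`` array of non-negative feature values (binary or counts).
    """

    descriptor_name: str
    molecule_ids: list[str]
    activity_labels: dict[str, str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FingerprintFormatError(
                f"values must be 2-D, got shape {self.values.shape}"
            )
        n = len(self.molecule_ids)
        if len(set(self.molecule_ids)) != n:
            raise FingerprintFormatError("molecule_ids must be unique")
        if self.values.shape[0] != n:
            raise FingerprintFormatError(
                f"{n} molecule_ids but {self.values.shape[0]} value rows"
            )
        missing = [m for m in self.molecule_ids if m not in self.activity_labels]
        if missing:
            raise FingerprintFormatError(
                f"molecules without activity label: {missing[:5]}"
            )
        if self.values.size and self.values.min() < 0:
            raise FingerprintFormatError("fingerprint values must be non-negative")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels_array(self) -> np.ndarray:
        """Activity labels in row order, as an object array."""
        return np.asarray([self.activity_labels[m] for m in self.molecule_ids])

    def with_values(self, values: np.ndarray, descriptor_name: str | None = None
                    ) -> "FingerprintMatrix":
        """Copy of this matrix with new values (same molecules and labels)."""
        return FingerprintMatrix(
            descriptor_name=descriptor_name or self.descriptor_name,
            molecule_ids=list(self.molecule_ids),
            activity_labels=dict(self.activity_labels),
            values=np.asarray(values, dtype=float),
        )

    def select_columns(self, indices: Sequence[int],
                       descriptor_name: str | None = None) -> "FingerprintMatrix":
        """Sub-matrix restricted to the given feature columns, order kept."""
        idx = np.asarray(list(indices), dtype=int)
        return self.with_values(self.values[:, idx], descriptor_name)


def _split_line(line: str) -> list[str]:
    # dense rows may be comma- or tab-separated
    sep = "," if "," in line else "\t"
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def read_fingerprints(
    path: str | Path,
    format: str = "dense",
    *,
    n_features: int | None = None,
    descriptor_name: str | None = None,
) -> FingerprintMatrix:
    """Read a fingerprint matrix from a delimited text file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"dense"`` (CSV/TSV, one value per feature) or ``"sparse"``
        (whitespace-separated 0-based set-bit indices).
    n_features:
        Required for ``sparse``: the total feature count M.
    descriptor_name:
        Label for the returned matrix; defaults to the file stem.

    Raises
    ------
    FingerprintFormatError
        On malformed rows (naming the 1-based line number), duplicate
        molecule ids, negative values or out-of-range sparse indices.
    """
    path = Path(path)
    if format not in ("dense", "sparse"):
        raise ValueError(f"unknown format {format!r}")
    if format == "sparse" and n_features is None:
        raise ValueError("n_features is required for the sparse format")

    ids: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    width: int | None = None
    header_name: str | None = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            if raw.lstrip().startswith("#"):
                for tok in raw.lstrip("# \t").split():
                    if tok.startswith("descriptor="):
                        header_name = tok.split("=", 1)[1]
                    elif tok.startswith("n_features=") and width is None:
                        width = int(tok.split("=", 1)[1])
                continue
            if format == "dense":
                parts = _split_line(raw)
                if len(parts) < 2:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: expected id, class and values"
                    )
                mol, cls, *vals = parts
                try:
                    row = np.array([float(v) for v in vals], dtype=float)
                except ValueError as exc:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: non-numeric value ({exc})"
                    ) from None
                if width is None:
                    width = row.size
                elif row.size != width:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: row has {row.size} values, "
                        f"expected {width}"
                    )
            else:
                parts = raw.split()
                if len(parts) < 2:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: expected id, class and indices"
                    )
                mol, cls, *idx_s = parts
                try:
                    idx = [int(i) for i in idx_s]
                except ValueError:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: non-integer bit index"
                    ) from None
                bad = [i for i in idx if i < 0 or i >= int(n_features)]
                if bad:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: bit index out of range: {bad[0]}"
                    )
                row = np.zeros(int(n_features), dtype=float)
                row[idx] = 1.0
            if mol in labels:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: duplicate molecule_id {mol!r}"
                )
            ids.append(mol)
            labels[mol] = cls
            rows.append(row)

    m = width if format == "dense" else int(n_features)
    values = np.vstack(rows) if rows else np.empty((0, m or 0))
    return FingerprintMatrix(
        descriptor_name=descriptor_name or header_name or path.stem,
        molecule_ids=ids,
        activity_labels=labels,
        values=values,
    )


def write_matrix(fp: FingerprintMatrix, path: str | Path) -> None:
    """Write a matrix in the dense CSV layout (round-trips with ``read``).

    Binary matrices are written as integers so the round-trip is exact;
    continuous values use ``repr`` precision.
    """
    path = Path(path)
    is_binary = fp.values.size == 0 or np.array_equal(
        fp.values, fp.values.astype(int)
    )
    with path.open("w") as fh:
        fh.write(f"# descriptor={fp.descriptor_name} n_features={fp.n_features}\n")
        for mol, row in zip(fp.molecule_ids, fp.values):
            if is_binary:
                vals = ",".join(str(int(v)) for v in row)
            else:
                vals = ",".join(repr(float(v)) for v in row)
            fh.write(f"{mol},{fp.activity_labels[mol]}" + ("," + vals if fp.n_features else "") + "\n")


def binarize(fp: FingerprintMatrix, threshold: float = 0.0) -> FingerprintMatrix:
    """Map count values onto {0, 1}: entry -> 1 iff entry > threshold.

    Idempotent for already-binary matrices at the default threshold.  The
    descriptor name is annotated with ``"binarized"`` (once).
    """
    if fp.values.size and fp.values.min() < 0:
        raise FingerprintFormatError("cannot binarize negative values")
    name = fp.descriptor_name
    if not name.endswith(":binarized"):
        name = f"{name}:binarized"
    return fp.with_values((fp.values > threshold).astype(float), name)
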