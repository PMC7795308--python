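"""Reconstruction-error PCA, low-error feature selection and descriptor fusion.

After DBN training, each feature (column of the fingerprint matrix) has a
reconstruction-error profile across molecules.  Transposing the N x M error
matrix E gives T = E^T whose rows are features; centering each row across
molecules gives the deviation matrix D, and the Gram/covariance matrix
C = D D^T (no 1/(N-1) normalization — scaling changes neither eigenvectors
nor relative distances).  The top-k eigenvectors of C span the error-PCA
space; each feature's coordinates are its projections onto the principal
directions of D's row space (equivalently U_k diag(s_k) from the SVD
D = U S V^T, since C = U S^2 U^T), and its distance to the origin
sqrt(x^2 + y^2 + z^2) scores how anomalous its error profile is.  Features
near the origin reconstruct consistently and are kept.

Per descriptor, the features with the smallest distances (subject to an
optional distance threshold, default 3.0, and a top-k cap, default 300) are
selected; selections from several descriptors are fused by column-wise
concatenation into a single combined descriptor with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .dbn import ReconstructionResult
from .fingerprint_io import FingerprintMatrix

__all__ = [
    "ErrorPCA",
    "SelectedFeatureSet",
    "CombinedDescriptor",
    "build_error_pca",
    "select_features",
    "combine_descriptors",
    "enumerate_combinations",
]


@dataclass
class ErrorPCA:
    """PCA of the transposed reconstruction-error matrix.

    ``T`` is M x N (features by molecules), ``D`` its row-centered form,
    ``C = D D^T``.  ``components`` holds the top-k orthonormal eigenvectors
    of C as columns (nonincreasing eigenvalues), ``coords`` the M x k
    feature coordinates and ``dist`` the per-feature distance to the origin.
    """

    T: np.ndarray
    mu: np.ndarray
    D: np.ndarray
    C: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    coords: np.ndarray
    dist: np.ndarray


def build_error_pca(E: np.ndarray, k: int = 3) -> ErrorPCA:
    """Project per-feature error profiles onto the top-k principal axes.

    Parameters
    ----------
    E:
        N x M reconstruction-error matrix (molecules by features).
    k:
        Number of principal components (default 3: PCA1..PCA3).

    Eigenvectors are sign-fixed so each component's largest-magnitude entry
    is positive; degenerate spectra are resolved by this convention plus
    eigenvalue order.  A zero-variance E yields all-zero coordinates and
    distances.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    n, m = E.shape
    if n < 2:
        raise ValueError("need at least 2 molecules")
    if k < 1 or k > m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    T = E.T                                   # (M, N)
    mu = T.mean(axis=1)
    D = T - mu[:, None]
    C = D @ D.T                               # (M, M)
    eigvals, eigvecs = np.linalg.eigh(C)      # ascending
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order][:k]
    U = eigvecs[:, order][:, :k]
    # sign convention: largest-|.| entry of each component positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    # coords = projections of D's rows onto its principal directions
    # = U_k diag(s_k) since C = U S^2 U^T
    s = np.sqrt(np.clip(eigvals, 0.0, None))
    coords = U * s[None, :]
    dist = np.sqrt((coords ** 2).sum(axis=1))
    return ErrorPCA(T=T, mu=mu, D=D, C=C, eigenvalues=eigvals,
                    components=U, coords=coords, dist=dist)


@dataclass
class SelectedFeatureSet:
    """Features chosen for one descriptor, lowest error-distance first."""

    descriptor_name: str
    selected_indices: list[int]
    scores: list[float]
    threshold_used: float
    top_k_used: int

    def __len__(self) -> int:
        return len(self.selected_indices)


def select_features(
    pca: ErrorPCA,
    threshold: float = 3.0,
    top_k: int = 300,
    descriptor_name: str = "",
) -> SelectedFeatureSet:
    """Keep the features closest to the PCA origin.

    Features with ``dist <= threshold`` are sorted by ascending distance
    (ties by ascending original index) and truncated to ``top_k``.  An
    empty selection is returned (not raised) if nothing passes.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ok = np.flatnonzero(pca.dist <= threshold)
    order = ok[np.lexsort((ok, pca.dist[ok]))][:top_k]
    return SelectedFeatureSet(
        descriptor_name=descriptor_name,
        selected_indices=[int(i) for i in order],
        scores=[float(pca.dist[i]) for i in order],
        threshold_used=float(threshold),
        top_k_used=int(top_k),
    )


@dataclass
class CombinedDescriptor:
    """Column-wise fusion of selected features from several descriptors."""

    parts: list[tuple[str, list[int]]]
    total_width: int
    provenance: dict[int, tuple[str, int]]   # combined column -> (descriptor, original index)


def combine_descriptors(
    sets: list[SelectedFeatureSet],
    matrices: list,
) -> tuple[CombinedDescriptor, FingerprintMatrix]:
    """Concatenate each descriptor's selected columns into one matrix.

    ``matrices`` supplies the values per descriptor: either the original
    :class:`FingerprintMatrix` (binary bits) or a reconstruction paired with
    a matrix via ``(FingerprintMatrix, ReconstructionResult)`` semantics —
    pass a FingerprintMatrix whose ``values`` are the reconstructed weights
    (see :meth:`FingerprintMatrix.with_values`).  All matrices must share
    ``molecule_ids`` in the same order.
    """
    if len(sets) != len(matrices):
        raise ValueError("one matrix per selected set is required")
    mats: list[FingerprintMatrix] = []
    for s, m in zip(sets, matrices):
        if isinstance(m, ReconstructionResult):
            raise TypeError(
                "wrap reconstructed values with FingerprintMatrix.with_values "
                "so molecule ids and labels travel along"
            )
        mats.append(m)
    ref_ids = mats[0].molecule_ids
    for m in mats[1:]:
        if m.molecule_ids != ref_ids:
            raise ValueError("molecule_ids differ across descriptors")
    blocks = []
    parts = []
    provenance: dict[int, tuple[str, int]] = {}
    col = 0
    for s, m in zip(sets, mats):
        blocks.append(m.values[:, s.selected_indices])
        parts.append((s.descriptor_name or m.descriptor_name,
                      list(s.selected_indices)))
        for orig in s.selected_indices:
            provenance[col] = (s.descriptor_name or m.descriptor_name, orig)
            col += 1
    combined_values = (np.hstack(blocks) if blocks
                       else np.empty((len(ref_ids), 0)))
    combined = mats[0].with_values(
        combined_values,
        descriptor_name="+".join(p[0] for p in parts),
    )
    desc = CombinedDescriptor(parts=parts, total_width=col,
                              provenance=provenance)
    return desc, combined


def enumerate_combinations(descriptor_names: list[str]) -> list[tuple[str, ...]]:
    """All descriptor subsets of size >= 2, ordered by size then name."""
    names = list(descriptor_names)
    if len(names) < 2:
        raise ValueError("need at least 2 descriptor names")
    if len(set(names)) != len(names):
        raise ValueError("descriptor names must be unique")
    out: list[tuple[str, ...]] = []
    for size in range(2, len(names) + 1):
        out.extend(combinations(sorted(names), size))
    return out
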