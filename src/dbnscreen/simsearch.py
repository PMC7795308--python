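"""Tanimoto similarity searching over a fingerprint database.

For a binary representation the Tanimoto coefficient of two bit vectors is
``|a AND b| / (|a| + |b| - |a AND b|``); for non-negative continuous vectors
the generalization ``a.b / (|a|^2 + |b|^2 - a.b)`` is used, which reduces to
the binary form on 0/1 inputs.  A reference structure (query) is scored
against every other molecule in the database, the list is ranked by
descending similarity (ties broken by ascending molecule id) and a top-n%
cutoff — ceil(fraction x database size) after excluding the query — defines
the retrieved set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fingerprint_io import FingerprintMatrix

__all__ = [
    "RankedList",
    "tanimoto_binary",
    "tanimoto_continuous",
    "rank_database",
    "apply_cutoff",
]


def tanimoto_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Binary Tanimoto: common on-bits over union of on-bits; 0 if both empty."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    common = int(np.count_nonzero(a & b))
    denom = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - common
    return common / denom if denom else 0.0


def tanimoto_continuous(a: np.ndarray, b: np.ndarray) -> float:
    """Continuous Tanimoto on non-negative vectors; 0 if both are zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    return dot / denom if denom else 0.0


@dataclass
class RankedList:
    """Similarity ranking of a database against one reference structure.

    ``entries`` is ``[(molecule_id, score), ...]`` in nonincreasing score
    order with ties broken by ascending molecule id; the query itself is
    excluded.  ``retrieved_ids`` caches the ids within the applied cutoff.
    """

    query_id: str
    entries: list[tuple[str, float]]
    cutoff_fraction: float | None = None
    retrieved_ids: list[str] | None = None


def _scores_against(query_row: np.ndarray, values: np.ndarray,
                    mode: str) -> np.ndarray:
    if mode == "binary":
        q = query_row.astype(bool)
        db = values.astype(bool)
        common = (db & q).sum(axis=1)
        denom = db.sum(axis=1) + q.sum() - common
        with np.errstate(invalid="ignore"):
            s = np.where(denom > 0, common / np.maximum(denom, 1), 0.0)
        return s.astype(float)
    if mode == "continuous":
        dot = values @ query_row
        denom = (values ** 2).sum(axis=1) + float(query_row @ query_row) - dot
        return np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    raise ValueError("mode must be 'binary' or 'continuous'")


def rank_database(
    query_id: str,
    matrix: FingerprintMatrix,
    mode: str = "continuous",
    *,
    exclude_query: bool = True,
) -> RankedList:
    """Rank all database molecules by Tanimoto similarity to the query.

    The reference structure is excluded from its own ranked list by default
    (set ``exclude_query=False`` to keep it).  Deterministic: ties are
    resolved by ascending molecule id.
    """
    try:
        qi = matrix.molecule_ids.index(query_id)
    except ValueError:
        raise KeyError(f"unknown query_id {query_id!r}") from None
    scores = _scores_against(matrix.values[qi], matrix.values, mode)
    ids = np.asarray(matrix.molecule_ids, dtype=object)
    mask = np.ones(len(ids), dtype=bool)
    if exclude_query:
        mask[qi] = False
    ids = ids[mask]
    scores = scores[mask]
    order = np.lexsort((ids, -scores))
    entries = [(str(ids[i]), float(scores[i])) for i in order]
    return RankedList(query_id=query_id, entries=entries)


def apply_cutoff(ranked: RankedList, fraction: float) -> list[str]:
    """Ids of the top ``ceil(fraction x len(list))`` ranked molecules."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(ranked.entries))
    retrieved = [mid for mid, _ in ranked.entries[:n]]
    ranked.cutoff_fraction = fraction
    ranked.retrieved_ids = retrieved
    return retrieved
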