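"""Recall protocol and Kendall-W concordance for screening benchmarks.

The recall protocol: for each activity class, draw ``n_refs`` reference
structures at random (without replacement, seeded), rank the rest of the
database against each, apply a top-n% cutoff and count the retrieved
molecules that share the reference's class.  Recall is reported as a
percentage of the class's other actives (the reference itself is excluded
from both the ranked list and the denominator).  Per-class recalls averaged
over references form a classes x methods table, summarized by column means,
per-method gains and best-in-class counts.

Method agreement across classes is quantified by Kendall's coefficient of
concordance W: with each activity class acting as a judge ranking the n
methods (rank n = highest recall, mid-ranks on ties), the rank sums
R_i = sum_j r_ij deviate from the grand mean R-bar = m(n+1)/2 by
S = sum_i (R_i - R-bar)^2, and

    W = 12 S / (m^2 (n^3 - n)),

ranging from 0 (no agreement) to 1 (complete agreement).  Significance uses
the chi-square approximation chi2 = m (n - 1) W on n - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .fingerprint_io import FingerprintMatrix
from .simsearch import apply_cutoff, rank_database

__all__ = [
    "RecallTable",
    "ConcordanceResult",
    "recall",
    "class_recall",
    "build_recall_table",
    "gains",
    "kendall_w",
]


def recall(
    retrieved_ids: list[str],
    query_id: str,
    activity_labels: dict[str, str],
) -> float:
    """Percent of the query's other actives among the retrieved molecules.

    ``100 x |retrieved with the query's class| / (class size - 1)``.  The
    query must already be excluded from ``retrieved_ids``.
    """
    if query_id in retrieved_ids:
        raise ValueError("query must be excluded from the retrieved list")
    cls = activity_labels[query_id]
    class_size = sum(1 for c in activity_labels.values() if c == cls)
    if class_size < 2:
        raise ValueError(
            f"class {cls!r} has a single member; recall is undefined"
        )
    hits = sum(1 for m in retrieved_ids if activity_labels.get(m) == cls)
    return 100.0 * hits / (class_size - 1)


def class_recall(
    matrix: FingerprintMatrix,
    class_id: str,
    n_refs: int = 10,
    cutoff: float = 0.01,
    seed: int = 0,
    mode: str = "continuous",
) -> float:
    """Mean recall over seeded random reference structures of one class.

    Reference structures are sampled without replacement; if the class has
    fewer than ``n_refs`` members, all of them are used (with a warning).
    """
    members = [m for m in matrix.molecule_ids
               if matrix.activity_labels[m] == class_id]
    if not members:
        raise ValueError(f"no molecules with class {class_id!r}")
    rng = np.random.default_rng(seed)
    if len(members) < n_refs:
        warnings.warn(
            f"class {class_id!r} has {len(members)} members < n_refs="
            f"{n_refs}; using all members as references", stacklevel=2,
        )
        refs = list(members)
    else:
        refs = [members[i] for i in
                rng.choice(len(members), size=n_refs, replace=False)]
    vals = []
    for q in refs:
        ranked = rank_database(q, matrix, mode=mode)
        retrieved = apply_cutoff(ranked, cutoff)
        vals.append(recall(retrieved, q, matrix.activity_labels))
    return float(np.mean(vals))


@dataclass
class RecallTable:
    """Classes x methods recall table with the standard summary rows."""

    dataset_name: str
    cutoff_fraction: float
    rows: pd.DataFrame                   # index: class id, columns: methods
    column_means: dict[str, float]
    best_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Table plus ``Mean`` and ``Best`` summary rows."""
        out = self.rows.copy()
        out.loc["Mean"] = pd.Series(self.column_means)
        out.loc["Best"] = pd.Series(self.best_counts)
        return out


def build_recall_table(
    per_method: dict[str, dict[str, float]],
    dataset_name: str = "",
    cutoff_fraction: float = float("nan"),
) -> RecallTable:
    """Assemble a recall table from ``{method: {class_id: recall%}}``.

    Column means are arithmetic means over classes; ``best_counts`` credits
    every method tied for the row maximum of each class.
    """
    df = pd.DataFrame(per_method)
    if df.isna().any().any():
        missing = df.stack(future_stack=True)
        missing = missing[missing.isna()]
        raise ValueError(f"missing recall cells: {list(missing.index)[:5]}")
    if ((df < 0) | (df > 100)).any().any():
        raise ValueError("recall values must be within [0, 100]")
    means = {m: float(df[m].mean()) for m in df.columns}
    row_max = df.max(axis=1)
    best = {m: int((df[m] >= row_max - 1e-12).sum()) for m in df.columns}
    return RecallTable(
        dataset_name=dataset_name,
        cutoff_fraction=cutoff_fraction,
        rows=df,
        column_means=means,
        best_counts=best,
    )


def _printed_mean(column) -> Decimal:
    """Column mean at table precision: exact decimal mean of the 2-decimal
    cell values, rounded half-up to 2 decimals as summary rows print it."""
    cells = [Decimal(repr(float(v))) for v in column]
    mean = sum(cells) / Decimal(len(cells))
    return mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def gains(table: RecallTable, reference_method: str) -> dict[str, float]:
    """Advantage of ``reference_method`` over every method's column mean.

    Computed as the difference of the table-precision (2-decimal,
    half-up-rounded) column means — the convention summary narratives use —
    so the values agree with what a reader derives from a printed table.
    Positive values favor the reference; the gain over itself is 0.
    """
    if reference_method not in table.rows.columns:
        raise KeyError(f"{reference_method!r} not in table")
    ref = _printed_mean(table.rows[reference_method])
    return {m: float(ref - _printed_mean(table.rows[m]))
            for m in table.rows.columns}


@dataclass
class ConcordanceResult:
    """Kendall-W concordance of judges' (classes') method rankings."""

    rank_matrix: np.ndarray   # (m judges, n objects)
    totals: np.ndarray        # R_i, length n
    grand_mean: float         # R-bar = m(n+1)/2
    S: float
    W: float
    m: int
    n: int
    p_value: float

    @property
    def mean_ranks(self) -> np.ndarray:
        return self.totals / self.m


def kendall_w(recall_rows) -> ConcordanceResult:
    """Kendall's coefficient of concordance over a judges x objects table.

    ``recall_rows`` is an (m judges x n objects) array or DataFrame of
    scores; within each judge's row the highest score receives rank n
    (mid-ranks on ties).  Returns W, the rank sums and the chi-square
    p-value (chi2 = m(n-1)W, df = n-1).
    """
    X = np.asarray(
        recall_rows.values if isinstance(recall_rows, pd.DataFrame)
        else recall_rows, dtype=float,
    )
    if X.ndim != 2:
        raise ValueError("expected a 2-D judges x objects table")
    m, n = X.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 judges and 2 objects")
    ranks = np.vstack([rankdata(row) for row in X])   # 1 = lowest score
    totals = ranks.sum(axis=0)
    grand = m * (n + 1) / 2.0
    S = float(((totals - grand) ** 2).sum())
    W = 12.0 * S / (m * m * (n ** 3 - n))
    chi2 = m * (n - 1) * W
    p = float(chi2_dist.sf(chi2, n - 1))
    return ConcordanceResult(
        rank_matrix=ranks, totals=totals, grand_mean=grand,
        S=S, W=W, m=m, n=n, p_value=p,
    )
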