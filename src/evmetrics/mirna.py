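"""Inter-facility small-RNA (miRNA) comparison.

The same EV RNA preparation sequenced at two facilities yields partially
overlapping miRNA catalogues and facility-specific count profiles.  This
module quantifies the agreement: set overlap with inclusion–exclusion,
sample × sample Pearson correlation of normalized counts (log2(x+1) by
default), a strict facility-clustering check (every within-facility
correlation must exceed every between-facility correlation), and top-k
expression tables per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SetOverlap",
    "set_overlap",
    "correlation_matrix",
    "facility_cluster_check",
    "top_expression_table",
]


@dataclass(frozen=True)
class SetOverlap:
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int


def set_overlap(ids_a: Iterable, ids_b: Iterable) -> SetOverlap:
    """Cardinalities |A|, |B|, |A∩B| and |A∪B| = |A| + |B| − |A∩B|."""
    a, b = set(ids_a), set(ids_b)
    return SetOverlap(len(a), len(b), len(a & b), len(a | b))


def correlation_matrix(counts: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Sample × sample Pearson r of (log-transformed) normalized counts.

    Rows are miRNAs, columns samples.  By default counts are transformed
    to log2(count + 1), the conventional scale for count-correlation
    heatmaps; pass ``log_transform=False`` for raw-scale r.  Zero-variance
    samples yield NaN in their row/column rather than an error.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be >= 0")
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    degenerate = sd == 0
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=counts.columns, columns=counts.columns)


def facility_cluster_check(
    corr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
) -> tuple[bool, float]:
    """Strict facility dominance: min within-facility r > max between-facility r.

    Returns (clusters, margin) with margin = min(within) − max(between);
    the boolean is the assertable content of "samples cluster by facility"
    without committing to a particular clustering algorithm.
    """
    labels = dict(labels)
    samples = list(corr.columns)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValueError(f"samples without facility label: {missing}")
    facilities = {labels[s] for s in samples}
    if len(facilities) < 2:
        raise ValueError("need two facilities for a clustering check")

    within, between = [], []
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            r = corr.loc[si, sj]
            (within if labels[si] == labels[sj] else between).append(float(r))
    if not within or not between:
        raise ValueError("need both within- and between-facility sample pairs")
    margin = float(np.nanmin(within) - np.nanmax(between))
    return margin > 0, margin


def top_expression_table(
    counts: pd.DataFrame,
    samples: Iterable[str],
    k: int,
) -> pd.DataFrame:
    """Top-k miRNAs by mean normalized count over a sample group.

    Ties break lexicographically by miRNA id.  If k exceeds the table, the
    full ranking is returned with a ``truncated = False`` marker column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = list(samples)
    if not cols:
        raise ValueError("empty sample group")
    missing = set(cols) - set(counts.columns)
    if missing:
        raise ValueError(f"unknown samples {sorted(missing)}")
    means = counts[cols].mean(axis=1)
    ranked = (
        pd.DataFrame({"mirna": means.index.astype(str), "mean_count": means.to_numpy()})
        .sort_values(["mean_count", "mirna"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    truncated = k < len(ranked)
    out = ranked.head(k).copy() if truncated else ranked.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["truncated"] = truncated
    return out[["rank", "mirna", "mean_count"]]
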