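"""DIA-proteomics intensity normalization and EV-marker annotation.

Raw DIA intensities x[p, s] (protein p, sample file s) are scaled by two
mean factors:

    K[p, s] = (x[p, s] / a̅[p]) · (C̅[s] / D̅)            (default, "product")
    K[p, s] =  x[p, s] · D̅ / (a̅[p] · C̅[s])              ("ratio")

where a̅[p] is the per-protein mean of the raw data, C̅[s] the per-sample-
file mean, and D̅ the grand mean over the whole matrix.  The flattened
published formula is typographically ambiguous between the two groupings;
the product form is the default and the ratio form — the one that exactly
removes a multiplicative sample-file effect — is available via ``mode``.
Final normalized data K̅ is the arithmetic mean of K over the n = 3
replicate files per sample group.

Marker annotation labels proteins against a small editable roster of
canonical EV markers (tetraspanins CD9/CD63/CD81, cytosolic ALIX, TSG101,
syntenin-1, flotillin-1, annexins A5/A7), known contaminants (serum
albumin, endoplasmin/HSP90B1) and proteins expected absent from clean EV
preparations (cytochrome C1, MHC-1/HLA-A, calnexin, apolipoprotein A-2).
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_eq1",
    "finalize_eq2",
    "annotate_markers",
    "load_default_roster",
    "CATEGORIES",
]

CATEGORIES = (
    "tetraspanin",
    "cytosolic_marker",
    "annexin",
    "contaminant",
    "expected_absent",
    "other",
)


def normalize_eq1(matrix: pd.DataFrame, mode: str = "product") -> pd.DataFrame:
    """Two-factor mean scaling of a raw protein × sample intensity matrix.

    Proteins whose raw mean a̅ is zero are dropped with a warning (DIA
    matrices routinely carry all-missing proteins); a zero grand mean or a
    zero sample-file mean is an error naming the offender.  The output is
    identically 1 on constant matrices and invariant to rescaling the
    whole matrix by a global factor.
    """
    if mode not in ("product", "ratio"):
        raise ValueError(f"mode must be 'product' or 'ratio', got {mode!r}")
    x = matrix.astype(float)
    if (x.to_numpy() < 0).any():
        raise ValueError("raw intensities must be >= 0")

    a_bar = x.mean(axis=1)  # per-protein mean of the raw data
    zero_rows = a_bar[a_bar == 0].index
    if len(zero_rows):
        warnings.warn(
            f"dropping {len(zero_rows)} protein(s) with zero mean intensity: "
            f"{list(zero_rows[:5])}{'...' if len(zero_rows) > 5 else ''}",
            stacklevel=2,
        )
        x = x.drop(index=zero_rows)
        a_bar = a_bar.drop(index=zero_rows)
    if x.empty:
        raise ValueError("no proteins left after dropping zero-mean rows")

    c_bar = x.mean(axis=0)  # per-sample-file mean
    d_bar = float(x.to_numpy().mean())  # grand mean over the whole matrix
    if d_bar == 0:
        raise ValueError("grand mean D̅ is zero")
    zero_cols = c_bar[c_bar == 0].index
    if len(zero_cols):
        raise ValueError(f"zero sample-file mean C̅ for sample(s) {list(zero_cols)}")

    rel = x.div(a_bar, axis=0)
    if mode == "product":
        return rel.mul(c_bar / d_bar, axis=1)
    return rel.div(c_bar / d_bar, axis=1)


def finalize_eq2(
    k: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Mean normalized datum K̅ per protein over each group's replicate files.

    ``groups`` maps a group name to its replicate column names (n = 3 in
    the study design; any n >= 1 is accepted, and a single replicate's K̅
    equals its K).  Without ``groups``, all columns form one group.
    """
    if groups is None:
        groups = {"all": list(k.columns)}
    out = {}
    for name, cols in groups.items():
        cols = list(cols)
        if not cols:
            raise ValueError(f"group {name!r} has no replicate columns")
        missing = set(cols) - set(k.columns)
        if missing:
            raise ValueError(f"group {name!r} names unknown columns {sorted(missing)}")
        out[name] = k[cols].mean(axis=1)
    return pd.DataFrame(out)


def load_default_roster() -> pd.DataFrame:
    """The shipped marker roster (protein_id, category), an editable TSV."""
    with resources.files("evmetrics").joinpath("data/marker_roster.tsv").open() as fh:
        roster = pd.read_csv(fh, sep="\t")
    return roster


def annotate_markers(
    protein_ids: Sequence[str],
    roster: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label proteins by marker category; unmatched proteins become "other".

    Returns the annotated table (protein_id, category, flag) and the
    per-category counts.  Contaminants are flagged "contaminant" and
    expected-absent proteins present in the input are flagged
    "expected_absent_violation" — the proteins a clean EV preparation
    should not contain.  Case-insensitive pure lookup: idempotent and
    permutation-invariant.
    """
    if roster is None:
        roster = load_default_roster()
    bad = set(roster["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"roster contains unknown categories {sorted(bad)}")
    lookup = {
        str(pid).casefold(): cat
        for pid, cat in zip(roster["protein_id"], roster["category"])
    }
    cats = [lookup.get(str(p).casefold(), "other") for p in protein_ids]
    flags = [
        "expected_absent_violation"
        if c == "expected_absent"
        else ("contaminant" if c == "contaminant" else "")
        for c in cats
    ]
    table = pd.DataFrame(
        {"protein_id": list(protein_ids), "category": cats, "flag": flags}
    )
    counts = table["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return table, counts
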