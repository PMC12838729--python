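"""Tabular readers/writers for every pipeline input and output.

All formats are plain text: comma-separated CSV with a header for particle
and event tables (UTF-8; unknown extra columns are preserved on read but
ignored by the analysis), tab-separated TSV for intensity and count
matrices.  Row-level validation failures are collected into a single
error report naming the offending lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import METHODS

log = logging.getLogger("evmetrics")

__all__ = [
    "ParticleTableError",
    "read_particle_table",
    "write_particle_table",
    "read_mrps_events",
    "read_cryoem_particles",
    "read_elugram",
    "read_intensity_matrix",
    "read_mirna_counts",
    "read_sample_metadata",
]

PARTICLE_COLUMNS = ("sample_id", "method", "replicate", "diameter_nm")


class ParticleTableError(ValueError):
    """Format- or row-level validation failure with line numbers."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ParticleTableError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )


def read_particle_table(path: str | Path) -> pd.DataFrame:
    """Read a per-particle diameter table (CSV).

    Required columns: sample_id, method (cryoem/mrps/pta/af4), replicate
    (integer >= 1), diameter_nm (positive real).  Every row is parsed or
    rejected with a line-numbered error report; extra columns pass
    through untouched.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PARTICLE_COLUMNS, path)

    errors: list[str] = []
    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2

    diam = pd.to_numeric(df["diameter_nm"], errors="coerce")
    for ln in lines[diam.isna().to_numpy()]:
        errors.append(f"line {ln}: diameter_nm is not a number")
    bad = (diam <= 0).fillna(False).to_numpy()
    for ln in lines[bad]:
        errors.append(f"line {ln}: diameter_nm must be positive")

    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad_rep = (rep.isna() | (rep < 1) | (rep != rep.round())).to_numpy()
    for ln in lines[bad_rep]:
        errors.append(f"line {ln}: replicate must be an integer >= 1")

    bad_method = ~df["method"].astype(str).isin(METHODS)
    for ln in lines[bad_method.to_numpy()]:
        errors.append(f"line {ln}: method must be one of {METHODS}")

    if errors:
        raise ParticleTableError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )

    df = df.copy()
    df["diameter_nm"] = diam.astype(float)
    df["replicate"] = rep.astype(np.int64)
    df["sample_id"] = df["sample_id"].astype(str)
    df["method"] = df["method"].astype(str)
    log.info("read %d particle records from %s", len(df), path)
    return df


def write_particle_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a particle table; read_particle_table round-trips it."""
    _require_columns(df, PARTICLE_COLUMNS, path)
    df.to_csv(path, index=False)


def read_mrps_events(path: str | Path) -> pd.DataFrame:
    """MRPS event CSV: transit_time_us, symmetry, diameter_nm, snr."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("transit_time_us", "symmetry", "diameter_nm", "snr"), path)
    for col in ("transit_time_us", "symmetry", "diameter_nm", "snr"):
        df[col] = pd.to_numeric(df[col])
    if not np.isfinite(df[["transit_time_us", "symmetry", "diameter_nm", "snr"]].to_numpy()).all():
        raise ParticleTableError(f"{path}: MRPS event fields must be finite")
    if (df["diameter_nm"] <= 0).any():
        raise ParticleTableError(f"{path}: event diameters must be positive")
    return df


def read_cryoem_particles(path: str | Path) -> pd.DataFrame:
    """Cryo-EM particle CSV: area_nm2, morphology, overlaps_support, overlaps_other."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("area_nm2", "morphology", "overlaps_support", "overlaps_other"), path)
    df["area_nm2"] = pd.to_numeric(df["area_nm2"])
    if (df["area_nm2"] <= 0).any():
        raise ParticleTableError(f"{path}: areas must be positive")
    for col in ("overlaps_support", "overlaps_other"):
        df[col] = df[col].astype(bool)
    return df


def read_elugram(path: str | Path) -> pd.DataFrame:
    """Elugram CSV: slice_id, angle_deg, intensity (tidy, one angle per row)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("slice_id", "angle_deg", "intensity"), path)
    df["angle_deg"] = pd.to_numeric(df["angle_deg"])
    df["intensity"] = pd.to_numeric(df["intensity"])
    return df


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Protein × sample raw DIA intensity TSV (first column = protein id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mirna_counts(path: str | Path) -> pd.DataFrame:
    """miRNA × sample normalized count TSV (first column = miRNA id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, facility, content."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "facility"), path)
    return df
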