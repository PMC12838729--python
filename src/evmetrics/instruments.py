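"""Method-specific selection and conversion rules.

Each sizing method applies its own gatekeeping before diameters enter the
shared PSD analysis: MRPS events pass a four-rule peak-filter box, Cryo-EM
particles are manually outlined areas converted to equivalent-sphere
diameters and screened for morphology/overlap, and every method has a
lower measurement cutoff below which it reports nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import METHODS, RunConfig

log = logging.getLogger("evmetrics")

__all__ = [
    "MRPS_FILTERS",
    "filter_mrps_events",
    "cryoem_area_to_diameter",
    "cryoem_select",
    "apply_measurement_cutoff",
    "CryoEMSelection",
]

# MRPS peak-filter box (all comparisons strict, as printed):
# transit time < 100 us, 0.2 < symmetry < 4.0, diameter > 65 nm, S/N > 10.
MRPS_FILTERS = {
    "transit": lambda ev: ev["transit_time_us"] < 100.0,
    "symmetry": lambda ev: (ev["symmetry"] > 0.2) & (ev["symmetry"] < 4.0),
    "diameter": lambda ev: ev["diameter_nm"] > 65.0,
    "snr": lambda ev: ev["snr"] > 10.0,
}


def filter_mrps_events(events: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the MRPS peak filters; return passing events and a rejection tally.

    An event passes iff it satisfies all four rules; the tally counts, per
    rule, how many events violated it (an event violating several rules is
    counted under each).  Idempotent: the passing set is the intersection
    of the four single-rule filters.
    """
    required = {"transit_time_us", "symmetry", "diameter_nm", "snr"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"MRPS event table missing columns: {sorted(missing)}")
    masks = {name: rule(events) for name, rule in MRPS_FILTERS.items()}
    tally = {name: int((~m).sum()) for name, m in masks.items()}
    keep = np.logical_and.reduce(list(masks.values()))
    return events[keep].reset_index(drop=True), tally


def cryoem_area_to_diameter(area_nm2):
    """Equivalent-sphere diameter d = 2 sqrt(A/pi) from an outlined area."""
    a = np.asarray(area_nm2, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be positive")
    d = 2.0 * np.sqrt(a / math.pi)
    return float(d) if d.ndim == 0 else d


@dataclass
class CryoEMSelection:
    records: pd.DataFrame
    rejected: dict[str, int]
    stopped_early: bool


def cryoem_select(
    particles: pd.DataFrame,
    target_n: int = 500,
    min_diameter_nm: float = 30.0,
    sample_id: str = "sample",
    replicate: int = 1,
) -> CryoEMSelection:
    """Select single, non-overlapping vesicles above 30 nm, stopping at ~500.

    Particles are examined in input order (the sequential count across
    images); retained ones become ParticleRecords and counting stops once
    ``target_n`` are accepted.  ``rejected`` tallies each violated
    criterion among the examined particles.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    required = {"area_nm2", "morphology", "overlaps_support", "overlaps_other"}
    missing = required - set(particles.columns)
    if missing:
        raise ValueError(f"Cryo-EM particle table missing columns: {sorted(missing)}")

    rejected = {"morphology": 0, "overlap_support": 0, "overlap_other": 0, "diameter": 0}
    diameters: list[float] = []
    stopped = False
    for row in particles.itertuples(index=False):
        ok = True
        if row.morphology != "single":
            rejected["morphology"] += 1
            ok = False
        if bool(row.overlaps_support):
            rejected["overlap_support"] += 1
            ok = False
        if bool(row.overlaps_other):
            rejected["overlap_other"] += 1
            ok = False
        d = cryoem_area_to_diameter(row.area_nm2)
        if d <= min_diameter_nm:
            rejected["diameter"] += 1
            ok = False
        if ok:
            diameters.append(d)
            if len(diameters) >= target_n:
                stopped = True
                break
    records = pd.DataFrame(
        {
            "sample_id": sample_id,
            "method": "cryoem",
            "replicate": replicate,
            "diameter_nm": diameters,
        }
    )
    return CryoEMSelection(records, rejected, stopped)


# PTA's cutoff is the smallest diameter actually detected (an observed
# value, so inclusive); AF4's is a set lower bound treated the same way.
# MRPS prints a strict "> 65 nm" filter and Cryo-EM selection a strict
# "greater than 30 nm", so those exclude the boundary itself.
_INCLUSIVE_CUTOFF = {"pta", "af4"}


def apply_measurement_cutoff(records: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Drop particle records below each method's lower measurement cutoff."""
    if config is None:
        config = RunConfig()
    if records.empty:
        return records.copy()
    records = records.reset_index(drop=True)
    unknown = set(records["method"].unique()) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods in records: {sorted(unknown)}")
    keep = np.zeros(len(records), dtype=bool)
    for method, grp in records.groupby("method"):
        cut = config.cutoff_for(str(method))
        d = grp["diameter_nm"].to_numpy()
        ok = d >= cut if method in _INCLUSIVE_CUTOFF else d > cut
        keep[grp.index.to_numpy()] = ok
        removed = int((~ok).sum())
        if removed:
            log.info("cutoff %s nm removed %d/%d %s records", cut, removed, len(grp), method)
    return records[keep].reset_index(drop=True)
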