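"""Particle number concentration: dilution correction, triplicate
aggregation, and particles per microgram of protein.

PNCs are reported as mean ± one standard deviation over n = 3 replicate
measurements, each corrected for the dilution applied before measurement,
together with the method's lower measurement cutoff (the concentration a
method reports depends directly on how small a particle it can see).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PNCResult",
    "dilution_corrected_pnc",
    "aggregate_pnc",
    "format_pnc",
    "particles_per_microgram",
    "round_sig",
]


@dataclass
class PNCResult:
    method: str
    mean: float          # particles/mL
    sd: float | None     # None for a single replicate
    n: int
    cutoff_nm: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean concentration must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")

    def formatted(self) -> str:
        return format_pnc(self.mean, self.sd)


def dilution_corrected_pnc(measured: float, dilution_factor: float) -> float:
    """Stock concentration = measured concentration x dilution factor."""
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    return measured * dilution_factor


def aggregate_pnc(
    replicate_pncs: Sequence[float],
    method: str,
    cutoff_nm: float,
    dilution_factor: float = 1.0,
) -> PNCResult:
    """Mean ± sample SD over replicate concentrations (already corrected).

    A single replicate yields a mean with the SD flagged absent (None)
    rather than zero.
    """
    vals = np.asarray(list(replicate_pncs), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate PNC")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return PNCResult(method, float(vals.mean()), sd, int(vals.size), cutoff_nm, dilution_factor)


def format_pnc(mean: float, sd: float | None) -> str:
    """Render "(9 ± 1) × 10^9"-style mean ± SD with a shared exponent.

    The exponent is taken from the mean; the SD mantissa is rounded to one
    significant figure and the mean mantissa to the same decimal place.
    """
    if mean == 0:
        return "0" if sd is None else f"0 ± {sd:g}"
    exp = int(math.floor(math.log10(abs(mean))))
    m = mean / 10**exp
    if sd is None:
        return f"{m:.1f} × 10^{exp}"
    s = sd / 10**exp
    if s == 0:
        decimals = 1
    else:
        # one significant figure on the SD mantissa fixes the decimal place
        decimals = max(0, -int(math.floor(math.log10(s))))
    return f"({m:.{decimals}f} ± {s:.{decimals}f}) × 10^{exp}"


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def particles_per_microgram(pnc_per_ml: float, protein_conc_ug_per_ul: float) -> float:
    """Particles per µg of total protein, to two significant figures.

    pnc [1/mL] / (protein [µg/µL] × 1000 µL/mL).  E.g. an MRPS PNC of
    7.1e11/mL at 0.34 µg/µL gives 2.1e9 particles/µg.
    """
    if protein_conc_ug_per_ul <= 0:
        raise ValueError("protein concentration must be positive")
    if pnc_per_ml < 0:
        raise ValueError("PNC must be >= 0")
    return round_sig(pnc_per_ml / (protein_conc_ug_per_ul * 1000.0), 2)
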