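"""Particle size distribution statistics with multinomial uncertainty.

Diameters from every sizing method are grouped into shared 5-nm bins on
[0, 400) nm and the binned counts are treated as multinomial data: with
count x_i in bin i out of N retained measurements, the bin probability is
p_i = x_i / N with theoretical standard deviation sqrt(p_i (1 - p_i) / N).
Dividing by p_i gives the *single-measurement relative uncertainty* of a
replicate.  Triplicate measurements are combined into a mean PSD by
averaging the three probability vectors bin-wise, and the uncertainty of
that mean is estimated by a parametric bootstrap: each draw resamples a
full multinomial count vector per replicate at the replicate's own (N_r,
p_r), converts to probabilities, and averages across replicates; the SD of
the simulated mean probabilities over 100,000 draws, divided by the actual
mean p_i, is the *replicate-to-replicate relative uncertainty*.  The draw
procedure resamples the fixed per-replicate probabilities exactly as
stated — between-replicate disagreement enters only through differing p_r,
no extra replicate-resampling layer is added.

:class:`PSDModel` wraps these pieces statsmodels-style: build it from
per-replicate diameters (or a particle table), call :meth:`PSDModel.fit`,
and read estimates, uncertainties and a ``summary()`` off the returned
:class:`PSDResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "BinnedPSD",
    "MeanPSD",
    "PSDUncertainty",
    "bin_diameters",
    "single_measurement_relative_uncertainty",
    "mean_psd",
    "bootstrap_replicate_uncertainty",
    "psd_summary",
    "PSDModel",
    "PSDResults",
]


@dataclass
class BinnedPSD:
    """Counts of one replicate over the half-open bins [lo, lo + width).

    ``n_excluded`` records diameters falling outside [range_min, range_max)
    (400.0 itself is excluded by the half-open convention).  A replicate
    with N = 0 is valid but carries undefined probabilities.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n(self) -> int:
        """Total retained measurements N."""
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """p_i = x_i / N; all-NaN when the replicate is empty (flagged by N=0)."""
        if self.n == 0:
            return np.full(len(self.counts), np.nan)
        return self.counts / self.n

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class MeanPSD:
    """Bin-wise arithmetic mean of replicate probability vectors."""

    bin_edges: np.ndarray
    mean_p: np.ndarray
    n_replicates: int


@dataclass
class PSDUncertainty:
    """Bootstrap SD of the mean bin probability and its relative form.

    ``replicate_rel`` is the SD divided by the *actual* mean p_i (missing —
    NaN — exactly where the mean p_i is zero), keeping the estimator
    anchored to the data rather than to the simulation.
    """

    sd: np.ndarray
    replicate_rel: np.ndarray
    draws: int
    seed: int


def bin_diameters(diameters, config: RunConfig | None = None) -> BinnedPSD:
    """Histogram diameters into the shared bin grid.

    Diameters outside [range_min, range_max) are excluded and counted in
    ``n_excluded``; an empty input yields a valid N = 0 distribution.
    """
    if config is None:
        config = RunConfig()
    d = np.asarray(diameters, dtype=float)
    if d.ndim != 1:
        d = d.ravel()
    inside = (d >= config.range_min) & (d < config.range_max)
    kept = d[inside]
    idx = np.floor((kept - config.range_min) / config.bin_width).astype(np.int64)
    counts = np.bincount(idx, minlength=config.n_bins)
    return BinnedPSD(config.bin_edges, counts, n_excluded=int((~inside).sum()))


def single_measurement_relative_uncertainty(psd: BinnedPSD) -> np.ndarray:
    """Per-bin sqrt(p_i (1 - p_i) / N) / p_i; NaN where p_i = 0.

    Scales as 1/sqrt(N) for fixed p_i, so methods that measure many
    particles (AF4, ~1e9-1e10) report near-zero values while count-limited
    methods (~1e3 for MRPS/PTA) do not.
    """
    if psd.n == 0:
        raise ValueError("single-measurement uncertainty undefined for N = 0")
    p = psd.probabilities
    out = np.full_like(p, np.nan)
    occ = p > 0
    out[occ] = np.sqrt(p[occ] * (1.0 - p[occ]) / psd.n) / p[occ]
    return out


def _check_common_grid(replicates: Sequence[BinnedPSD]) -> np.ndarray:
    if not replicates:
        raise ValueError("need at least one replicate")
    edges = replicates[0].bin_edges
    for r in replicates[1:]:
        if len(r.bin_edges) != len(edges) or not np.allclose(r.bin_edges, edges):
            raise ValueError("replicates must share the same bin grid")
    return edges


def mean_psd(replicates: Sequence[BinnedPSD]) -> MeanPSD:
    """Unweighted bin-wise mean of replicate probabilities.

    A single replicate is allowed (the Cryo-EM case: one analysis of ~500
    particles); the mean then equals that replicate.
    """
    edges = _check_common_grid(replicates)
    for r in replicates:
        if r.n == 0:
            raise ValueError("every replicate must have N > 0 to form a mean PSD")
    p = np.vstack([r.probabilities for r in replicates])
    return MeanPSD(edges, p.mean(axis=0), len(replicates))


def bootstrap_replicate_uncertainty(
    replicates: Sequence[BinnedPSD],
    draws: int = 100_000,
    seed: int = 0,
) -> PSDUncertainty:
    """Parametric-bootstrap SD of the mean bin probability.

    Each draw samples a count vector from Multinomial(N_r, p_r) for every
    replicate r, converts to probabilities and averages across replicates;
    the per-bin SD over all draws is reported, relative to the actual mean
    p_i.  Deterministic under a fixed seed.  With equal replicate
    probabilities the SD converges to the closed form
    (1/R) sqrt(Σ_r p(1-p)/N_r).
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    _check_common_grid(replicates)
    for r in replicates:
        if r.n == 0:
            raise ValueError("every replicate must have N > 0 to bootstrap")

    rng = np.random.default_rng(seed)
    n_bins = len(replicates[0].counts)
    acc = np.zeros((draws, n_bins))
    for r in replicates:
        p = r.probabilities
        p = p / p.sum()  # guard the multinomial sampler against float round-off
        acc += rng.multinomial(r.n, p, size=draws) / r.n
    sim_mean = acc / len(replicates)
    sd = sim_mean.std(axis=0, ddof=1) if draws > 1 else np.zeros(n_bins)

    actual = np.vstack([r.probabilities for r in replicates]).mean(axis=0)
    rel = np.full(n_bins, np.nan)
    occ = actual > 0
    rel[occ] = sd[occ] / actual[occ]
    return PSDUncertainty(sd=sd, replicate_rel=rel, draws=draws, seed=seed)


def psd_summary(diameters, config: RunConfig | None = None) -> tuple[float, float, float]:
    """(mean, sample SD, mode-bin midpoint) of the retained raw diameters.

    Statistics are computed on the raw (not binned) diameters inside the
    analysis range; the mode is the midpoint of the most populated 5-nm
    bin.  SD uses the n-1 convention; it is 0 for a single diameter.
    """
    if config is None:
        config = RunConfig()
    d = np.asarray(diameters, dtype=float)
    d = d[(d >= config.range_min) & (d < config.range_max)]
    if d.size == 0:
        raise ValueError("no diameters inside the analysis range")
    psd = bin_diameters(d, config)
    mode_mid = float(psd.bin_midpoints[int(np.argmax(psd.counts))])
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd, mode_mid


class PSDModel:
    """Multinomial PSD model for one sample/method's replicate diameters.

    Parameters
    ----------
    replicates : sequence of 1-d diameter arrays
        One array of raw diameters (nm) per replicate measurement.
    config : RunConfig, optional
        Bin grid and bootstrap size; defaults to 5-nm bins on [0, 400) nm
        with 100,000 bootstrap draws.
    label : str
        Free-text label (e.g. "LNCaP / mrps") carried into the summary.
    """

    def __init__(
        self,
        replicates: Sequence,
        config: RunConfig | None = None,
        label: str = "",
    ) -> None:
        self.config = config if config is not None else RunConfig()
        self.label = label
        self.raw_replicates = [np.asarray(r, dtype=float) for r in replicates]
        if not self.raw_replicates:
            raise ValueError("need at least one replicate")
        self.binned = [bin_diameters(r, self.config) for r in self.raw_replicates]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: RunConfig | None = None,
        sample_id: str | None = None,
        method: str | None = None,
    ) -> "PSDModel":
        """Build from a particle table (columns sample_id, method, replicate,
        diameter_nm), optionally filtered to one sample and method."""
        sub = df
        if sample_id is not None:
            sub = sub[sub["sample_id"] == sample_id]
        if method is not None:
            sub = sub[sub["method"] == method]
        if sub.empty:
            raise ValueError("no particle records after filtering")
        reps = [
            grp["diameter_nm"].to_numpy()
            for _, grp in sub.groupby("replicate", sort=True)
        ]
        label = " / ".join(str(x) for x in (sample_id, method) if x is not None)
        return cls(reps, config=config, label=label)

    def fit(self, draws: int | None = None, seed: int | None = None) -> "PSDResults":
        """Estimate the mean PSD and both uncertainty curves."""
        cfg = self.config
        draws = cfg.bootstrap_draws if draws is None else draws
        seed = cfg.seed if seed is None else seed
        mean = mean_psd(self.binned)
        single = np.vstack(
            [single_measurement_relative_uncertainty(b) for b in self.binned]
        )
        boot = bootstrap_replicate_uncertainty(self.binned, draws=draws, seed=seed)
        summaries = [psd_summary(r, cfg) for r in self.raw_replicates]
        return PSDResults(self, mean, single, boot, summaries)


class PSDResults:
    """Fitted PSD estimates: mean probabilities plus both uncertainties."""

    def __init__(self, model, mean, single_rel, bootstrap, replicate_summaries):
        self.model = model
        self.mean_psd = mean
        self.single_rel = single_rel  # (R, n_bins), NaN in empty bins
        self.bootstrap = bootstrap
        self.replicate_summaries = replicate_summaries  # [(mean, sd, mode), ...]

    @property
    def mean_p(self) -> np.ndarray:
        return self.mean_psd.mean_p

    @property
    def replicate_rel(self) -> np.ndarray:
        return self.bootstrap.replicate_rel

    def frame(self) -> pd.DataFrame:
        """Per-bin tidy table (plot-ready): mean p, per-replicate single
        relative uncertainty, bootstrap replicate-to-replicate uncertainty."""
        mids = 0.5 * (self.mean_psd.bin_edges[:-1] + self.mean_psd.bin_edges[1:])
        data = {
            "bin_lo": self.mean_psd.bin_edges[:-1],
            "bin_hi": self.mean_psd.bin_edges[1:],
            "bin_mid": mids,
            "mean_p": self.mean_p,
        }
        for i in range(self.single_rel.shape[0]):
            data[f"single_rel_rep{i + 1}"] = self.single_rel[i]
        data["replicate_rel"] = self.replicate_rel
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [
            f"Particle size distribution fit{(': ' + self.model.label) if self.model.label else ''}",
            "=" * 52,
            f"replicates (R)          {self.mean_psd.n_replicates}",
            f"bin width               {self.model.config.bin_width} nm on "
            f"[{self.model.config.range_min:g}, {self.model.config.range_max:g}) nm",
            f"bootstrap draws         {self.bootstrap.draws} (seed {self.bootstrap.seed})",
        ]
        for i, (b, (m, s, mode)) in enumerate(
            zip(self.model.binned, self.replicate_summaries), start=1
        ):
            lines.append(
                f"replicate {i}: N = {b.n:6d}  mean = {m:7.1f} nm  "
                f"sd = {s:6.1f} nm  mode bin = {mode:6.1f} nm  "
                f"(excluded {b.n_excluded})"
            )
        occ = self.mean_p > 0
        if occ.any():
            rel = self.replicate_rel[occ]
            lines.append(
                f"occupied bins           {int(occ.sum())}; replicate-to-replicate "
                f"rel. uncertainty median {np.nanmedian(rel) * 100:.1f}%"
            )
        return "\n".join(lines)
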