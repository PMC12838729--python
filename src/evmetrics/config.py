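"""Run configuration: bin grid, method cutoffs, bootstrap size, optics.

A :class:`RunConfig` collects every knob shared across the pipeline stages:
the 5-nm histogram grid on [0, 400) nm used to compare particle size
distributions across methods, the per-method lower measurement cutoffs,
the number of multinomial bootstrap draws, and the coated-sphere optical
constants used by the AF4/MALS stage.  Configs are plain YAML files; any
key left out takes its default, and unknown keys are rejected loudly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mals import CoatedSphereModel

log = logging.getLogger("evmetrics")

#: The four sizing modalities compared by the pipeline.
METHODS = ("cryoem", "mrps", "pta", "af4")

#: Lower measurement cutoff per method, nm.  Cryo-EM selection excludes
#: sub-30 nm objects (indistinguishable from grid contamination), PTA's 25 nm
#: is the smallest diameter detected and tracked, AF4 was set to 30 nm, and
#: the MRPS cartridge reports nothing below 65 nm.
DEFAULT_CUTOFFS = {"cryoem": 30.0, "pta": 25.0, "af4": 30.0, "mrps": 65.0}


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configuration."""


@dataclass
class RunConfig:
    bin_width: float = 5.0
    range_min: float = 0.0
    range_max: float = 400.0
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    bootstrap_draws: int = 100_000
    seed: int = 0
    mals: CoatedSphereModel = field(default_factory=CoatedSphereModel)
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        span = self.range_max - self.range_min
        if span <= 0:
            raise ConfigError("range_max must exceed range_min")
        n = span / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"bin_width {self.bin_width} does not divide the range "
                f"[{self.range_min}, {self.range_max})"
            )
        if self.bootstrap_draws < 1:
            raise ConfigError("bootstrap_draws must be >= 1")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError(f"seed must be an integer, got {self.seed!r}")
        unknown = set(self.cutoffs) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods in cutoffs: {sorted(unknown)}")
        for m, c in self.cutoffs.items():
            if c < self.range_min:
                raise ConfigError(f"cutoff for {m} ({c}) below range_min")
        self.output_dir = Path(self.output_dir)

    @property
    def n_bins(self) -> int:
        return int(round((self.range_max - self.range_min) / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        """Edges of the half-open bins [lo, lo + bin_width)."""
        return self.range_min + self.bin_width * np.arange(self.n_bins + 1)

    def cutoff_for(self, method: str) -> float:
        if method not in METHODS:
            raise ConfigError(f"unknown method {method!r}; expected one of {METHODS}")
        return float(self.cutoffs.get(method, DEFAULT_CUTOFFS[method]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


_TOP_KEYS = {
    "bin_width", "range_min", "range_max", "cutoffs", "bootstrap_draws",
    "seed", "mals", "output_dir",
}
_MALS_KEYS = {"n_core", "shell_thickness", "n_shell", "n_medium", "wavelength_vacuum"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent keys.

    ``None`` (or an empty file) yields the all-defaults config.  Unknown
    keys raise :class:`ConfigError` listing the valid key set.  The fully
    resolved configuration is echoed to the log at INFO level.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )

    kwargs: dict = {}
    for key in _TOP_KEYS - {"cutoffs", "mals"}:
        if key in raw:
            kwargs[key] = raw[key]
    if "cutoffs" in raw:
        cutoffs = dict(DEFAULT_CUTOFFS)
        if not isinstance(raw["cutoffs"], dict):
            raise ConfigError("cutoffs must be a mapping method -> nm")
        cutoffs.update({str(k): float(v) for k, v in raw["cutoffs"].items()})
        kwargs["cutoffs"] = cutoffs
    if "mals" in raw:
        mraw = raw["mals"]
        if not isinstance(mraw, dict):
            raise ConfigError("mals must be a mapping of optical parameters")
        unknown = set(mraw) - _MALS_KEYS
        if unknown:
            raise ConfigError(
                f"unknown mals keys {sorted(unknown)}; valid keys: {sorted(_MALS_KEYS)}"
            )
        kwargs["mals"] = CoatedSphereModel(**{k: float(v) for k, v in mraw.items()})

    cfg = RunConfig(**kwargs)
    log.info("resolved run configuration: %s", cfg.to_dict())
    return cfg
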