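"""Analysis configuration: every tunable the pipeline exposes, with the
study defaults, plus YAML round-trip and a content hash for run logging."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]

#: band edges in Hz
BANDS = {"delta": (1.0, 3.5), "theta": (4.0, 7.0)}
#: post-stimulus PLV averaging window in ms, per band
PLV_WINDOWS_MS = {"delta": (0.0, 600.0), "theta": (0.0, 300.0)}


@dataclass
class CsdConfig:
    spline_order: int = 4       # m
    legendre_degree: int = 10   # truncation of the Legendre series
    lam: float = 1e-5           # ridge added to the spline system diagonal


@dataclass
class NetworkConfig:
    density: float = 0.10       # retained edge fraction after thresholding
    n_random: int = 100         # degree-matched nulls per graph
    node_set: str = "full"      # "full" (all montage channels) or "pairset"

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")


@dataclass
class ResamplingConfig:
    n_boot: int = 5000
    n_perm: int = 5000
    bolasso_B: int = 100
    bolasso_threshold: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_boot", "n_perm", "bolasso_B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class AnalysisConfig:
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in BANDS.items()})
    n_freq_bins: int = 30
    wavelet_cycles: float = 3.0
    plv_windows_ms: dict = field(
        default_factory=lambda: {k: list(v) for k, v in PLV_WINDOWS_MS.items()}
    )
    csd: CsdConfig = field(default_factory=CsdConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    cv_folds: int = 10
    lasso_n_lambda: int = 100
    lasso_lambda_min_ratio: float = 1e-2
    rng_seed: int = 0
    fs: float = 256.0
    amplitude_threshold: float = 100.0  # artifact rejection, same units as the data
    synth: dict = field(default_factory=dict)  # forwarded to the cohort generator

    def __post_init__(self) -> None:
        for band, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band edges for {band} must be strictly increasing")
        if self.n_freq_bins < 1 or self.cv_folds < 2:
            raise ValueError("n_freq_bins must be >= 1 and cv_folds >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable content hash of the full configuration (logged with every run)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    for key, cls in (("csd", CsdConfig), ("network", NetworkConfig), ("resampling", ResamplingConfig)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    return AnalysisConfig(**d)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a YAML config; ``None`` or a missing 'analysis' block means defaults."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(raw)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
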