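"""Analysis configuration: defaults, TOML loading, validation.

The defaults follow common practice for diffusing-molecule PIE measurements:
bursts are called with an inter-photon threshold dT = 100 us and kept if they
contain between 30 and 1000 photons; aggregates are removed by dropping 2 s
bins whose photon count exceeds the trace mean by more than 6 SD; the direct
acceptor excitation factor alpha defaults to 0.042; stoichiometric FRET pairs
are selected with S in [0.3, 0.7]; burst-asymmetry confidence is cut at 1.5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .photons import ChannelMap

__all__ = ["AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or inconsistent configuration values."""


@dataclass
class AnalysisConfig:
    # burst search
    burst_dt_us: float = 100.0        # max inter-photon gap inside a burst
    min_photons: int = 30
    max_photons: int = 1000
    # aggregate removal
    aggregate_bin_s: float = 2.0
    aggregate_k_sd: float = 6.0
    # corrections
    alpha: float = 0.042              # direct acceptor excitation
    leakage: float = 0.0              # donor emission into acceptor channel
    gamma: float = 1.0                # detection-efficiency ratio (Dex)
    gamma_pie: float = 1.0            # relative excitation/detection, PIE
    background_dd_hz: float = 0.0     # bg rate in (Dex gate, donor channels)
    background_da_hz: float = 0.0     # bg rate in (Dex gate, acceptor channels)
    background_aa_hz: float = 0.0     # bg rate in (Aex gate, acceptor channels)
    stoich_delta_on_naa: bool = True  # delta term in S denominator multiplies n_AA
    # selection
    s_window: tuple[float, float] = (0.3, 0.7)
    asymmetry_threshold: float = 1.5
    # population fitting / histograms
    hist_bin_width: float = 0.025
    min_bursts_for_fit: int = 100
    # lifetime analysis
    irf_offset_ns: float = 0.0
    donor_only_s_min: float = 0.8
    min_donor_only_bursts: int = 50
    min_donor_photons_lifetime: int = 10
    forster_radius_nm: float = 6.0
    # anisotropy
    g_factor: float = 1.0
    # FCS
    fcs_aspect_ratio: float = 3.0
    # randomness (mixture-fit initialisation)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.s_window = tuple(float(x) for x in self.s_window)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.min_photons >= self.max_photons:
            raise ConfigError(
                f"min_photons ({self.min_photons}) must be < max_photons "
                f"({self.max_photons})"
            )
        for name in ("burst_dt_us", "aggregate_bin_s", "aggregate_k_sd",
                     "asymmetry_threshold", "hist_bin_width", "gamma",
                     "gamma_pie", "g_factor", "fcs_aspect_ratio",
                     "forster_radius_nm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.alpha < 1):
            raise ConfigError("alpha must lie in [0, 1)")
        if self.leakage < 0:
            raise ConfigError("leakage must be >= 0")
        for name in ("background_dd_hz", "background_da_hz", "background_aa_hz"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.s_window
        if not lo < hi:
            raise ConfigError("s_window must be (low, high) with low < high")
        if self.burst_dt_us > 100.0:
            warnings.warn(
                f"burst_dt_us={self.burst_dt_us} exceeds the usual 100 us; "
                "bursts from separate molecules may merge",
                stacklevel=3,
            )

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["s_window"] = list(self.s_window)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def corrections(self) -> "CorrectionSet":
        from .bursts import CorrectionSet

        return CorrectionSet(
            background_dd_hz=self.background_dd_hz,
            background_da_hz=self.background_da_hz,
            background_aa_hz=self.background_aa_hz,
            leakage=self.leakage,
            alpha=self.alpha,
            gamma=self.gamma,
            gamma_pie=self.gamma_pie,
        )


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML file.

    Unspecified keys take the documented defaults; unknown keys are rejected
    so typos do not silently fall back to defaults.  ``path=None`` returns
    the default configuration.
    """
    if path is None:
        return AnalysisConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return AnalysisConfig.from_dict(data)
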