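"""Run configuration with validated defaults.

All tunable numbers of the pipeline live here so that the simulator, the
feature extractors and the statistics stage share one source of truth
(in particular the optics tables, which must be identical on the forward
and inverse paths).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: EEG frequency bands in Hz: delta, theta, alpha, beta.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

EEG_CHANNELS = ("Fp1", "Fpz", "Fp2")

#: Long source-detector channels, grouped into prefrontal location pairs.
LONG_CHANNELS = ("S1D2", "S2D1", "S2D3", "S3D2", "S3D4", "S4D3")
SHORT_CHANNELS = ("S1D1", "S2D2", "S3D3", "S4D4")
LOCATION_PAIRS: dict[str, tuple[str, str]] = {
    "Fp1": ("S1D2", "S2D1"),
    "Fpz": ("S2D3", "S3D2"),
    "Fp2": ("S3D4", "S4D3"),
}
#: Short channels flanking each long channel (near-source, near-detector).
LONG_TO_SHORTS: dict[str, tuple[str, str]] = {
    "S1D2": ("S1D1", "S2D2"),
    "S2D1": ("S2D2", "S1D1"),
    "S2D3": ("S2D2", "S3D3"),
    "S3D2": ("S3D3", "S2D2"),
    "S3D4": ("S3D3", "S4D4"),
    "S4D3": ("S4D4", "S3D3"),
}

WAVELENGTHS = (735, 805, 850)

STAGES = ("NonF", "ModF", "SevF")
STAGE_INDEX = {"NonF": 1, "ModF": 2, "SevF": 3}


class OpticsConfig(BaseModel):
    """Optical constants for the modified Beer-Lambert inversion.

    Extinction coefficients are tabulated compendium values for
    oxy-/deoxy-hemoglobin at the three LED wavelengths, in 1/(mM*cm).
    """

    model_config = ConfigDict(extra="forbid")

    wavelengths_nm: tuple[int, int, int] = WAVELENGTHS
    # rows: wavelengths; columns irrelevant here -- stored per chromophore
    extinction_hbo: tuple[float, float, float] = (0.450, 0.810, 1.058)
    extinction_hbr: tuple[float, float, float] = (1.123, 0.770, 0.691)
    dpf: float = Field(6.0, gt=0, description="differential pathlength factor")
    long_distance_cm: float = Field(3.0, gt=0)
    short_distance_cm: float = Field(0.84, gt=0)


class EEGConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rate_hz: float = 250.0
    notch_freqs_hz: tuple[float, ...] = (12.5, 25.0, 37.5, 50.0)
    notch_q: float = 30.0
    bandpass_hz: tuple[float, float] = (0.5, 30.0)
    filter_order: int = 4
    welch_segment_s: float = 4.0
    welch_overlap: float = 0.5
    # automated bad-channel proxy for the manual inspection step
    bad_ptp_uv: float = 500.0
    bad_flat_s: float = 5.0
    bad_window_fraction: float = 0.30
    ocular_wavelet: str = "sym4"
    ocular_swt_level: int = 6
    ocular_mad_k: float = 3.0
    adaptive_order: int = 3
    adaptive_mu: float = 0.5


class FNIRSConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rate_hz: float = 12.5
    baseline_s: float = 2.0
    lowpass_hz: float = 0.1
    filter_order: int = 4
    motion_sd_window_s: float = 1.0
    motion_sd_k: float = 3.0
    motion_pad_s: float = 0.5
    wavelet: str = "db4"
    wavelet_level: int = 4
    wavelet_mad_k: float = 4.0
    od_excursion_limit: float = 1.0
    flatline_s: float = 0.5
    cardiac_band_hz: tuple[float, float] = (0.5, 2.5)
    cardiac_snr_db: float = 3.0
    window_missing_fraction: float = 0.5


class PRVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pulse_band_hz: tuple[float, float] = (0.5, 2.5)
    filter_order: int = 4
    ibi_bounds_s: tuple[float, float] = (0.33, 1.5)
    ibi_mad_k: float = 3.0
    min_ibi_count: int = 10


class WindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_s: float = 30.0
    rest_s: float = 60.0
    drive_s: float = 4800.0


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(0.05, gt=0, lt=1)
    normalization_percentiles: tuple[float, float] = (5.0, 95.0)


class RunConfig(BaseModel):
    """Top-level configuration; every field has a validated default."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    eeg: EEGConfig = Field(default_factory=EEGConfig)
    fnirs: FNIRSConfig = Field(default_factory=FNIRSConfig)
    prv: PRVConfig = Field(default_factory=PRVConfig)
    windows: WindowConfig = Field(default_factory=WindowConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @model_validator(mode="after")
    def _ranges(self) -> "RunConfig":
        lo, hi = self.eeg.bandpass_hz
        if not 0 < lo < hi:
            raise ValueError("eeg.bandpass_hz must satisfy 0 < low < high")
        lo, hi = self.prv.ibi_bounds_s
        if not 0 < lo < hi:
            raise ValueError("prv.ibi_bounds_s must satisfy 0 < low < high")
        return self


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config file, filling every unset key with defaults.

    An empty or missing file yields the full default configuration; unknown
    keys and out-of-range values raise ``ValueError`` naming the key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # surface the offending key in a ValueError
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc
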