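"""Core in-memory containers for multimodal recordings and timelines."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EEG_CHANNELS, LONG_CHANNELS, SHORT_CHANNELS, WAVELENGTHS

ALL_CHANNELS = LONG_CHANNELS + SHORT_CHANNELS


@dataclass
class BehaviorStreams:
    """Derived behavioral streams ingested alongside the physiology.

    eye_state: binary (1 = closed) at ``eye_rate_hz``; yawns are
    (start_s, duration_s) events; fisa are (time_min, score 1..5)
    verbal self-reports, time in minutes from recording start.
    """

    eye_state: np.ndarray
    eye_rate_hz: float
    yawns: list[tuple[float, float]]
    fisa: list[tuple[float, int]]


@dataclass
class MultimodalRecording:
    """One session: 3-channel prefrontal EEG, 10-channel fNIRS, behavior.

    EEG in microvolts at 250 Hz; fNIRS detector voltages in volts at
    12.5 Hz, keyed by (channel, wavelength nm); time zero is the start of
    the 1-minute rest that precedes the 80-minute drive.
    """

    subject_id: str
    paradigm: str  # "active" | "passive"
    eeg: dict[str, np.ndarray]
    eeg_rate_hz: float
    fnirs_voltages: dict[tuple[str, int], np.ndarray]
    fnirs_rate_hz: float
    dark_voltages: dict[tuple[str, int], float]
    geometry_mm: dict[str, float]
    behavior: BehaviorStreams
    duration_s: float

    def validate(self) -> None:
        if self.paradigm not in ("active", "passive"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        for ch in EEG_CHANNELS:
            if ch not in self.eeg:
                raise ValueError(f"missing EEG channel {ch}")
        n_eeg = int(round(self.duration_s * self.eeg_rate_hz))
        for ch, x in self.eeg.items():
            if abs(len(x) - n_eeg) > 1:
                raise ValueError(
                    f"EEG channel {ch}: {len(x)} samples, expected ~{n_eeg}"
                )
        present = {ch for ch, _ in self.fnirs_voltages}
        for ch in ALL_CHANNELS:
            if ch not in present:
                raise ValueError(f"missing fNIRS channel {ch}")
        extra = present - set(ALL_CHANNELS)
        if extra:
            raise ValueError(f"unexpected fNIRS channels {sorted(extra)}")
        n_nirs = int(round(self.duration_s * self.fnirs_rate_hz))
        for key, x in self.fnirs_voltages.items():
            if abs(len(x) - n_nirs) > 1:
                raise ValueError(
                    f"fNIRS channel {key}: {len(x)} samples, expected ~{n_nirs}"
                )
            if key not in self.dark_voltages:
                raise ValueError(f"missing dark voltage for {key}")
        for ch in ALL_CHANNELS:
            if ch not in self.geometry_mm:
                raise ValueError(f"missing geometry for {ch}")
        for t, s in self.behavior.fisa:
            if s not in (1, 2, 3, 4, 5):
                raise ValueError(f"F-ISA score {s} at {t} min outside 1..5")
        wavelengths = {wl for _, wl in self.fnirs_voltages}
        if wavelengths != set(WAVELENGTHS):
            raise ValueError(f"wavelength set {sorted(wavelengths)} != {WAVELENGTHS}")


@dataclass
class Interval:
    start_s: float
    end_s: float
    label: str


@dataclass
class TransitionPoint:
    time_s: float
    direction: str  # "up" | "down"
    evidence: str  # "perclos_derivative" | "yawn" | "segment_boundary"
    low_confidence: bool = False


@dataclass
class StageTimeline:
    """Ordered NonF/ModF/SevF intervals partitioning the driving period."""

    intervals: list[Interval]
    transitions: list[TransitionPoint] = field(default_factory=list)

    def validate(self, drive_start_s: float, drive_end_s: float) -> None:
        iv = self.intervals
        if not iv:
            raise ValueError("empty timeline")
        if abs(iv[0].start_s - drive_start_s) > 1e-9:
            raise ValueError("timeline does not start at the driving period")
        if abs(iv[-1].end_s - drive_end_s) > 1e-9:
            raise ValueError("timeline does not end at the driving period")
        for a, b in zip(iv, iv[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError("timeline intervals are not contiguous")
            if a.label == b.label:
                raise ValueError("adjacent timeline intervals share a label")
        times = [t.time_s for t in self.transitions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("transition times not strictly increasing")

    def label_at(self, t: float) -> str | None:
        """Stage containing time ``t``; ties at a boundary go to the later stage."""
        for itv in self.intervals:
            if itv.start_s <= t < itv.end_s:
                return itv.label
        if self.intervals and t == self.intervals[-1].end_s:
            return self.intervals[-1].label
        return None


@dataclass
class GroundTruth:
    """Programmed truth for a simulated session (test oracle)."""

    timeline: StageTimeline
    stage_band_sd_uv: dict[str, dict[str, float]]
    stage_hbo_um: dict[str, float]
    stage_hbr_um: dict[str, float]
    stage_ibi_s: dict[str, float]
    stage_ibi_jitter_s: dict[str, float]
    subject_offsets: dict[str, float] = field(default_factory=dict)
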