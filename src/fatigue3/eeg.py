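"""Prefrontal EEG preprocessing and spectral features.

The feature set follows the conventional drowsiness literature: relative
power of the delta/theta/alpha/beta bands within each non-overlapping 30 s
window, plus the beta/(theta+alpha) ratio indexing the dominance of
engagement-related fast activity over fatigue-related slow activity.
The 13-14 Hz gap between the alpha and beta definitions is excluded from
every band power.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .config import EEG_BANDS, EEG_CHANNELS, EEGConfig, RunConfig, WindowConfig
from .types import MultimodalRecording, StageTimeline
from .labeling import assign_windows

try:  # the sequential adaptive-filter update is the only hot scalar loop here
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


@dataclass
class BandPowerSet:
    """Absolute band powers (uV^2) for the four conventional bands."""

    delta: float
    theta: float
    alpha: float
    beta: float

    def total(self) -> float:
        return self.delta + self.theta + self.alpha + self.beta


def preprocess_eeg(
    eeg: dict[str, np.ndarray], cfg: EEGConfig
) -> tuple[dict[str, np.ndarray], dict[str, bool]]:
    """Notch the four switching-crosstalk lines, band-pass 0.5-30 Hz, flag bad channels.

    All filtering is zero-phase.  The manual bad-channel inspection of the
    original protocol is replaced by an automated proxy: a 30 s window is
    flagged when peak-to-peak exceeds ``bad_ptp_uv`` or the signal is flat
    for more than ``bad_flat_s``; a channel is masked when more than
    ``bad_window_fraction`` of its windows are flagged.
    """
    fs = cfg.rate_hz
    out: dict[str, np.ndarray] = {}
    mask: dict[str, bool] = {}
    sos_bp = signal.butter(
        cfg.filter_order, cfg.bandpass_hz, btype="bandpass", fs=fs, output="sos"
    )
    notches = [signal.iirnotch(f0, cfg.notch_q, fs=fs) for f0 in cfg.notch_freqs_hz]
    for ch, x in eeg.items():
        y = np.asarray(x, float)
        for b, a in notches:
            y = signal.filtfilt(b, a, y)
        y = signal.sosfiltfilt(sos_bp, y)
        out[ch] = y
        mask[ch] = _channel_is_bad(np.asarray(x, float), cfg)
    if all(mask.get(ch, False) for ch in EEG_CHANNELS):
        raise ValueError("all EEG channels flagged bad")
    return out, mask


def _channel_is_bad(x: np.ndarray, cfg: EEGConfig) -> bool:
    fs = cfg.rate_hz
    win = int(round(30.0 * fs))
    n = x.size // win
    if n == 0:
        return False
    flat_run = int(round(cfg.bad_flat_s * fs))
    flagged = 0
    for k in range(n):
        seg = x[k * win : (k + 1) * win]
        if np.ptp(seg) > cfg.bad_ptp_uv:
            flagged += 1
            continue
        # flatline: longest run of (numerically) constant signal
        const = np.abs(np.diff(seg)) < 1e-12
        if const.any():
            runs = np.diff(np.flatnonzero(np.concatenate(([True], ~const, [True]))))
            if const.all() or (runs.size and runs.max() >= flat_run):
                flagged += 1
    return flagged > cfg.bad_window_fraction * n


if njit is not None:

    @njit(cache=True)
    def _adaptive_cancel(x, ref, upd, order, mu, eps):  # pragma: no cover - compiled
        n = x.size
        w = np.zeros(order)
        u = np.zeros(order)
        out = np.empty(n)
        for i in range(n):
            for j in range(order - 1, 0, -1):
                u[j] = u[j - 1]
            u[0] = ref[i]
            y = 0.0
            for j in range(order):
                y += w[j] * u[j]
            e = x[i] - y
            out[i] = e
            if upd[i]:
                norm = eps
                for j in range(order):
                    norm += u[j] * u[j]
                g = mu * e / norm
                for j in range(order):
                    w[j] += g * u[j]
        return out

else:  # pragma: no cover - numba is a hard dependency in practice

    def _adaptive_cancel(x, ref, upd, order, mu, eps):
        n = x.size
        w = np.zeros(order)
        u = np.zeros(order)
        out = np.empty(n)
        for i in range(n):
            u[1:] = u[:-1]
            u[0] = ref[i]
            e = x[i] - w @ u
            out[i] = e
            if upd[i]:
                w += mu * e * u / (eps + u @ u)
        return out


def remove_ocular(x: np.ndarray, cfg: EEGConfig | None = None) -> np.ndarray:
    """Wavelet-assisted adaptive cancelation of blink artifacts.

    A stationary wavelet decomposition (sym4) isolates the low-frequency
    approximation; samples where that approximation exceeds k*MAD form the
    blink reference, which a normalized-LMS adaptive filter subtracts from
    the signal (normalized LMS is unconditionally stable under the bursty,
    gated excitation a blink reference provides).  Blink-free stretches
    pass through nearly unchanged because the reference is zero there.
    """
    cfg = cfg or EEGConfig()
    x = np.asarray(x, float)
    if x.size == 0 or not np.any(x):
        return x.copy()
    level = cfg.ocular_swt_level
    block = 2**level
    pad = (-x.size) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = pywt.swt(xp, cfg.ocular_wavelet, level=level, trim_approx=True)
    approx = np.asarray(coeffs[0])[: x.size]
    mad = np.median(np.abs(approx - np.median(approx)))
    thresh = cfg.ocular_mad_k * 1.4826 * mad
    active = np.abs(approx) > thresh
    if not active.any():
        return x.copy()
    # taper the blink gate: a hard on/off reference would inject broadband
    # steps at epoch edges through the adaptive subtraction
    fs = cfg.rate_hz
    dilate = np.ones(int(round(0.15 * fs)) * 2 + 1)
    gate = np.convolve(active.astype(float), dilate, "same") > 0
    hann = np.hanning(int(round(0.2 * fs)) * 2 + 1)
    gate = np.convolve(gate.astype(float), hann / hann.sum(), "same")
    gate = np.clip(gate, 0.0, 1.0)
    ref = approx * gate
    upd = gate > 0.5
    return _adaptive_cancel(x, ref, upd, cfg.adaptive_order, cfg.adaptive_mu, 1e-12)


def band_powers(window: np.ndarray, cfg: EEGConfig | None = None) -> BandPowerSet:
    """Welch band powers of one 30 s window (4 s Hann segments, 50% overlap)."""
    cfg = cfg or EEGConfig()
    x = np.asarray(window, float)
    nperseg = int(round(cfg.welch_segment_s * cfg.rate_hz))
    noverlap = int(round(nperseg * cfg.welch_overlap))
    f, psd = signal.welch(
        x, fs=cfg.rate_hz, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    df = f[1] - f[0]
    powers = {}
    for name, (lo, hi) in EEG_BANDS.items():
        sel = (f >= lo) & (f < hi)
        powers[name] = float(psd[sel].sum() * df)
    return BandPowerSet(**powers)


def rpl(powers: BandPowerSet) -> dict[str, float]:
    """Relative power level of each band: P_m over the four-band total."""
    total = powers.total()
    if total <= 0:
        return {b: np.nan for b in EEG_BANDS}
    return {b: getattr(powers, b) / total for b in EEG_BANDS}


def beta_ratio(powers: BandPowerSet) -> float:
    """beta / (theta + alpha) power ratio."""
    denom = powers.theta + powers.alpha
    if denom <= 0:
        return np.nan
    return powers.beta / denom


def eeg_feature_table(
    recording: MultimodalRecording,
    timeline: StageTimeline,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-30 s-window relative band powers and beta ratio, per channel and averaged."""
    config = config or RunConfig()
    cfg = config.eeg
    wcfg = config.windows
    cleaned, bad = preprocess_eeg(recording.eeg, cfg)
    cleaned = {ch: remove_ocular(x, cfg) for ch, x in cleaned.items()}

    labels = assign_windows(timeline, wcfg)
    fs = cfg.rate_hz
    wlen = int(round(wcfg.window_s * fs))
    rows = []
    feat_names = [f"rpl_{b}" for b in EEG_BANDS] + ["eta"]
    for mid, stage in labels:
        start = int(round((mid - wcfg.window_s / 2.0) * fs))
        row: dict[str, object] = {"window_mid_s": mid, "stage": stage}
        per_channel: dict[str, list[float]] = {f: [] for f in feat_names}
        for ch in EEG_CHANNELS:
            suffix = ch.lower()
            if bad.get(ch, False):
                for f in feat_names:
                    row[f"{f}_{suffix}"] = np.nan
                continue
            seg = cleaned[ch][start : start + wlen]
            if seg.size < wlen:
                for f in feat_names:
                    row[f"{f}_{suffix}"] = np.nan
                continue
            p = band_powers(seg, cfg)
            vals = rpl(p)
            for b in EEG_BANDS:
                row[f"rpl_{b}_{suffix}"] = vals[b]
                per_channel[f"rpl_{b}"].append(vals[b])
            eta = beta_ratio(p)
            row[f"eta_{suffix}"] = eta
            per_channel["eta"].append(eta)
        for f in feat_names:
            good = [v for v in per_channel[f] if np.isfinite(v)]
            row[f"{f}_chavg"] = float(np.mean(good)) if good else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
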