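"""fNIRS optical-density processing and hemodynamic features.

Chain: dark-corrected voltages -> optical density against a 2 s baseline ->
quality screen -> spline+wavelet motion correction -> cubic detrend ->
dual short-channel regression (superficial-noise removal) -> modified
Beer-Lambert inversion -> 0.1 Hz low-pass -> location pairing -> per-window
means, normalized per experiment to [-1, 1] by 5-95 percentile min-max.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt
from scipy import interpolate, signal

from .config import (
    FNIRSConfig,
    LOCATION_PAIRS,
    LONG_CHANNELS,
    LONG_TO_SHORTS,
    RunConfig,
    SHORT_CHANNELS,
    WAVELENGTHS,
    WindowConfig,
)
from .optics import derive_hbt_coe, mbll_inverse
from .types import MultimodalRecording, StageTimeline
from .labeling import assign_windows

HEMO_FEATURES = ("hbo", "hbr", "hbt", "coe")


def to_optical_density(
    voltages: np.ndarray,
    dark: float,
    rate_hz: float = 12.5,
    baseline_s: float = 2.0,
) -> np.ndarray:
    """dOD = -log10((V - dark) / (V_baseline - dark)).

    ``V_baseline`` is the mean dark-corrected voltage over the first
    ``baseline_s`` seconds.  Non-positive corrected voltages are masked
    (NaN) with a warning rather than propagating complex logs.
    """
    v = np.asarray(voltages, float) - dark
    n_base = max(1, int(round(baseline_s * rate_hz)))
    v_base = float(np.mean(v[:n_base]))
    if v_base <= 0:
        raise ValueError("non-positive baseline voltage after dark correction")
    bad = v <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive corrected voltage samples masked")
        v = np.where(bad, np.nan, v)
    return -np.log10(v / v_base)


def quality_screen(od: np.ndarray, cfg: FNIRSConfig | None = None) -> np.ndarray:
    """Boolean mask of samples with inadequate signal quality.

    Automated proxy for the protocol's visual inspection: flags saturation
    plateaus (flat runs longer than ``flatline_s``), |dOD| excursions above
    ``od_excursion_limit``, and whole 30 s windows lacking a cardiac
    spectral peak at least ``cardiac_snr_db`` above the in-band background.
    """
    cfg = cfg or FNIRSConfig()
    x = np.asarray(od, float)
    mask = ~np.isfinite(x)
    mask |= np.abs(np.where(np.isfinite(x), x, 0.0)) > cfg.od_excursion_limit

    # flat (saturated) runs
    flat_run = max(2, int(round(cfg.flatline_s * cfg.rate_hz)))
    const = np.abs(np.diff(x)) < 1e-12
    if const.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], const.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s + 1 >= flat_run:
                mask[s : e + 2] = True

    # cardiac SNR per 30 s window: the band must contain an interior,
    # locally prominent spectral peak -- drift leakage is monotone across
    # the band and therefore peaks at the band edge without prominence
    win = int(round(30.0 * cfg.rate_hz))
    lo, hi = cfg.cardiac_band_hz
    ratio_min = 10 ** (cfg.cardiac_snr_db / 10.0)
    for k in range(x.size // win):
        seg = x[k * win : (k + 1) * win]
        if not np.all(np.isfinite(seg)):
            continue
        f, psd = signal.welch(
            seg, fs=cfg.rate_hz, nperseg=min(128, win), detrend="linear"
        )
        band_idx = np.flatnonzero((f >= lo) & (f <= hi))
        if band_idx.size < 3:
            continue
        interior = band_idx[1:-1]
        j = interior[int(np.argmax(psd[interior]))]
        f0 = f[j]
        flank = ((np.abs(f - f0) >= 0.2) & (np.abs(f - f0) <= 0.4))
        background = np.median(psd[flank]) if flank.any() else 0.0
        edge_peak = max(psd[band_idx[0]], psd[band_idx[-1]])
        prominent = (
            background > 0
            and psd[j] >= ratio_min * background
            and psd[j] >= edge_peak
        )
        if not prominent:
            mask[k * win : (k + 1) * win] = True
    return mask


def correct_motion(od: np.ndarray, cfg: FNIRSConfig | None = None) -> np.ndarray:
    """Hybrid spline + wavelet motion correction.

    Motion epochs are detected where the 1 s moving standard deviation
    exceeds ``motion_sd_k`` times the channel's median moving SD; within
    each epoch a smoothing-spline estimate of the artifact is subtracted
    and the segment re-anchored to its neighbours.  A wavelet soft
    threshold then attenuates residual spikes across the whole series.
    """
    cfg = cfg or FNIRSConfig()
    x = np.asarray(od, float).copy()
    n = x.size
    if n < 8 or not np.any(np.isfinite(x)):
        return x
    finite = np.isfinite(x)
    xf = np.where(finite, x, np.nanmedian(x[finite]) if finite.any() else 0.0)

    w = max(2, int(round(cfg.motion_sd_window_s * cfg.rate_hz)))
    series = pd.Series(xf)
    msd = series.rolling(w, center=True, min_periods=1).std().to_numpy()
    med = np.nanmedian(msd)
    if med > 0:
        bad = msd > cfg.motion_sd_k * med
        grow = max(1, int(round(cfg.motion_pad_s * cfg.rate_hz)))
        bad = np.convolve(bad.astype(int), np.ones(2 * grow + 1, int), "same") > 0
        # extend each epoch over any step's decay tail: keep absorbing
        # samples until the smoothed level returns to the pre-epoch baseline
        smooth = series.rolling(w, center=True, min_periods=1).mean().to_numpy()
        edges0 = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        max_ext = int(round(15.0 * cfg.rate_hz))
        for s, e in zip(edges0[::2], edges0[1::2]):
            pre = smooth[max(0, s - 3 * grow) : max(1, s - grow)]
            if pre.size == 0:
                continue
            base = np.median(pre)
            j = int(e)
            while j < min(n, e + max_ext) and abs(smooth[j] - base) > 3 * med:
                bad[j] = True
                j += 1
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            s0, e0 = int(s), int(e)
            seg = xf[s0:e0]
            if seg.size < 4:
                continue
            t = np.arange(seg.size, dtype=float)
            spl = interpolate.UnivariateSpline(t, seg, k=3, s=seg.size * np.var(seg) * 0.01)
            artifact = spl(t)
            left = xf[max(0, s0 - grow) : s0]
            right = xf[e0 : e0 + grow]
            anchor_l = left.mean() if left.size else seg[0]
            anchor_r = right.mean() if right.size else seg[-1]
            bridge = np.linspace(anchor_l, anchor_r, seg.size)
            xf[s0:e0] = seg - artifact + bridge

    # wavelet clipping of residual spikes: detail coefficients beyond
    # k*MAD are shrunk to the threshold, everything else passes untouched
    level = min(cfg.wavelet_level, pywt.dwt_max_level(n, cfg.wavelet))
    if level >= 1:
        coeffs = pywt.wavedec(xf, cfg.wavelet, level=level)
        for i in range(1, len(coeffs)):
            c = coeffs[i]
            mad = np.median(np.abs(c - np.median(c)))
            thr = cfg.wavelet_mad_k * 1.4826 * mad
            if thr > 0:
                coeffs[i] = np.clip(c, -thr, thr)
        xf = pywt.waverec(coeffs, cfg.wavelet)[:n]
    out = np.where(finite, xf, np.nan)
    return out


def detrend_poly3(od: np.ndarray) -> np.ndarray:
    """Remove a least-squares cubic drift model from the series."""
    x = np.asarray(od, float)
    if x.size <= 4:
        raise ValueError("series too short for cubic detrending")
    t = np.arange(x.size, dtype=float)
    finite = np.isfinite(x)
    coef = np.polynomial.polynomial.polyfit(t[finite], x[finite], 3)
    return x - np.polynomial.polynomial.polyval(t, coef)


def short_channel_denoise(
    od_long: np.ndarray, od_short_src: np.ndarray, od_short_det: np.ndarray
) -> np.ndarray:
    """Least-squares projection residual of the long channel on both shorts.

    dOD_brain = dOD_L - S (S^T S)^-1 S^T dOD_L with S = [src, det]; no
    intercept because all series are baseline-referenced.  A collinear or
    null short regressor is dropped with a warning.
    """
    y = np.asarray(od_long, float)
    cols = [np.asarray(od_short_src, float), np.asarray(od_short_det, float)]
    finite = np.isfinite(y)
    for c in cols:
        finite &= np.isfinite(c)
    keep: list[np.ndarray] = []
    for c in cols:
        nrm = np.linalg.norm(c[finite])
        if nrm < 1e-12:
            warnings.warn("null short-channel regressor dropped")
            continue
        if keep:
            prev = keep[0]
            cos = abs(prev[finite] @ c[finite]) / (
                np.linalg.norm(prev[finite]) * nrm
            )
            if cos > 1 - 1e-12:
                warnings.warn("collinear short-channel regressor dropped")
                continue
        keep.append(c)
    if not keep:
        return y.copy()
    S = np.stack(keep, axis=1)
    beta, *_ = np.linalg.lstsq(S[finite], y[finite], rcond=None)
    resid = y - S @ beta
    return resid


def lowpass_hemo(x: np.ndarray, cfg: FNIRSConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass at 0.1 Hz for hemodynamic series."""
    cfg = cfg or FNIRSConfig()
    sos = signal.butter(
        cfg.filter_order, cfg.lowpass_hz, btype="low", fs=cfg.rate_hz, output="sos"
    )
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    y = signal.sosfiltfilt(sos, xf)
    return np.where(finite, y, np.nan)


def pair_locations(series_by_channel: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Average each long-channel pair into its prefrontal location series.

    If one pair member is entirely missing the other is used alone (with a
    warning); if both are missing the location is NaN.
    """
    out: dict[str, np.ndarray] = {}
    for loc, (a, b) in LOCATION_PAIRS.items():
        xa = series_by_channel.get(a)
        xb = series_by_channel.get(b)
        have_a = xa is not None and np.any(np.isfinite(xa))
        have_b = xb is not None and np.any(np.isfinite(xb))
        if have_a and have_b:
            out[loc] = np.nanmean(np.stack([xa, xb]), axis=0)
        elif have_a or have_b:
            warnings.warn(f"location {loc}: one pair member missing, using the other")
            out[loc] = np.array(xa if have_a else xb, float)
        else:
            n = len(xa) if xa is not None else (len(xb) if xb is not None else 0)
            out[loc] = np.full(n, np.nan)
    return out


def normalize_features(
    values: np.ndarray,
    percentiles: tuple[float, float] = (5.0, 95.0),
    out_range: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Percentile-based min-max normalization, clipped to ``out_range``.

    x' maps the 5th percentile to the range minimum and the 95th to the
    maximum; a degenerate spread (p95 == p5) maps to the range midpoint.
    """
    x = np.asarray(values, float)
    finite = np.isfinite(x)
    if not finite.any():
        return x.copy()
    p_lo, p_hi = np.percentile(x[finite], percentiles)
    lo, hi = out_range
    if p_hi <= p_lo:
        warnings.warn("degenerate feature spread; normalized to range midpoint")
        out = np.where(finite, (lo + hi) / 2.0, np.nan)
        return out
    scaled = lo + (hi - lo) * (x - p_lo) / (p_hi - p_lo)
    return np.clip(scaled, lo, hi)


def process_fnirs_od(
    recording: MultimodalRecording,
    config: RunConfig | None = None,
    robust: bool = True,
) -> tuple[dict[tuple[str, int], np.ndarray], dict[tuple[str, int], np.ndarray]]:
    """Voltages -> cleaned optical density for every channel/wavelength.

    Returns (od, mask).  ``robust=False`` skips the motion-correction and
    detrending stages (used for exactness checks on noise-free data, where
    detrending would remove part of a deterministic stage profile).
    """
    config = config or RunConfig()
    cfg = config.fnirs
    od: dict[tuple[str, int], np.ndarray] = {}
    masks: dict[tuple[str, int], np.ndarray] = {}
    for key, v in recording.fnirs_voltages.items():
        x = to_optical_density(
            v, recording.dark_voltages[key], cfg.rate_hz, cfg.baseline_s
        )
        m = quality_screen(x, cfg) if robust else ~np.isfinite(x)
        if robust:
            x = correct_motion(x, cfg)
            x = detrend_poly3(x)
        od[key] = x
        masks[key] = m
    return od, masks


def denoise_long_channels(
    od: dict[tuple[str, int], np.ndarray]
) -> dict[tuple[str, int], np.ndarray]:
    """Apply the dual short-channel regression to every long channel/wavelength."""
    out: dict[tuple[str, int], np.ndarray] = {}
    for ch in LONG_CHANNELS:
        s_src, s_det = LONG_TO_SHORTS[ch]
        for wl in WAVELENGTHS:
            out[(ch, wl)] = short_channel_denoise(
                od[(ch, wl)], od[(s_src, wl)], od[(s_det, wl)]
            )
    return out


def hemodynamics_by_location(
    od_brain: dict[tuple[str, int], np.ndarray],
    config: RunConfig | None = None,
    lowpass: bool = True,
) -> dict[str, dict[str, np.ndarray]]:
    """MBLL inversion, 0.1 Hz low-pass, HbT/COE derivation and location pairing."""
    config = config or RunConfig()
    per_channel: dict[str, dict[str, np.ndarray]] = {f: {} for f in HEMO_FEATURES}
    for ch in LONG_CHANNELS:
        od3 = np.stack([od_brain[(ch, wl)] for wl in WAVELENGTHS], axis=1)
        hbo, hbr = mbll_inverse(od3, config.optics, short=False)
        if lowpass:
            hbo = lowpass_hemo(hbo, config.fnirs)
            hbr = lowpass_hemo(hbr, config.fnirs)
        hbt, coe = derive_hbt_coe(hbo, hbr)
        per_channel["hbo"][ch] = hbo
        per_channel["hbr"][ch] = hbr
        per_channel["hbt"][ch] = hbt
        per_channel["coe"][ch] = coe
    return {f: pair_locations(per_channel[f]) for f in HEMO_FEATURES}


def hemo_feature_table(
    location_series: dict[str, dict[str, np.ndarray]],
    timeline: StageTimeline,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-window means of dHbO/dHbR/dHbT/dCOE per location plus channel average.

    Adds per-experiment normalized columns (suffix ``_norm``) mapped to
    [-1, 1] by 5-95 percentile min-max; a window with more than half its
    samples masked is missing.
    """
    config = config or RunConfig()
    wcfg = config.windows
    fs = config.fnirs.rate_hz
    wlen = int(round(wcfg.window_s * fs))
    labels = assign_windows(timeline, wcfg)
    locations = list(LOCATION_PAIRS)
    rows = []
    for mid, stage in labels:
        start = int(round((mid - wcfg.window_s / 2.0) * fs))
        row: dict[str, object] = {"window_mid_s": mid, "stage": stage}
        for feat in HEMO_FEATURES:
            vals = []
            for loc in locations:
                seg = location_series[feat][loc][start : start + wlen]
                if seg.size < wlen or np.mean(~np.isfinite(seg)) > config.fnirs.window_missing_fraction:
                    row[f"m_{feat}_{loc.lower()}"] = np.nan
                else:
                    m = float(np.nanmean(seg))
                    row[f"m_{feat}_{loc.lower()}"] = m
                    vals.append(m)
            row[f"m_{feat}_chavg"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    pcts = config.stats.normalization_percentiles
    for col in [c for c in df.columns if c.startswith("m_")]:
        df[col + "_norm"] = normalize_features(df[col].to_numpy(), pcts, (-1.0, 1.0))
    return df
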