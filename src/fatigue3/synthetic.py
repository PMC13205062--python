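"""Synthetic multimodal driving-fatigue sessions with known ground truth.

The generator inverts the analysis chain: EEG is band-limited noise whose
per-band variance follows a programmed stage schedule; fNIRS detector
voltages are produced by running programmed hemoglobin concentration
changes forward through the same Beer-Lambert tables the analysis inverts
(plus superficial Mayer/respiration waves shared between each long channel
and its flanking short channels, cardiac pulsation with stage-dependent
inter-beat jitter, cubic drift and step+decay motion spikes); behavioral
streams carry a deterministic eyelid duty cycle that steps at the
programmed transitions, with yawns placed at upward transitions.

Scenario defaults reproduce the study conditions: 1 min rest + 80 min
drive, self-reports every 10 min, transitions drawn around 34.3/53.8 min
(active) and 24.5/40.2 min (passive).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import (
    EEG_BANDS,
    EEG_CHANNELS,
    LOCATION_PAIRS,
    LONG_CHANNELS,
    LONG_TO_SHORTS,
    RunConfig,
    SHORT_CHANNELS,
    STAGES,
    WAVELENGTHS,
)
from .optics import mbll_forward
from .types import (
    BehaviorStreams,
    GroundTruth,
    Interval,
    MultimodalRecording,
    StageTimeline,
    TransitionPoint,
)

#: Mean and SD (minutes into the drive) of the two upward transitions.
TRANSITION_PRIORS = {
    "active": ((34.3, 10.3), (53.8, 15.4)),
    "passive": ((24.5, 8.8), (40.2, 13.2)),
}

# Per-stage EEG band variances (uV^2).  The active profile makes the
# beta/(theta+alpha) ratio follow an inverted U (0.975 -> 1.152 -> 0.908);
# the passive profile declines late (0.82 -> 0.806 -> 0.761).
ACTIVE_BAND_VAR = {
    "NonF": {"delta": 10.0, "theta": 8.0, "alpha": 12.0, "beta": 19.5},
    "ModF": {"delta": 8.0, "theta": 6.5, "alpha": 10.0, "beta": 19.0},
    "SevF": {"delta": 7.0, "theta": 9.0, "alpha": 15.0, "beta": 21.8},
}
PASSIVE_BAND_VAR = {
    "NonF": {"delta": 10.0, "theta": 8.0, "alpha": 12.0, "beta": 16.4},
    "ModF": {"delta": 10.7, "theta": 8.0, "alpha": 12.4, "beta": 16.44},
    "SevF": {"delta": 8.6, "theta": 8.0, "alpha": 13.1, "beta": 16.06},
}

# Stage-mean hemodynamics (umol/L) shared across the three locations.
ACTIVE_HBO = {"NonF": 0.30, "ModF": 0.30, "SevF": -0.30}
ACTIVE_HBR = {"NonF": -0.10, "ModF": 0.15, "SevF": -0.08}
PASSIVE_HBO = {"NonF": -0.04, "ModF": -0.03, "SevF": -0.07}
PASSIVE_HBR = {"NonF": -0.05, "ModF": 0.00, "SevF": -0.05}

# Cardiac schedule: mean inter-beat interval and its jitter SD (s).
ACTIVE_IBI = {"NonF": 0.85, "ModF": 0.88, "SevF": 0.92}
ACTIVE_JITTER = {"NonF": 0.022, "ModF": 0.027, "SevF": 0.032}
PASSIVE_IBI = {"NonF": 0.85, "ModF": 0.90, "SevF": 0.95}
PASSIVE_JITTER = {"NonF": 0.018, "ModF": 0.030, "SevF": 0.042}

#: Eyelid-closure fraction per stage (duty cycle of the eye-state stream).
PERCLOS_BY_STAGE = {"NonF": 0.02, "ModF": 0.05, "SevF": 0.09}

FISA_BY_STAGE = {"NonF": 2, "ModF": 3, "SevF": 4}


@dataclass
class ScenarioSpec:
    """Fully populated description of one simulated session."""

    paradigm: str
    seed: int
    transition_times_min: tuple[float, float]
    band_var_uv2: dict[str, dict[str, float]]
    hbo_um: dict[str, float]
    hbr_um: dict[str, float]
    ibi_s: dict[str, float]
    ibi_jitter_s: dict[str, float]
    perclos: dict[str, float] = field(default_factory=lambda: dict(PERCLOS_BY_STAGE))
    mayer_amp_um: float = 1.0
    resp_amp_um: float = 0.5
    superficial_hbr_ratio: float = -0.35
    superficial_coupling: float = 0.4
    pulse_amp_hbo_um: float = 2.0
    pulse_amp_hbr_um: float = -0.5
    motion_spike_rate_per_min: float = 0.3
    motion_spike_amp_od: float = 0.08
    drift_od_amp: float = 0.02
    od_noise_sd: float = 4e-4  # long channels (low light level)
    od_noise_sd_short: float = 1e-4  # shorts collect ~10x more light
    ocular_rate_per_min: float = 4.0
    ocular_amp_uv: float = 80.0
    crosstalk_amp_uv: float = 1.5
    eeg_noise_sd_uv: float = 1.0
    eye_rate_hz: float = 10.0
    crossfade_s: float = 10.0
    rest_s: float = 60.0
    drive_s: float = 4800.0
    hemo_offset_um: float = 0.0  # per-subject random intercept (cohorts)
    beta_var_scale: float = 1.0
    jitter_scale: float = 1.0

    def validate(self) -> None:
        t1, t2 = self.transition_times_min
        if not 0 < t1 < t2 < self.drive_s / 60.0:
            raise ValueError(f"invalid transition times {self.transition_times_min}")
        for stage in STAGES:
            for band, v in self.band_var_uv2[stage].items():
                if v < 0:
                    raise ValueError(f"negative band variance {band}@{stage}")
            if not 0.5 <= self.ibi_s[stage] <= 1.5:
                raise ValueError(f"mean IBI out of [0.5, 1.5] s at {stage}")

    @property
    def duration_s(self) -> float:
        return self.rest_s + self.drive_s


def make_scenario(paradigm: str, seed: int = 0, overrides: dict | None = None) -> ScenarioSpec:
    """Deterministic scenario for (paradigm, seed) with optional field overrides.

    Transition times are drawn from the paradigm's priors and redrawn until
    they are ordered with at least 4 minutes between them and 4 minutes of
    margin at either end of the drive.
    """
    if paradigm not in TRANSITION_PRIORS:
        raise ValueError(f"paradigm must be 'active' or 'passive', got {paradigm!r}")
    rng = np.random.default_rng(seed)
    (m1, s1), (m2, s2) = TRANSITION_PRIORS[paradigm]
    for _ in range(1000):
        t1 = rng.normal(m1, s1)
        t2 = rng.normal(m2, s2)
        if 4.0 <= t1 and t1 + 4.0 <= t2 <= 76.0:
            break
    else:  # pragma: no cover - priors make this astronomically unlikely
        t1, t2 = m1, m2
    if paradigm == "active":
        band_var, hbo, hbr = ACTIVE_BAND_VAR, ACTIVE_HBO, ACTIVE_HBR
        ibi, jit = ACTIVE_IBI, ACTIVE_JITTER
    else:
        band_var, hbo, hbr = PASSIVE_BAND_VAR, PASSIVE_HBO, PASSIVE_HBR
        ibi, jit = PASSIVE_IBI, PASSIVE_JITTER
    spec = ScenarioSpec(
        paradigm=paradigm,
        seed=seed,
        transition_times_min=(float(t1), float(t2)),
        band_var_uv2={s: dict(band_var[s]) for s in STAGES},
        hbo_um=dict(hbo),
        hbr_um=dict(hbr),
        ibi_s=dict(ibi),
        ibi_jitter_s=dict(jit),
    )
    if overrides:
        for key, value in overrides.items():
            if not hasattr(spec, key):
                raise ValueError(f"unknown scenario field {key!r}")
            setattr(spec, key, value)
    spec.validate()
    return spec


def truth_timeline(spec: ScenarioSpec) -> StageTimeline:
    t1 = spec.rest_s + spec.transition_times_min[0] * 60.0
    t2 = spec.rest_s + spec.transition_times_min[1] * 60.0
    end = spec.rest_s + spec.drive_s
    return StageTimeline(
        [
            Interval(spec.rest_s, t1, "NonF"),
            Interval(t1, t2, "ModF"),
            Interval(t2, end, "SevF"),
        ],
        [
            TransitionPoint(t1, "up", "yawn"),
            TransitionPoint(t2, "up", "yawn"),
        ],
    )


def _stage_at(spec: ScenarioSpec, t_s: float) -> str:
    t1 = spec.rest_s + spec.transition_times_min[0] * 60.0
    t2 = spec.rest_s + spec.transition_times_min[1] * 60.0
    if t_s < t1:
        return "NonF"
    if t_s < t2:
        return "ModF"
    return "SevF"


def _stage_profile(
    spec: ScenarioSpec, values: dict[str, float], t: np.ndarray,
    zero_in_rest: bool = False,
) -> np.ndarray:
    """Piecewise-stage value with raised-cosine crossfades at the transitions."""
    t1 = spec.rest_s + spec.transition_times_min[0] * 60.0
    t2 = spec.rest_s + spec.transition_times_min[1] * 60.0
    prof = np.full(t.shape, values["NonF"], float)
    for t_star, v_from, v_to in (
        (t1, values["NonF"], values["ModF"]),
        (t2, values["ModF"], values["SevF"]),
    ):
        half = spec.crossfade_s / 2.0
        ramp = np.clip((t - (t_star - half)) / spec.crossfade_s, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * ramp)
        prof = prof + (v_to - v_from) * w
    if zero_in_rest:
        on = np.clip((t - (spec.rest_s - spec.crossfade_s)) / spec.crossfade_s, 0, 1)
        prof = prof * (0.5 - 0.5 * np.cos(np.pi * on))
    return prof


def simulate_behavior(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> BehaviorStreams:
    """Self-reports, eye-state duty cycle and yawns consistent with the truth.

    The eye stream is deterministic: inside each 8 s block the eyes are
    closed for exactly the stage's PERCLOS fraction, so block-wise PERCLOS
    steps sharply at the programmed transitions.  A 2 s yawn marks each
    upward transition; short 1.2 s events (below the 1.5 s validity bound)
    are sprinkled in as distractors.
    """
    del rng  # behavior is deterministic given the spec
    fs = spec.eye_rate_hz
    n = int(round(spec.duration_s * fs))
    block = int(round(8.0 * fs))
    eye = np.zeros(n, dtype=float)
    for b0 in range(0, n - block + 1, block):
        t_block = b0 / fs
        p = spec.perclos[_stage_at(spec, t_block)]
        n_closed = int(round(p * block))
        eye[b0 : b0 + n_closed] = 1.0

    t1 = spec.rest_s + spec.transition_times_min[0] * 60.0
    t2 = spec.rest_s + spec.transition_times_min[1] * 60.0
    yawns = [(t1, 2.0), (t2, 2.2), (spec.rest_s + 300.0, 1.2), (t2 + 600.0, 1.0)]
    yawns = [(s, d) for s, d in yawns if s + d < spec.duration_s]
    yawns.sort()

    fisa = []
    for k in range(1, int(spec.drive_s // 600) + 1):
        t_min = (spec.rest_s + k * 600.0) / 60.0
        stage = _stage_at(spec, t_min * 60.0)
        score = FISA_BY_STAGE[stage]
        if stage == "NonF" and k == 1:
            score = 1
        if stage == "SevF" and t_min * 60.0 > t2 + 1200.0:
            score = 5
        fisa.append((t_min, score))
    return BehaviorStreams(eye, fs, yawns, fisa)


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise strictly confined to ``band`` (spectral synthesis).

    Brick-wall confinement keeps the programmed per-band variances from
    leaking into neighbouring bands, so Welch band powers of the generated
    signal match the schedule they are meant to encode.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f >= band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_kernel(fs: float) -> np.ndarray:
    t = np.arange(int(round(0.3 * fs))) / fs
    return np.exp(-0.5 * ((t - 0.15) / 0.06) ** 2)


def simulate_eeg(spec: ScenarioSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    fs = 250.0
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    out: dict[str, np.ndarray] = {}
    sd_profiles = {}
    for band in EEG_BANDS:
        variances = {s: spec.band_var_uv2[s][band] for s in STAGES}
        if band == "beta":
            variances = {s: v * spec.beta_var_scale for s, v in variances.items()}
        sd_profiles[band] = np.sqrt(_stage_profile(spec, variances, t))
    kernel = _blink_kernel(fs)
    blink_scale = {"Fp1": 1.0, "Fpz": 0.6, "Fp2": 1.0}
    for ch in EEG_CHANNELS:
        x = np.zeros(n)
        for band, (lo, hi) in EEG_BANDS.items():
            x += sd_profiles[band] * _band_limited_noise(rng, n, fs, (lo, hi))
        if spec.eeg_noise_sd_uv > 0:
            x += spec.eeg_noise_sd_uv * rng.standard_normal(n)
        for f0 in (12.5, 25.0, 37.5, 50.0):
            x += spec.crosstalk_amp_uv * np.sin(
                2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
            )
        n_blinks = rng.poisson(spec.ocular_rate_per_min * spec.duration_s / 60.0)
        starts = rng.integers(0, max(1, n - kernel.size), size=n_blinks)
        amps = rng.lognormal(np.log(spec.ocular_amp_uv), 0.3, size=n_blinks)
        for s0, a in zip(starts, amps):
            x[s0 : s0 + kernel.size] += blink_scale[ch] * a * kernel[: n - s0]
        out[ch] = x
    return out


def _beat_times(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = 0.1
    while t < spec.duration_s:
        times.append(t)
        stage = _stage_at(spec, t)
        ibi = spec.ibi_s[stage] + spec.jitter_scale * spec.ibi_jitter_s[
            stage
        ] * rng.standard_normal()
        t += max(0.4, ibi)
    return np.array(times)


def _pulse_wave(spec: ScenarioSpec, n: int, fs: float, beats: np.ndarray) -> np.ndarray:
    """Asymmetric (gamma-shaped) pressure wave train, unit peak amplitude.

    The kernel is evaluated analytically at each beat's fractional-sample
    offset so that programmed beat times are not quantized to the 12.5 Hz
    optical sampling grid.
    """
    a = 0.22  # smooth systolic upstroke/decay, as seen at the scalp
    width = 0.9
    x = np.zeros(n)
    for b in beats:
        i0 = max(0, int(np.ceil(b * fs)))
        i1 = min(n, int(np.floor((b + width) * fs)) + 1)
        if i0 >= i1:
            continue
        tau = np.arange(i0, i1) / fs - b
        wave = (tau / a) ** 2 * np.exp(2.0 - 2.0 * tau / a)
        x[i0:i1] += wave
    return x


@dataclass
class _FnirsParts:
    voltages: dict[tuple[str, int], np.ndarray]
    dark: dict[tuple[str, int], float]


def simulate_fnirs(spec: ScenarioSpec, rng: np.random.Generator) -> _FnirsParts:
    fs = 12.5
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    # cortical concentrations per location (zero during rest)
    hbo_prof = _stage_profile(
        spec, {s: spec.hbo_um[s] + spec.hemo_offset_um for s in STAGES}, t, True
    )
    hbr_prof = _stage_profile(
        spec, {s: spec.hbr_um[s] + 0.5 * spec.hemo_offset_um for s in STAGES}, t, True
    )
    brain_od: dict[str, np.ndarray] = {}
    for loc in LOCATION_PAIRS:
        brain_od[loc] = mbll_forward(hbo_prof, hbr_prof, RunConfig().optics, short=False)

    # superficial compartment per short-channel site: slow waves + pulse
    beats = _beat_times(spec, rng)
    pulse = _pulse_wave(spec, n, fs, beats)
    sup_od: dict[str, np.ndarray] = {}
    for ch in SHORT_CHANNELS:
        hbo_sup = (
            spec.mayer_amp_um * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
            + spec.resp_amp_um * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
            + spec.pulse_amp_hbo_um * pulse
        )
        hbr_sup = spec.superficial_hbr_ratio * (hbo_sup - spec.pulse_amp_hbo_um * pulse)
        hbr_sup = hbr_sup + spec.pulse_amp_hbr_um * pulse
        sup_od[ch] = mbll_forward(hbo_sup, hbr_sup, RunConfig().optics, short=True)

    # shared motion spikes (step + exponential decay) and per-channel drift
    n_spikes = rng.poisson(spec.motion_spike_rate_per_min * spec.duration_s / 60.0)
    spike_starts = rng.uniform(0, spec.duration_s, size=n_spikes)
    spike_signs = rng.choice([-1.0, 1.0], size=n_spikes)
    spike_common = np.zeros(n)
    for s0, sg in zip(spike_starts, spike_signs):
        i0 = int(s0 * fs)
        decay = np.exp(-(t[i0:] - t[i0]) / 3.0)
        spike_common[i0:] += sg * spec.motion_spike_amp_od * decay

    voltages: dict[tuple[str, int], np.ndarray] = {}
    dark: dict[tuple[str, int], float] = {}
    tn = t / t[-1]
    for ch in LONG_CHANNELS + SHORT_CHANNELS:
        is_short = ch in SHORT_CHANNELS
        v0 = 0.5 if is_short else 0.05
        for j, wl in enumerate(WAVELENGTHS):
            if is_short:
                od = sup_od[ch][:, j].copy()
            else:
                loc = next(L for L, pair in LOCATION_PAIRS.items() if ch in pair)
                s_src, s_det = LONG_TO_SHORTS[ch]
                od = (
                    brain_od[loc][:, j]
                    + spec.superficial_coupling * sup_od[s_src][:, j]
                    + spec.superficial_coupling * sup_od[s_det][:, j]
                )
            if spec.drift_od_amp > 0:
                c = rng.uniform(-1, 1, size=3) * spec.drift_od_amp
                od = od + c[0] * tn + c[1] * tn**2 + c[2] * tn**3
            ch_scale = rng.uniform(0.6, 1.0)
            od = od + ch_scale * spike_common
            noise_sd = spec.od_noise_sd_short if is_short else spec.od_noise_sd
            if noise_sd > 0:
                od = od + noise_sd * rng.standard_normal(n)
            d = 0.005
            voltages[(ch, wl)] = d + v0 * 10.0 ** (-od)
            dark[(ch, wl)] = d
    return _FnirsParts(voltages, dark)


def simulate_session(
    spec: ScenarioSpec, subject_id: str = "S01"
) -> tuple[MultimodalRecording, GroundTruth]:
    """Generate one full session; deterministic for a fixed spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    eeg = simulate_eeg(spec, np.random.default_rng(rng.integers(2**31)))
    fnirs = simulate_fnirs(spec, np.random.default_rng(rng.integers(2**31)))
    behavior = simulate_behavior(spec)
    rec = MultimodalRecording(
        subject_id=subject_id,
        paradigm=spec.paradigm,
        eeg=eeg,
        eeg_rate_hz=250.0,
        fnirs_voltages=fnirs.voltages,
        fnirs_rate_hz=12.5,
        dark_voltages=fnirs.dark,
        geometry_mm={ch: 30.0 for ch in LONG_CHANNELS}
        | {ch: 8.4 for ch in SHORT_CHANNELS},
        behavior=behavior,
        duration_s=spec.duration_s,
    )
    rec.validate()
    truth = GroundTruth(
        timeline=truth_timeline(spec),
        stage_band_sd_uv={
            s: {b: float(np.sqrt(v)) for b, v in spec.band_var_uv2[s].items()}
            for s in STAGES
        },
        stage_hbo_um=dict(spec.hbo_um),
        stage_hbr_um=dict(spec.hbr_um),
        stage_ibi_s=dict(spec.ibi_s),
        stage_ibi_jitter_s=dict(spec.ibi_jitter_s),
    )
    return rec, truth


def simulate_cohort(
    n_subjects: int,
    paradigm: str,
    seed: int = 0,
    effect_spec: dict | None = None,
) -> list[tuple[MultimodalRecording, GroundTruth]]:
    """Cohort with shared stage effects and per-subject random intercepts.

    ``effect_spec`` keys: ``zero_stage_effect`` (bool) flattens every stage
    schedule to its NonF value; ``sigma_hemo_um``, ``sigma_log_beta``,
    ``sigma_log_jitter`` set the between-subject spreads; any remaining key
    is forwarded as a scenario override.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    effect_spec = dict(effect_spec or {})
    zero_effect = effect_spec.pop("zero_stage_effect", False)
    sigma_hemo = effect_spec.pop("sigma_hemo_um", 0.10)
    sigma_log_beta = effect_spec.pop("sigma_log_beta", 0.06)
    sigma_log_jitter = effect_spec.pop("sigma_log_jitter", 0.10)
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        spec = make_scenario(paradigm, sub_seed, dict(effect_spec))
        if zero_effect:
            spec.band_var_uv2 = {s: dict(spec.band_var_uv2["NonF"]) for s in STAGES}
            spec.hbo_um = {s: spec.hbo_um["NonF"] for s in STAGES}
            spec.hbr_um = {s: spec.hbr_um["NonF"] for s in STAGES}
            spec.ibi_s = {s: spec.ibi_s["NonF"] for s in STAGES}
            spec.ibi_jitter_s = {s: spec.ibi_jitter_s["NonF"] for s in STAGES}
        spec.hemo_offset_um = float(rng.normal(0.0, sigma_hemo))
        spec.beta_var_scale = float(rng.lognormal(0.0, sigma_log_beta))
        spec.jitter_scale = float(rng.lognormal(0.0, sigma_log_jitter))
        rec, truth = simulate_session(spec, subject_id=f"P{i + 1:02d}")
        truth.subject_offsets = {
            "hemo_um": spec.hemo_offset_um,
            "log_beta": float(np.log(spec.beta_var_scale)),
            "log_jitter": float(np.log(spec.jitter_scale)),
        }
        out.append((rec, truth))
    return out


def simulate_feature_cohort(
    n_subjects: int,
    seed: int = 0,
    stage_effects: dict[str, float] | None = None,
    sigma_subject: float = 0.5,
    sigma_resid: float = 1.0,
    windows_per_subject: int = 160,
    stage_fractions: tuple[float, float, float] = (0.45, 0.25, 0.30),
) -> pd.DataFrame:
    """Window-level feature draws from the mixed model's assumed structure.

    y = stage effect + subject intercept + iid noise, with the realistic
    per-session window count and stage split.  Used for statistical
    calibration, where regenerating full multimodal cohorts per replicate
    would be pointless: the quantity under test is the model fit.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    stage_effects = stage_effects or {s: 0.0 for s in STAGES}
    rng = np.random.default_rng(seed)
    n_per_stage = [int(round(f * windows_per_subject)) for f in stage_fractions]
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0.0, sigma_subject)
        for stage, n_s in zip(STAGES, n_per_stage):
            y = stage_effects[stage] + b + rng.normal(0.0, sigma_resid, size=n_s)
            for v in y:
                rows.append({"y": v, "stage": stage, "subject": f"P{i + 1:02d}"})
    return pd.DataFrame(rows)
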