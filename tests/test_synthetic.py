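"""Generator contracts: determinism, invariants, scheduled effects."""
import numpy as np
import pytest

from fatigue3.config import STAGES
from fatigue3.eeg import band_powers
from fatigue3.labeling import compute_perclos
from fatigue3.synthetic import (
    TRANSITION_PRIORS,
    make_scenario,
    simulate_behavior,
    simulate_cohort,
    simulate_session,
    truth_timeline,
)


def test_make_scenario_deterministic():
    a = make_scenario("active", seed=1)
    b = make_scenario("active", seed=1)
    assert a == b
    c = make_scenario("active", seed=2)
    assert c.transition_times_min != a.transition_times_min


def test_scenario_transition_prior():
    """Drawn transition times scatter around the paradigm's schedule."""
    (m1, _), (m2, _) = TRANSITION_PRIORS["active"]
    t1s, t2s = zip(
        *(make_scenario("active", seed=s).transition_times_min for s in range(60))
    )
    assert abs(np.mean(t1s) - m1) < 5.0
    assert abs(np.mean(t2s) - m2) < 6.0
    assert all(t1 < t2 for t1, t2 in zip(t1s, t2s))


def test_scenario_invalid_overrides_fatal():
    with pytest.raises(ValueError):
        make_scenario("active", seed=1, overrides=dict(transition_times_min=(50.0, 20.0)))
    with pytest.raises(ValueError):
        make_scenario("active", seed=1, overrides=dict(no_such_field=1))
    with pytest.raises(ValueError):
        make_scenario("sleepy", seed=1)
    with pytest.raises(ValueError):
        make_scenario(
            "active", seed=1,
            overrides=dict(ibi_s={"NonF": 0.1, "ModF": 0.9, "SevF": 0.9}),
        )


def test_session_satisfies_recording_invariants(active_session):
    rec, truth, spec = active_session
    rec.validate()  # raises on violation
    truth.timeline.validate(60.0, 4860.0)
    # voltages stay above dark on essentially all samples
    for key, v in rec.fnirs_voltages.items():
        frac = np.mean(v > rec.dark_voltages[key])
        assert frac >= 0.99


def test_session_seed_determinism():
    spec = make_scenario("active", seed=42, overrides=dict(drive_s=720.0, transition_times_min=(4.0, 8.0)))
    r1, _ = simulate_session(spec)
    r2, _ = simulate_session(spec)
    assert np.array_equal(r1.eeg["Fp1"], r2.eeg["Fp1"])
    key = ("S1D1", 805)
    assert np.array_equal(r1.fnirs_voltages[key], r2.fnirs_voltages[key])
    assert np.array_equal(r1.behavior.eye_state, r2.behavior.eye_state)


def test_behavior_perclos_steps_at_transitions():
    spec = make_scenario("active", seed=3)
    b = simulate_behavior(spec)
    vals, times = compute_perclos(b.eye_state, b.eye_rate_hz)
    t1 = spec.rest_s + spec.transition_times_min[0] * 60.0
    before = vals[(times > t1 - 300) & (times < t1 - 8)]
    after = vals[(times > t1 + 8) & (times < t1 + 300)]
    assert np.median(before) == pytest.approx(spec.perclos["NonF"], abs=0.01)
    assert np.median(after) == pytest.approx(spec.perclos["ModF"], abs=0.01)
    # yawns mark the upward transitions
    starts = [s for s, d in b.yawns if d > 1.5]
    assert any(abs(s - t1) < 1e-6 for s in starts)


def test_fisa_consistent_with_truth():
    spec = make_scenario("passive", seed=9)
    b = simulate_behavior(spec)
    tl = truth_timeline(spec)
    mapping = {"NonF": (1, 2), "ModF": (3,), "SevF": (4, 5)}
    for t_min, score in b.fisa:
        stage = tl.label_at(t_min * 60.0)
        assert score in mapping[stage]


def test_beta_variance_doubling_shows_in_welch():
    """Doubling the scheduled beta variance doubles measured beta power."""
    var = {
        "NonF": {"delta": 5.0, "theta": 5.0, "alpha": 5.0, "beta": 10.0},
        "ModF": {"delta": 5.0, "theta": 5.0, "alpha": 5.0, "beta": 20.0},
        "SevF": {"delta": 5.0, "theta": 5.0, "alpha": 5.0, "beta": 20.0},
    }
    spec = make_scenario(
        "active", seed=21,
        overrides=dict(
            band_var_uv2=var, transition_times_min=(30.0, 60.0),
            ocular_rate_per_min=0.0, crosstalk_amp_uv=0.0, eeg_noise_sd_uv=0.0,
        ),
    )
    rec, _ = simulate_session(spec)
    fs = 250.0
    t1 = 60.0 + 30 * 60.0
    pre = []
    post = []
    for k in range(10):
        s_pre = int((t1 - 420 + 30 * k) * fs)
        s_post = int((t1 + 120 + 30 * k) * fs)
        pre.append(band_powers(rec.eeg["Fp1"][s_pre : s_pre + int(30 * fs)]).beta)
        post.append(band_powers(rec.eeg["Fp1"][s_post : s_post + int(30 * fs)]).beta)
    assert np.mean(post) / np.mean(pre) == pytest.approx(2.0, rel=0.10)


def test_pulse_ibi_matches_programmed_mean():
    """Zero jitter: detected inter-beat interval equals the schedule."""
    from fatigue3.fnirs import to_optical_density
    from fatigue3.prv import clean_ibi, detect_peaks_ampd, extract_pulse

    spec = make_scenario(
        "active", seed=22,
        overrides=dict(
            ibi_s={s: 1.0 for s in STAGES},
            ibi_jitter_s={s: 0.0 for s in STAGES},
            mayer_amp_um=0.0, resp_amp_um=0.0,
            od_noise_sd=0.0, od_noise_sd_short=0.0,
            motion_spike_rate_per_min=0.0, drift_od_amp=0.0,
        ),
    )
    rec, _ = simulate_session(spec)
    od = {
        key: to_optical_density(v, rec.dark_voltages[key])
        for key, v in rec.fnirs_voltages.items()
        if key[0] == "S1D1"
    }
    hbo_p, _ = extract_pulse(od)["S1D1"]
    fs = 12.5
    seg = hbo_p[int(1000 * fs) : int(1030 * fs)]
    peaks = detect_peaks_ampd(seg, fs)
    ibi = clean_ibi(peaks)
    assert ibi is not None
    assert ibi.mean_ibi == pytest.approx(1.0, abs=0.02)


def test_cohort_requirements_and_determinism():
    with pytest.raises(ValueError):
        simulate_cohort(1, "active", seed=0)

    kw = dict(drive_s=720.0, transition_times_min=(4.0, 8.0))
    a = simulate_cohort(2, "active", seed=5, effect_spec=kw)
    b = simulate_cohort(2, "active", seed=5, effect_spec=kw)
    assert [r.subject_id for r, _ in a] == ["P01", "P02"]
    assert np.array_equal(a[0][0].eeg["Fpz"], b[0][0].eeg["Fpz"])
    assert not np.array_equal(a[0][0].eeg["Fpz"], a[1][0].eeg["Fpz"])


def test_cohort_zero_sigma_shares_stage_means():
    kw = dict(drive_s=720.0, transition_times_min=(4.0, 8.0))
    cohort = simulate_cohort(
        2, "active", seed=5,
        effect_spec=dict(kw, sigma_hemo_um=0.0, sigma_log_beta=0.0, sigma_log_jitter=0.0),
    )
    (r1, t1), (r2, t2) = cohort
    assert t1.stage_hbo_um == t2.stage_hbo_um
    assert t1.subject_offsets["hemo_um"] == 0.0 == t2.subject_offsets["hemo_um"]


def test_feature_cohort_null_distribution():
    from fatigue3.synthetic import simulate_feature_cohort

    df = simulate_feature_cohort(11, seed=0)
    assert df["subject"].nunique() == 11
    assert set(df["stage"]) == set(STAGES)
    # realistic per-session window counts
    per = df.groupby("subject").size().unique()
    assert len(per) == 1 and 150 <= per[0] <= 170
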