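"""Optical density, motion correction, short-channel regression and MBLL."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatigue3.config import FNIRSConfig, OpticsConfig, RunConfig
from fatigue3.fnirs import (
    correct_motion,
    detrend_poly3,
    hemo_feature_table,
    normalize_features,
    pair_locations,
    quality_screen,
    short_channel_denoise,
    to_optical_density,
)
from fatigue3.optics import derive_hbt_coe, mbll_forward, mbll_inverse

FS = 12.5
CFG = FNIRSConfig()
OPT = OpticsConfig()


# ------------------------------------------------------------- optical density

def test_od_zero_at_baseline():
    v = np.full(1000, 0.5)
    od = to_optical_density(v, dark=0.01, rate_hz=FS)
    assert np.allclose(od, 0.0)


def test_od_decade_and_doubling():
    v = np.full(1000, 0.51)
    v[100:] = 0.01 + (0.51 - 0.01) / 10  # corrected voltage drops a decade
    od = to_optical_density(v, dark=0.01, rate_hz=FS)
    assert od[500] == pytest.approx(1.0, abs=1e-12)

    v = np.full(1000, 0.51)
    v[100:] = 0.01 + 2 * (0.51 - 0.01)
    od = to_optical_density(v, dark=0.01, rate_hz=FS)
    assert od[500] == pytest.approx(-np.log10(2.0), abs=1e-9)


def test_od_masks_nonpositive_voltage():
    v = np.full(1000, 0.5)
    v[200] = 0.005  # below the dark voltage
    with pytest.warns(UserWarning):
        od = to_optical_density(v, dark=0.01, rate_hz=FS)
    assert np.isnan(od[200]) and np.isfinite(od[199])


# -------------------------------------------------------------- quality screen

def _pulse_od(n, rng=None, f=1.2):
    t = np.arange(n) / FS
    x = 0.004 * np.sin(2 * np.pi * f * t)
    if rng is not None:
        x = x + 1e-4 * rng.standard_normal(n)
    return x


def test_quality_screen_clean_channel_empty_mask(rng):
    od = _pulse_od(int(120 * FS), rng)
    assert not quality_screen(od, CFG).any()


def test_quality_screen_flags_saturation_plateau(rng):
    od = _pulse_od(int(120 * FS), rng)
    od[500:540] = od[500]  # frozen samples: saturated detector
    mask = quality_screen(od, CFG)
    assert mask[505:535].all()
    assert not mask[: int(30 * FS)].any()


def test_quality_screen_flags_cardiac_free_windows():
    t = np.arange(int(90 * FS)) / FS
    od = 0.01 * np.sin(2 * np.pi * 0.05 * t)  # slow drift only, no pulse
    mask = quality_screen(od, CFG)
    assert mask[: int(30 * FS) * 3].all()


# ------------------------------------------------------------ motion correction

def test_motion_correction_attenuates_step_decay(rng):
    n = int(240 * FS)
    t = np.arange(n) / FS
    clean = 0.004 * np.sin(2 * np.pi * 1.2 * t) + 2e-4 * rng.standard_normal(n)
    artifact = np.zeros(n)
    i0 = n // 2
    artifact[i0:] = 0.08 * np.exp(-(t[i0:] - t[i0]) / 2.0)
    out = correct_motion(clean + artifact, CFG)
    epoch = slice(i0, i0 + int(5 * FS))
    before = np.sqrt(np.mean((clean + artifact)[epoch] ** 2))
    after = np.sqrt(np.mean((out - clean)[epoch] ** 2 + 1e-30))
    assert after <= 0.3 * before


def test_motion_correction_spares_clean_series(rng):
    n = int(240 * FS)
    t = np.arange(n) / FS
    clean = 0.004 * np.sin(2 * np.pi * 1.2 * t) + 2e-4 * rng.standard_normal(n)
    out = correct_motion(clean, CFG)
    assert np.corrcoef(clean, out)[0, 1] >= 0.98


def test_motion_correction_zero_in_zero_out():
    assert np.all(correct_motion(np.zeros(1000), CFG) == 0)


# ------------------------------------------------------------------- detrending

def test_detrend_annihilates_cubic():
    t = np.linspace(0, 1, 2000)
    x = 0.3 - 0.2 * t + 0.5 * t**2 - 0.1 * t**3
    out = detrend_poly3(x)
    assert np.linalg.norm(out) < 1e-9 * np.linalg.norm(x)


def test_detrend_preserves_oscillation():
    t = np.arange(int(300 * FS)) / FS
    sine = 0.01 * np.sin(2 * np.pi * 1.0 * t)
    cubic = 1e-8 * (t - t.mean()) ** 3
    out = detrend_poly3(sine + cubic)
    assert np.std(out) == pytest.approx(np.std(sine), rel=0.02)


def test_detrend_constant_to_zero():
    assert np.allclose(detrend_poly3(np.full(100, 3.14)), 0.0, atol=1e-12)


# -------------------------------------------------- short-channel regression

def test_denoise_annihilates_in_span(rng):
    src = rng.standard_normal(5000)
    det = rng.standard_normal(5000)
    long = 0.7 * src + 0.3 * det
    resid = short_channel_denoise(long, src, det)
    assert np.linalg.norm(resid) < 1e-10


def test_denoise_identity_when_orthogonal():
    n = 5000
    t = np.arange(n)
    long = np.sin(2 * np.pi * t / 50)
    src = np.sin(2 * np.pi * t / 50 + np.pi / 2)  # quadrature: zero covariance
    det = np.sin(2 * np.pi * t / 25)
    resid = short_channel_denoise(long, src, det)
    assert np.allclose(resid, long, atol=1e-8)


def test_denoise_recovers_neural_component(rng):
    n = 10000
    neural = np.cumsum(rng.standard_normal(n)) * 0.01
    neural -= neural.mean()
    superficial = np.sin(2 * np.pi * 0.1 * np.arange(n) / FS)
    long = neural + 0.8 * superficial
    src = superficial + 0.05 * rng.standard_normal(n)
    det = superficial + 0.05 * rng.standard_normal(n)
    resid = short_channel_denoise(long, src, det)
    assert np.corrcoef(resid, neural)[0, 1] >= 0.95


def test_denoise_drops_null_regressor(rng):
    long = rng.standard_normal(1000)
    src = np.zeros(1000)
    det = rng.standard_normal(1000)
    with pytest.warns(UserWarning):
        resid = short_channel_denoise(long, src, det)
    assert np.linalg.norm(resid) <= np.linalg.norm(long) + 1e-12


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_denoise_projection_contract(seed):
    r = np.random.default_rng(seed)
    long = r.standard_normal(500)
    src = r.standard_normal(500)
    det = r.standard_normal(500)
    resid = short_channel_denoise(long, src, det)
    assert np.linalg.norm(resid) <= np.linalg.norm(long) + 1e-9


# ------------------------------------------------------------------------ MBLL

def test_mbll_zero_to_zero():
    hbo, hbr = mbll_inverse(np.zeros((100, 3)), OPT)
    assert np.all(hbo == 0) and np.all(hbr == 0)


def test_mbll_forward_inverse_exact(rng):
    hbo = rng.normal(0, 1.0, 500)
    hbr = rng.normal(0, 0.5, 500)
    od = mbll_forward(hbo, hbr, OPT)
    got_o, got_r = mbll_inverse(od, OPT)
    assert np.max(np.abs(got_o - hbo)) < 1e-9
    assert np.max(np.abs(got_r - hbr)) < 1e-9


def test_mbll_noise_propagation_matches_ls_covariance(rng):
    """Monte-Carlo recovery error vs the closed-form least-squares variance."""
    sigma = 0.001
    n = 4000
    od = mbll_forward(np.zeros(n), np.zeros(n), OPT)
    od = od + sigma * rng.standard_normal((n, 3))
    hbo, hbr = mbll_inverse(od, OPT)
    from fatigue3.optics import extinction_matrix, pathlengths_cm

    E = extinction_matrix(OPT)
    L = pathlengths_cm(OPT)
    # od/L has per-component noise sigma/L; cov(c) = (E E^T)^-1 scaled
    A = np.linalg.pinv(E)  # 3x2
    cov = (sigma / L[0]) ** 2 * (A.T @ A) * 1e6  # umol/L scale
    assert np.var(hbo) == pytest.approx(cov[0, 0], rel=0.15)
    assert np.var(hbr) == pytest.approx(cov[1, 1], rel=0.15)


def test_hbt_coe_identities(rng):
    hbt, coe = derive_hbt_coe(np.array([2.0]), np.array([-1.0]))
    assert hbt[0] == 1.0 and coe[0] == -3.0
    hbt, coe = derive_hbt_coe(np.zeros(5), np.zeros(5))
    assert np.all(hbt == 0) and np.all(coe == 0)
    hbo = rng.standard_normal(100)
    hbr = rng.standard_normal(100)
    hbt, coe = derive_hbt_coe(hbo, hbr)
    assert np.allclose(hbt + coe, 2 * hbr, atol=1e-12)


# ------------------------------------------------------- pairing and features

def test_pair_locations_rules(rng):
    a = rng.standard_normal(100)
    same = pair_locations({"S1D2": a, "S2D1": a.copy()})
    assert np.allclose(same["Fp1"], a)

    const = pair_locations({"S1D2": np.full(10, 1.0), "S2D1": np.full(10, 3.0)})
    assert np.allclose(const["Fp1"], 2.0)

    with pytest.warns(UserWarning):
        partial = pair_locations({"S2D3": np.full(10, np.nan), "S3D2": np.full(10, 5.0)})
    assert np.allclose(partial["Fpz"], 5.0)


def test_normalization_endpoints_and_clipping(rng):
    x = rng.standard_normal(500)
    out = normalize_features(x, (5.0, 95.0), (-1.0, 1.0))
    p5, p95 = np.percentile(x, [5, 95])
    i5 = int(np.argmin(np.abs(x - p5)))
    i95 = int(np.argmin(np.abs(x - p95)))
    assert out[i5] == pytest.approx(-1.0, abs=0.02)
    assert out[i95] == pytest.approx(1.0, abs=0.02)
    assert out.min() >= -1.0 and out.max() <= 1.0
    beyond = np.argmax(x)  # beyond p95 -> clipped to +1
    assert out[beyond] == 1.0


def test_normalization_degenerate_spread():
    with pytest.warns(UserWarning):
        out = normalize_features(np.full(20, 7.0), (5.0, 95.0), (-1.0, 1.0))
    assert np.allclose(out, 0.0)


def test_hemo_feature_table_constant_window(config):
    from fatigue3.types import Interval, StageTimeline

    tl = StageTimeline([Interval(60.0, 4860.0, "NonF")])
    n = int(4860 * FS)
    series = {
        f: {loc: np.full(n, c) for loc, c in (("Fp1", 1.0), ("Fpz", 2.0), ("Fp2", 3.0))}
        for f in ("hbo", "hbr", "hbt", "coe")
    }
    df = hemo_feature_table(series, tl, config)
    assert len(df) == 160
    assert np.allclose(df["m_hbo_fp1"], 1.0)
    assert np.allclose(df["m_hbo_chavg"], 2.0)
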