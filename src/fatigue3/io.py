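"""Reading and writing sessions, feature tables, timelines and results.

The canonical on-disk session layout is a directory of plain-text files:

    meta.json      subject, paradigm, rates, dark voltages, geometry
    eeg.csv        Fp1,Fpz,Fp2 columns in microvolts (or eeg.edf)
    fnirs.csv      one column per channel_wavelength, detector volts
    fisa.csv       time_min,score
    eyestate.csv   time_s,closed
    yawns.csv      start_s,duration_s

EDF (EEG) and SNIRF (fNIRS) containers are supported alongside: EDF via a
minimal EDF+ writer and mne's reader, SNIRF directly on HDF5 via h5py.
Feature tables are tab-separated with "NA" for missing cells, printed at
12 significant digits so that write -> read inverts at print precision.
"""
from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    EEG_CHANNELS,
    LONG_CHANNELS,
    SHORT_CHANNELS,
    WAVELENGTHS,
)
from .types import (
    BehaviorStreams,
    Interval,
    MultimodalRecording,
    StageTimeline,
    TransitionPoint,
)

logger = logging.getLogger("fatigue3")

ALL_CHANNELS = LONG_CHANNELS + SHORT_CHANNELS
ID_COLUMNS = ("subject", "paradigm", "window_mid_s", "stage")
_FEATURE_COL_RE = re.compile(
    r"^(rpl_(delta|theta|alpha|beta)|eta|m_(hbo|hbr|hbt|coe))_"
    r"(fp1|fpz|fp2|chavg)(_norm)?$|^(sdnn|rmssd|n_ibi)(_norm)?$"
)


def log_stage(stage: str, **counts) -> None:
    """One structured log line per pipeline stage."""
    payload = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, payload)


def _hash_array(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()[:12]


# ---------------------------------------------------------------- sessions

def write_session(rec: MultimodalRecording, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write a session directory; ``fmt`` picks csv, edf+csv or snirf+csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": rec.subject_id,
        "paradigm": rec.paradigm,
        "eeg_rate_hz": rec.eeg_rate_hz,
        "fnirs_rate_hz": rec.fnirs_rate_hz,
        "eye_rate_hz": rec.behavior.eye_rate_hz,
        "duration_s": rec.duration_s,
        "dark_voltages": {f"{ch}@{wl}": v for (ch, wl), v in rec.dark_voltages.items()},
        "geometry_mm": rec.geometry_mm,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    eeg = pd.DataFrame({ch: rec.eeg[ch] for ch in EEG_CHANNELS})
    if fmt == "edf":
        write_edf(out / "eeg.edf", rec.eeg, rec.eeg_rate_hz)
    else:
        eeg.to_csv(out / "eeg.csv", index=False, float_format="%.17g")

    if fmt == "snirf":
        write_snirf(out / "fnirs.snirf", rec)
    else:
        nirs = pd.DataFrame(
            {f"{ch}_{wl}": rec.fnirs_voltages[(ch, wl)] for ch in ALL_CHANNELS for wl in WAVELENGTHS}
        )
        nirs.to_csv(out / "fnirs.csv", index=False, float_format="%.17g")

    b = rec.behavior
    pd.DataFrame({"time_min": [t for t, _ in b.fisa], "score": [s for _, s in b.fisa]}).to_csv(
        out / "fisa.csv", index=False, float_format="%.17g"
    )
    t = np.arange(b.eye_state.size) / b.eye_rate_hz
    pd.DataFrame({"time_s": t, "closed": b.eye_state.astype(int)}).to_csv(
        out / "eyestate.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {"start_s": [s for s, _ in b.yawns], "duration_s": [d for _, d in b.yawns]}
    ).to_csv(out / "yawns.csv", index=False, float_format="%.17g")
    log_stage("write_session", path=str(out), fmt=fmt, eeg_hash=_hash_array(eeg.to_numpy()))
    return out


def load_recording(session_dir: str | Path) -> MultimodalRecording:
    """Load and validate a session directory in any supported layout."""
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())

    if (d / "eeg.edf").exists():
        eeg, rate = read_edf(d / "eeg.edf")
        if abs(rate - meta["eeg_rate_hz"]) / meta["eeg_rate_hz"] > 0.01:
            raise ValueError("EEG rate mismatch exceeds 1%")
    else:
        df = pd.read_csv(d / "eeg.csv", float_precision="round_trip")
        for ch in EEG_CHANNELS:
            if ch not in df.columns:
                raise ValueError(f"missing EEG channel {ch}")
        eeg = {ch: df[ch].to_numpy(float) for ch in EEG_CHANNELS}

    if (d / "fnirs.snirf").exists():
        voltages = read_snirf(d / "fnirs.snirf")
    else:
        df = pd.read_csv(d / "fnirs.csv", float_precision="round_trip")
        voltages = {}
        for ch in ALL_CHANNELS:
            for wl in WAVELENGTHS:
                col = f"{ch}_{wl}"
                if col not in df.columns:
                    raise ValueError(f"missing fNIRS channel {ch} (column {col})")
                voltages[(ch, wl)] = df[col].to_numpy(float)

    dark = {}
    for key, v in meta["dark_voltages"].items():
        ch, wl = key.split("@")
        dark[(ch, int(wl))] = float(v)

    fisa_df = pd.read_csv(d / "fisa.csv", float_precision="round_trip")
    eye_df = pd.read_csv(d / "eyestate.csv", float_precision="round_trip")
    yawn_df = pd.read_csv(d / "yawns.csv", float_precision="round_trip")
    expected_eye = int(round(meta["duration_s"] * meta["eye_rate_hz"]))
    eye = eye_df["closed"].to_numpy(float)
    if eye.size < expected_eye:
        logger.warning(
            "truncated eye-state stream (%d of %d samples); trailing gap masked",
            eye.size, expected_eye,
        )
    behavior = BehaviorStreams(
        eye_state=eye,
        eye_rate_hz=float(meta["eye_rate_hz"]),
        yawns=list(zip(yawn_df["start_s"], yawn_df["duration_s"])),
        fisa=[(float(t), int(s)) for t, s in zip(fisa_df["time_min"], fisa_df["score"])],
    )
    rec = MultimodalRecording(
        subject_id=meta["subject_id"],
        paradigm=meta["paradigm"],
        eeg=eeg,
        eeg_rate_hz=float(meta["eeg_rate_hz"]),
        fnirs_voltages=voltages,
        fnirs_rate_hz=float(meta["fnirs_rate_hz"]),
        dark_voltages=dark,
        geometry_mm={k: float(v) for k, v in meta["geometry_mm"].items()},
        behavior=behavior,
        duration_s=float(meta["duration_s"]),
    )
    rec.validate()
    log_stage("load_recording", path=str(d), subject=rec.subject_id)
    return rec


# ------------------------------------------------------------- EDF writer

def write_edf(path: str | Path, eeg: dict[str, np.ndarray], rate_hz: float) -> None:
    """Minimal EDF writer: int16 records of one second, physical units uV."""
    chans = list(EEG_CHANNELS)
    ns = len(chans)
    spr = int(round(rate_hz))
    n = min(len(eeg[ch]) for ch in chans)
    n_rec = n // spr
    data = np.stack([np.asarray(eeg[ch][: n_rec * spr], float) for ch in chans])
    pmin = float(min(-1.0, data.min()))
    pmax = float(max(1.0, data.max()))
    dmin, dmax = -32768, 32767
    scaled = (data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    digital = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        ("".join(c.ljust(16)[:16] for c in chans), 16),
        ("".join("AgAgCl".ljust(80) for _ in chans), 80),
        ("".join("uV".ljust(8) for _ in chans), 8),
        ("".join(f"{pmin:.8g}"[:8].ljust(8) for _ in chans), 8),
        ("".join(f"{pmax:.8g}"[:8].ljust(8) for _ in chans), 8),
        ("".join(str(dmin).ljust(8) for _ in chans), 8),
        ("".join(str(dmax).ljust(8) for _ in chans), 8),
        ("".join("".ljust(80) for _ in chans), 80),
        ("".join(str(spr).ljust(8) for _ in chans), 8),
        ("".join("".ljust(32) for _ in chans), 32),
    ]
    sig_header = b"".join(f.encode("ascii") for f, _ in fields)
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read EEG channels from EDF using mne's native reader."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    out = {}
    for ch in EEG_CHANNELS:
        if ch not in raw.ch_names:
            raise ValueError(f"missing EEG channel {ch}")
        out[ch] = raw.get_data(picks=[ch])[0] * 1e6  # mne loads volts
    return out, rate


# ------------------------------------------------------------ SNIRF (h5py)

def write_snirf(path: str | Path, rec: MultimodalRecording) -> None:
    """Write raw intensities into the standard SNIRF HDF5 layout."""
    import h5py

    keys = [(ch, wl) for ch in ALL_CHANNELS for wl in WAVELENGTHS]
    n = min(len(rec.fnirs_voltages[k]) for k in keys)
    data = np.stack([rec.fnirs_voltages[k][:n] for k in keys], axis=1)
    src_of = lambda ch: int(ch[1])
    det_of = lambda ch: int(ch[3])
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(n) / rec.fnirs_rate_hz)
        for i, (ch, wl) in enumerate(keys, start=1):
            ml = d1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=src_of(ch))
            ml.create_dataset("detectorIndex", data=det_of(ch))
            ml.create_dataset("wavelengthIndex", data=WAVELENGTHS.index(wl) + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(WAVELENGTHS, float))
        probe.create_dataset("sourcePos3D", data=np.zeros((4, 3)))
        probe.create_dataset("detectorPos3D", data=np.zeros((4, 3)))


def read_snirf(path: str | Path) -> dict[tuple[str, int], np.ndarray]:
    """Read raw intensities back out of a SNIRF file."""
    import h5py

    out: dict[tuple[str, int], np.ndarray] = {}
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"])
        wavelengths = [int(round(w)) for w in np.asarray(f["nirs/probe/wavelengths"])]
        i = 1
        while f"measurementList{i}" in d1:
            ml = d1[f"measurementList{i}"]
            ch = f"S{int(ml['sourceIndex'][()])}D{int(ml['detectorIndex'][()])}"
            wl = wavelengths[int(ml["wavelengthIndex"][()]) - 1]
            out[(ch, wl)] = data[:, i - 1]
            i += 1
    return out


# ---------------------------------------------------------- feature tables

def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """TSV with stable column order and "NA" missing cells, 12 sig digits."""
    cols = [c for c in ID_COLUMNS if c in table.columns]
    feat = sorted(c for c in table.columns if c not in cols)
    out = table[cols + feat]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
    log_stage("write_feature_table", path=str(path), rows=len(out))
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature TSV back, rejecting unknown columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    for col in df.columns:
        if col in ID_COLUMNS:
            continue
        if not _FEATURE_COL_RE.match(col):
            raise ValueError(f"unknown feature column {col!r}")
    return df


# --------------------------------------------------------------- timelines

def timeline_to_json(tl: StageTimeline) -> dict:
    return {
        "intervals": [
            {"start_s": i.start_s, "end_s": i.end_s, "label": i.label}
            for i in tl.intervals
        ],
        "transitions": [
            {
                "time_s": t.time_s,
                "direction": t.direction,
                "evidence": t.evidence,
                "low_confidence": t.low_confidence,
            }
            for t in tl.transitions
        ],
    }


def timeline_from_json(data: dict) -> StageTimeline:
    return StageTimeline(
        [Interval(i["start_s"], i["end_s"], i["label"]) for i in data["intervals"]],
        [
            TransitionPoint(
                t["time_s"], t["direction"], t["evidence"], t.get("low_confidence", False)
            )
            for t in data["transitions"]
        ],
    )


def write_timeline(tl: StageTimeline, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(timeline_to_json(tl), indent=1))
    return Path(path)


def read_timeline(path: str | Path) -> StageTimeline:
    return timeline_from_json(json.loads(Path(path).read_text()))
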