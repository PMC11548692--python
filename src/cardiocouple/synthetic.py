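"""Seeded synthetic paired ECG/PCG generator with controllable class structure.

Real CAD recordings are private clinical data, so every pipeline stage is
exercised on synthetic pairs that emulate the class differences the method
exploits:

  * ECG: per-beat Gaussian-bump PQRST morphology at jittered RR intervals;
    the CAD class adds an ST-segment elevation (``st_shift``, in units of the
    clean signal's standard deviation) between the S and T waves.
  * PCG: a damped 30-80 Hz S1 oscillation at each R peak and a 50-120 Hz S2
    burst near the end of the T wave (at R + 0.35 RR); the CAD class adds
    band-limited (150-400 Hz) diastolic murmur noise of amplitude
    ``murmur_gain`` — the high-frequency turbulence signature of a narrowed
    coronary artery.
  * Both channels carry white noise and a 50 Hz mains sinusoid so the
    denoising filters have real work to do.

Everything is driven by a single seed; identical configs give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import PairedRecord


@dataclass
class SynthConfig:
    n_per_class: int = 20
    duration_s: float = 300.0  # matches the 5-min clinical recordings
    fs: float = 1000.0
    heart_rate_mean: float = 72.0  # bpm, between-subject mean
    heart_rate_sd: float = 8.0  # bpm, between-subject spread
    rr_jitter: float = 0.03  # within-subject relative RR variability
    st_shift: float = 2.0  # class-1 ST elevation in clean-signal-sd units
    murmur_gain: float = 1.5  # class-1 diastolic murmur amplitude
    mains_amp: float = 0.1  # 50 Hz interference amplitude
    mains_hz: float = 50.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 200:
            raise ValueError("fs must be >= 200")
        if self.duration_s < 10:
            raise ValueError("duration_s must be >= 10")
        for name in ("st_shift", "murmur_gain", "mains_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# PQRST bumps: (offset from R in s, amplitude, width in s)
_ECG_WAVES = (
    (-0.20, 0.15, 0.025),  # P
    (-0.030, -0.10, 0.010),  # Q
    (0.0, 1.00, 0.012),  # R
    (0.030, -0.15, 0.010),  # S
    (0.30, 0.30, 0.050),  # T
)
_ST_WINDOW = (0.06, 0.24)  # plateau between S end and T start, s after R


def _beat_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject R-peak times with optional beat-to-beat jitter."""
    hr = cfg.heart_rate_mean + cfg.heart_rate_sd * rng.standard_normal()
    hr = float(np.clip(hr, 40.0, 150.0))
    rr = 60.0 / hr
    times = []
    t = 0.25 * rr
    while t < cfg.duration_s + rr:
        times.append(t)
        t += rr * (1.0 + cfg.rr_jitter * rng.standard_normal())
    return np.array(times)


def synth_ecg(
    cfg: SynthConfig, rng: np.random.Generator, label: int, beat_times: np.ndarray
) -> np.ndarray:
    """Template-bump ECG trace; class 1 gets the ST plateau elevation."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    clean = np.zeros(n)
    for bt in beat_times:
        for off, amp, width in _ECG_WAVES:
            center = bt + off
            lo = int(max(0, (center - 5 * width) * cfg.fs))
            hi = int(min(n, (center + 5 * width) * cfg.fs))
            if hi > lo:
                clean[lo:hi] += amp * np.exp(
                    -0.5 * ((t[lo:hi] - center) / width) ** 2
                )
    baseline_sd = clean.std()
    if label == 1 and cfg.st_shift > 0:
        for bt in beat_times:
            lo = int((bt + _ST_WINDOW[0]) * cfg.fs)
            hi = int((bt + _ST_WINDOW[1]) * cfg.fs)
            lo, hi = max(0, lo), min(n, hi)
            clean[lo:hi] += cfg.st_shift * baseline_sd
    noise = cfg.noise_sd * rng.standard_normal(n)
    mains = cfg.mains_amp * np.sin(2 * np.pi * cfg.mains_hz * t)
    return clean + noise + mains


def _burst(t_local: np.ndarray, freq: float, decay_s: float) -> np.ndarray:
    return np.sin(2 * np.pi * freq * t_local) * np.exp(-t_local / decay_s)


def synth_pcg(
    cfg: SynthConfig, rng: np.random.Generator, label: int, beat_times: np.ndarray
) -> np.ndarray:
    """Heart-sound trace locked to the ECG beat times."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    pcg = np.zeros(n)
    rrs = np.diff(beat_times)
    rr_med = float(np.median(rrs)) if len(rrs) else 60.0 / cfg.heart_rate_mean
    s1_len = int(0.10 * cfg.fs)
    s2_len = int(0.08 * cfg.fs)
    tl1 = np.arange(s1_len) / cfg.fs
    tl2 = np.arange(s2_len) / cfg.fs
    for i, bt in enumerate(beat_times):
        rr = rrs[i] if i < len(rrs) else rr_med
        lo = int(bt * cfg.fs)
        if lo < n:
            hi = min(n, lo + s1_len)
            pcg[lo:hi] += 1.0 * _burst(tl1[: hi - lo], 50.0, 0.02)  # S1, 30-80 Hz band
        lo2 = int((bt + 0.35 * rr) * cfg.fs)
        if 0 <= lo2 < n:
            hi2 = min(n, lo2 + s2_len)
            pcg[lo2:hi2] += 0.7 * _burst(tl2[: hi2 - lo2], 90.0, 0.015)  # S2
        if label == 1 and cfg.murmur_gain > 0:
            # diastole: from S2 end to the next S1
            dlo = min(n, lo2 + s2_len)
            dhi = min(n, int((bt + rr) * cfg.fs))
            if dhi - dlo > 20:
                raw = rng.standard_normal(dhi - dlo)
                sos = sps.butter(4, [150.0, 400.0], btype="bandpass", fs=cfg.fs, output="sos")
                murmur = sps.sosfilt(sos, raw)
                window = np.hanning(dhi - dlo)
                pcg[dlo:dhi] += cfg.murmur_gain * murmur * window
    noise = cfg.noise_sd * rng.standard_normal(n)
    mains = cfg.mains_amp * np.sin(2 * np.pi * cfg.mains_hz * t)
    return pcg + noise + mains


def synth_record(cfg: SynthConfig, subject_id: str, label: int, subject_seed: int) -> PairedRecord:
    """One subject's paired record, fully determined by (cfg, subject_seed)."""
    rng = np.random.default_rng(subject_seed)
    beats = _beat_times(cfg, rng)
    ecg = synth_ecg(cfg, rng, label, beats)
    pcg = synth_pcg(cfg, rng, label, beats)
    return PairedRecord(subject_id, label, ecg, pcg, cfg.fs)


def synth_dataset(cfg: SynthConfig) -> list[PairedRecord]:
    """n_per_class subjects per class, deterministic under cfg.seed."""
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=2 * cfg.n_per_class)
    records = []
    i = 0
    for label in (0, 1):
        for j in range(cfg.n_per_class):
            sid = f"S{label}{j:03d}"
            records.append(synth_record(cfg, sid, label, int(seeds[i])))
            i += 1
    return records


def write_dataset(records: list[PairedRecord], out_dir: str | Path) -> Path:
    """CSV signal files plus a manifest readable by io_preprocess.read_manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}.csv"
        pd.DataFrame({"ecg": rec.ecg, "pcg": rec.pcg}).to_csv(
            out_dir / fname, index=False, float_format="%.6f"
        )
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def single_signal_config(cfg: SynthConfig, which: str) -> SynthConfig:
    """Config variant where only one channel carries class information."""
    if which == "ecg":
        return replace(cfg, murmur_gain=0.0)
    if which == "pcg":
        return replace(cfg, st_shift=0.0)
    raise ValueError("which must be 'ecg' or 'pcg'")
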