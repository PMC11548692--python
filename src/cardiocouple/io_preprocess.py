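"""Paired ECG/PCG record handling: loading, denoising, segmentation, normalization.

ECG is cleaned with a 0.5-60 Hz Butterworth band-pass, PCG with a 20 Hz Butterworth
high-pass; both get an IIR notch at the mains frequency. All filters are 4th order
and applied forward-backward (zero phase) so wave timing is preserved. Records are
then cropped into fixed-length windows (10 s by default) and z-scored per channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

FILTER_ORDER = 4
NOTCH_Q = 30.0


@dataclass
class PairedRecord:
    """One subject's synchronized ECG and PCG traces with a binary CAD label."""

    subject_id: str
    label: int
    ecg: np.ndarray
    pcg: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.pcg = np.asarray(self.pcg, dtype=float)
        if self.ecg.shape != self.pcg.shape or self.ecg.ndim != 1:
            raise ValueError("channel length mismatch")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SegmentTriplet:
    """One window's z-scored ECG, PCG, and (optionally) derived coupling signal."""

    subject_id: str
    label: int
    ecg_seg: np.ndarray
    pcg_seg: np.ndarray
    coupling_seg: np.ndarray | None = None
    start: int = 0  # sample offset of the window in the source record
    seg_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.seg_id:
            self.seg_id = f"{self.subject_id}:{self.start}"


def _check_signal(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("invalid samples")
    if len(x) <= min_len:
        raise ValueError("signal too short")
    return x


def _notch(x: np.ndarray, fs: float, notch_hz: float) -> np.ndarray:
    b, a = sps.iirnotch(notch_hz, NOTCH_Q, fs=fs)
    return sps.filtfilt(b, a, x)


def denoise_ecg(x: np.ndarray, fs: float, notch_hz: float = 50.0) -> np.ndarray:
    """Band-pass (0.5-60 Hz) + mains notch, zero phase. Same length as input."""
    if fs < 200:
        raise ValueError("sampling rate too low (need fs >= 200)")
    sos = sps.butter(FILTER_ORDER, [0.5, 60.0], btype="bandpass", fs=fs, output="sos")
    # filtfilt pads with 3 * max(len(coeffs)) samples; guard against short inputs
    x = _check_signal(x, min_len=3 * (2 * FILTER_ORDER + 1))
    y = sps.sosfiltfilt(sos, x)
    return _notch(y, fs, notch_hz)


def denoise_pcg(x: np.ndarray, fs: float, notch_hz: float = 50.0) -> np.ndarray:
    """High-pass (20 Hz) + mains notch, zero phase. Same length as input."""
    if fs < 200:
        raise ValueError("sampling rate too low (need fs >= 200)")
    sos = sps.butter(FILTER_ORDER, 20.0, btype="highpass", fs=fs, output="sos")
    x = _check_signal(x, min_len=3 * (2 * FILTER_ORDER + 1))
    y = sps.sosfiltfilt(sos, x)
    return _notch(y, fs, notch_hz)


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit population (1/N) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def segment(
    record: PairedRecord, window_s: float = 10.0, overlap_frac: float = 0.0
) -> list[SegmentTriplet]:
    """Crop a record into fixed windows; each window is z-scored per channel.

    Consecutive starts differ by ``window_s * fs * (1 - overlap_frac)`` samples;
    a trailing partial window is discarded. Returns an empty list (with a warning)
    when the record is shorter than one window.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    win = int(round(window_s * record.fs))
    step = int(round(win * (1.0 - overlap_frac)))
    if step < 1:
        raise ValueError("overlap too large: zero step")
    n = len(record.ecg)
    if n < win:
        warnings.warn(
            f"record {record.subject_id} shorter than one window; no segments",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, n - win + 1, step):
        out.append(
            SegmentTriplet(
                subject_id=record.subject_id,
                label=record.label,
                ecg_seg=zscore(record.ecg[start : start + win]),
                pcg_seg=zscore(record.pcg[start : start + win]),
                start=start,
            )
        )
    return out


def preprocess_record(
    record: PairedRecord,
    window_s: float = 10.0,
    overlap_frac: float = 0.0,
    notch_hz: float = 50.0,
) -> list[SegmentTriplet]:
    """Denoise the full record (both channels), then segment and z-score.

    Denoising before segmentation avoids filter edge transients inside windows.
    """
    clean = PairedRecord(
        subject_id=record.subject_id,
        label=record.label,
        ecg=denoise_ecg(record.ecg, record.fs, notch_hz),
        pcg=denoise_pcg(record.pcg, record.fs, notch_hz),
        fs=record.fs,
    )
    return segment(clean, window_s, overlap_frac)


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column ``ecg,pcg`` CSV into channel arrays."""
    df = pd.read_csv(path)
    missing = {"ecg", "pcg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df["ecg"].to_numpy(float), df["pcg"].to_numpy(float)


def read_manifest(path: str | Path, fs: float = 1000.0) -> list[PairedRecord]:
    """Load paired records listed in a manifest CSV/TSV.

    Columns: ``subject_id,label,path`` (two-channel CSV per record) or
    ``subject_id,label,ecg_path,pcg_path`` (one single-column CSV per channel).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    if len(df) == 0:
        return []
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id: {dupes}")
    records = []
    for _, row in df.iterrows():
        label = int(row["label"])
        if label not in (0, 1):
            raise ValueError(f"label outside {{0,1}} for subject {row['subject_id']}")
        if "path" in df.columns and not pd.isna(row.get("path", np.nan)):
            p = path.parent / str(row["path"])
            if not p.exists():
                raise FileNotFoundError(str(p))
            ecg, pcg = read_signal_csv(p)
        else:
            pe = path.parent / str(row["ecg_path"])
            pp = path.parent / str(row["pcg_path"])
            for q in (pe, pp):
                if not q.exists():
                    raise FileNotFoundError(str(q))
            ecg = pd.read_csv(pe).iloc[:, 0].to_numpy(float)
            pcg = pd.read_csv(pp).iloc[:, 0].to_numpy(float)
        if len(ecg) != len(pcg):
            raise ValueError("channel length mismatch")
        records.append(PairedRecord(str(row["subject_id"]), label, ecg, pcg, fs))
    return records


def write_segments(path: str | Path, segments: list[SegmentTriplet], fs: float) -> None:
    """Persist segments to an HDF5 container, one group per subject.

    Datasets per group: ``ecg``, ``pcg``, ``coupling`` (n_segments x window);
    attributes ``fs`` and ``label``.
    """
    by_subject: dict[str, list[SegmentTriplet]] = {}
    for seg in segments:
        by_subject.setdefault(seg.subject_id, []).append(seg)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = fs
        for sid, segs in by_subject.items():
            g = f.create_group(sid)
            g.attrs["label"] = segs[0].label
            g.attrs["fs"] = fs
            g.create_dataset("ecg", data=np.stack([s.ecg_seg for s in segs]))
            g.create_dataset("pcg", data=np.stack([s.pcg_seg for s in segs]))
            if all(s.coupling_seg is not None for s in segs):
                g.create_dataset(
                    "coupling", data=np.stack([s.coupling_seg for s in segs])
                )
            g.create_dataset("start", data=np.array([s.start for s in segs]))


def read_segments(path: str | Path) -> tuple[list[SegmentTriplet], float]:
    """Inverse of :func:`write_segments`."""
    out: list[SegmentTriplet] = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        for sid in sorted(f.keys()):
            g = f[sid]
            label = int(g.attrs["label"])
            coup = g["coupling"][...] if "coupling" in g else None
            starts = g["start"][...]
            for i in range(g["ecg"].shape[0]):
                out.append(
                    SegmentTriplet(
                        subject_id=sid,
                        label=label,
                        ecg_seg=g["ecg"][i],
                        pcg_seg=g["pcg"][i],
                        coupling_seg=None if coup is None else coup[i],
                        start=int(starts[i]),
                    )
                )
    return out, fs
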