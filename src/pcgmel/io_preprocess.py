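"""Audio I/O and the preprocessing chain for heart-sound recordings.

A phonocardiogram (PCG) arrives as a mono WAV file.  Before feature
extraction it is band-limited to the 25–950 Hz band that carries S1/S2
transients and murmurs, smoothed with a Savitzky–Golay filter, and cut
into fixed-length segments (2.5 s at 2 kHz by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "PreprocessConfig",
    "read_wav",
    "write_wav",
    "bandpass_filter",
    "smooth_savitzky_golay",
    "resample_to",
    "segment_fixed",
    "preprocess",
    "read_manifest",
    "write_manifest",
]

log = logging.getLogger(__name__)

NORMAL = "normal"
ABNORMAL = "abnormal"
LABELS = (NORMAL, ABNORMAL)

MANIFEST_COLUMNS = ["record_id", "path", "label", "domain_id"]


@dataclass(frozen=True)
class AudioRecording:
    """A mono heart-sound signal with its acquisition metadata.

    ``samples`` are dimensionless amplitudes (float64), ``fs`` the sampling
    frequency in Hz.  ``label`` is ``"normal"``/``"abnormal"`` (or ``""`` when
    unknown) and ``domain_id`` names the acquisition-device group.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    domain_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("AudioRecording requires a 1-D, non-empty signal")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioRecording samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be > 0, got {self.fs}")
        if self.label and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "AudioRecording":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults: 2 kHz sampling, 25–950 Hz Butterworth band (order 4, applied
    forward–backward for zero phase), Savitzky–Golay window 11 / polyorder 3,
    2.5 s segments.
    """

    target_fs: float = 2000.0
    band_low: float = 25.0
    band_high: float = 950.0
    butter_order: int = 4
    sg_window: int = 11
    sg_polyorder: int = 3
    segment_seconds: float = 2.5
    segment_overlap: float = 0.0  # fraction of a segment shared with the next

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high < self.target_fs / 2:
            raise ValueError(
                "band edges must satisfy 0 < low < high < Nyquist "
                f"(got {self.band_low}, {self.band_high} at fs {self.target_fs})"
            )
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if not 0 <= self.segment_overlap < 1:
            raise ValueError("segment_overlap must be in [0, 1)")
        n = self.segment_seconds * self.target_fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_seconds x target_fs must be an integer")

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_seconds * self.target_fs))


def read_wav(path: str | Path, label: str = "", domain_id: str = "",
             record_id: str = "") -> AudioRecording:
    """Read a PCM16/float32 WAV file as a mono recording scaled to [-1, 1].

    Multi-channel audio is averaged to mono.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header etc.
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).min)
        samples = data.astype(np.float64) / -scale
    else:
        samples = data.astype(np.float64)
    rid = record_id or path.stem
    return AudioRecording(samples=samples, fs=float(fs), label=label,
                          domain_id=domain_id, record_id=rid)


def write_wav(path: str | Path, rec: AudioRecording, dtype: str = "int16") -> None:
    """Write a recording as PCM16 (default, clipped to [-1, 1]) or float32."""
    path = Path(path)
    if dtype == "int16":
        clipped = np.clip(rec.samples, -1.0, 1.0 - 1.0 / 32768)
        wavfile.write(path, int(rec.fs), np.round(clipped * 32768).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, int(rec.fs), rec.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def bandpass_filter(rec: AudioRecording, cfg: PreprocessConfig) -> AudioRecording:
    """Zero-phase Butterworth band-pass to [band_low, band_high] Hz.

    The recording must already be at ``cfg.target_fs`` (use :func:`resample_to`
    first); the forward–backward pass doubles the effective order and cancels
    the phase delay.
    """
    if abs(rec.fs - cfg.target_fs) > 1e-9:
        raise ValueError(
            f"recording at {rec.fs} Hz; resample to {cfg.target_fs} Hz first")
    sos = signal.butter(cfg.butter_order,
                        [cfg.band_low, cfg.band_high],
                        btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples))


def smooth_savitzky_golay(rec: AudioRecording, cfg: PreprocessConfig) -> AudioRecording:
    """Savitzky–Golay smoothing (local least-squares polynomial fit)."""
    if cfg.sg_window > rec.samples.size:
        raise ValueError(
            f"sg_window {cfg.sg_window} exceeds signal length {rec.samples.size}")
    return rec.with_samples(
        signal.savgol_filter(rec.samples, cfg.sg_window, cfg.sg_polyorder))


def resample_to(rec: AudioRecording, target_fs: float) -> AudioRecording:
    """Band-limited (polyphase) resampling to ``target_fs``."""
    if not target_fs > 0:
        raise ValueError("target_fs must be > 0")
    if abs(rec.fs - target_fs) < 1e-9:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    want = int(round(rec.samples.size * target_fs / rec.fs))
    if out.size > want:
        out = out[:want]
    elif out.size < want:
        out = np.pad(out, (0, want - out.size))
    return replace(rec, samples=out, fs=float(target_fs))


def _energy_peak_offset(samples: np.ndarray, fs: float,
                        win_seconds: float = 0.05) -> int:
    """Index of the first local short-time-energy peak (rectangular window).

    Approximates the start of a cardiac cycle by the first S1-like burst: the
    first local maximum of short-time energy that reaches 50% of the global
    maximum.
    """
    w = max(1, int(round(win_seconds * fs)))
    energy = np.convolve(samples ** 2, np.ones(w), mode="same")
    thresh = 0.5 * energy.max()
    peaks, _ = signal.find_peaks(energy, height=thresh)
    if peaks.size == 0:
        return 0
    return max(0, int(peaks[0]) - w // 2)


def segment_fixed(rec: AudioRecording, cfg: PreprocessConfig,
                  align: str = "none") -> list[AudioRecording]:
    """Cut a recording into consecutive fixed-length segments.

    ``align="none"`` starts at sample 0; ``align="energy_peak"`` starts at the
    first short-time-energy peak (a stand-in for the start of a cardiac
    cycle).  A trailing remainder shorter than one segment is discarded.
    Segments inherit label and domain and get ``record_id#<i>`` identifiers.
    """
    if align not in ("none", "energy_peak"):
        raise ValueError(f"unknown align mode {align!r}")
    seg_len = cfg.segment_samples
    offset = 0
    if align == "energy_peak":
        offset = _energy_peak_offset(rec.samples, rec.fs)
    hop = max(1, int(round(seg_len * (1.0 - cfg.segment_overlap))))
    segments: list[AudioRecording] = []
    start = offset
    while start + seg_len <= rec.samples.size:
        chunk = rec.samples[start:start + seg_len]
        segments.append(replace(rec, samples=chunk,
                                record_id=f"{rec.record_id}#{len(segments)}"))
        start += hop
    if not segments:
        log.info("recording %s shorter than one segment (%d < %d samples)",
                 rec.record_id, rec.samples.size - offset, seg_len)
    return segments


def preprocess(rec: AudioRecording, cfg: PreprocessConfig | None = None,
               align: str = "none") -> list[AudioRecording]:
    """Full chain: resample -> band-pass -> Savitzky–Golay -> segment."""
    cfg = cfg or PreprocessConfig()
    rec = resample_to(rec, cfg.target_fs)
    rec = bandpass_filter(rec, cfg)
    rec = smooth_savitzky_golay(rec, cfg)
    return segment_fixed(rec, cfg, align=align)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV (record_id, path, label, domain_id)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
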