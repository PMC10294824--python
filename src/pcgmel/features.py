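"""MelSpectrum and Log-MelSpectrum feature extraction.

A fixed-length heart-sound segment is framed with a Hanning window, turned
into a periodogram power spectrum by short-time Fourier transform, mapped
through a bank of triangular Mel filters (the MelSpectrum), and optionally
log-compressed (the Log-MelSpectrum).

The log compression is the scientifically load-bearing step: a stethoscope
acts as a linear time-invariant channel, i.e. multiplicatively in each
frequency band.  In the log-Mel domain that multiplicative channel becomes a
per-band *additive* offset, constant over time, which a convolutional
classifier tolerates far better than a per-band rescaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io_preprocess import AudioRecording

__all__ = [
    "StftConfig",
    "PowerSpectrogram",
    "MelFilterbank",
    "FeatureMap",
    "hz_to_mel",
    "mel_to_hz",
    "frame_signal",
    "stft_power",
    "build_mel_filterbank",
    "mel_spectrum",
    "log_mel_spectrum",
    "to_model_input",
    "extract_feature_map",
    "save_feature_map",
    "load_feature_map",
]

# HTK-style Mel warping constants
_MEL_SCALE = 2595.0
_MEL_BREAK = 700.0


@dataclass(frozen=True)
class StftConfig:
    """Framing/FFT parameters: 240-sample Hanning windows hopped by 60,
    zero-padded to a 512-point FFT (2 kHz audio)."""

    window_size: int = 240
    hop_length: int = 60
    n_fft: int = 512
    window_function: str = "hanning"

    def __post_init__(self) -> None:
        if self.window_size > self.n_fft:
            raise ValueError("window_size must be <= n_fft")
        if self.hop_length < 1:
            raise ValueError("hop_length must be >= 1")
        if self.window_function != "hanning":
            raise ValueError("only the Hanning window is supported")

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    def window(self) -> np.ndarray:
        # periodic Hann, the standard STFT analysis window
        return np.hanning(self.window_size + 1)[:-1]


@dataclass(frozen=True)
class PowerSpectrogram:
    """One-sided periodogram |FFT|^2 per frame (no 1/N normalisation; any
    global scale cancels in log-Mel shifts and is standardised away later)."""

    values: np.ndarray          # (n_frames L, n_bins K)
    frame_times: np.ndarray     # seconds, frame centres
    bin_freqs: np.ndarray       # Hz

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("power spectrogram must be non-negative")


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular filters, rows = Mel bands, columns = FFT bins."""

    weights: np.ndarray         # (n_mels M, n_bins K)
    n_mels: int
    f_low: float
    f_high: float
    mel_scale: str = "htk-2595"

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class FeatureMap:
    """A Mel-band x frame matrix, flavor ``"mel"`` (power, >= 0) or
    ``"log_mel"`` (natural log power)."""

    values: np.ndarray          # (n_mels, n_frames)
    flavor: str
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.flavor not in ("mel", "log_mel"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "mel" and not self.standardized and np.any(self.values < 0):
            raise ValueError("mel-flavor feature maps must be non-negative")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return _MEL_SCALE * np.log10(1.0 + np.asarray(f, dtype=float) / _MEL_BREAK)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return _MEL_BREAK * (10.0 ** (np.asarray(m, dtype=float) / _MEL_SCALE) - 1.0)


def frame_signal(segment: AudioRecording, cfg: StftConfig) -> np.ndarray:
    """Slice into L = floor((N - W)/H) + 1 frames and apply the Hanning window.

    Returns an (L, window_size) matrix.
    """
    x = segment.samples
    if x.size < cfg.window_size:
        raise ValueError(
            f"segment of {x.size} samples shorter than one window "
            f"({cfg.window_size})")
    n_frames = (x.size - cfg.window_size) // cfg.hop_length + 1
    idx = (np.arange(cfg.window_size)[None, :]
           + cfg.hop_length * np.arange(n_frames)[:, None])
    return x[idx] * cfg.window()[None, :]


def stft_power(frames: np.ndarray, cfg: StftConfig,
               fs: float = 2000.0) -> PowerSpectrogram:
    """Periodogram power spectrum of (already windowed) frames.

    Each frame is zero-padded to ``n_fft`` and |FFT|^2 is taken over the
    one-sided spectrum (K = n_fft/2 + 1 bins).
    """
    frames = np.atleast_2d(frames)
    spec = np.fft.rfft(frames, n=cfg.n_fft, axis=1)
    power = np.abs(spec) ** 2
    centers = (np.arange(frames.shape[0]) * cfg.hop_length
               + cfg.window_size / 2) / fs
    freqs = np.fft.rfftfreq(cfg.n_fft, d=1.0 / fs)
    return PowerSpectrogram(values=power, frame_times=centers, bin_freqs=freqs)


def build_mel_filterbank(n_mels: int = 128, f_low: float = 25.0,
                         f_high: float = 950.0, n_fft: int = 512,
                         fs: float = 2000.0,
                         norm: str | None = None) -> MelFilterbank:
    """Bank of ``n_mels`` triangular filters with centres equally spaced on
    the Mel scale between ``f_low`` and ``f_high``.

    Filter m rises linearly from centre m-1, peaks at centre m, and falls to
    centre m+1 (evaluated at the FFT bin frequencies).  ``norm="column"``
    rescales each in-band column to sum to 1, which makes the filterbank
    energy-conserving.
    """
    if f_high > fs / 2 + 1e-9:
        raise ValueError("f_high must be <= Nyquist")
    mel_pts = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    df = fs / n_fft
    if np.any(np.diff(hz_pts) < df):
        warnings.warn(
            f"{n_mels} Mel filters over [{f_low}, {f_high}] Hz exceed the "
            f"{df:.2f} Hz bin resolution; adjacent centres share FFT bins",
            stacklevel=2)
    lower, center, upper = hz_pts[:-2], hz_pts[1:-1], hz_pts[2:]
    up = (freqs[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - freqs[None, :]) / (upper - center)[:, None]
    weights = np.maximum(0.0, np.minimum(up, down))
    if norm == "column":
        col = weights.sum(axis=0)
        in_band = (freqs >= f_low) & (freqs <= f_high) & (col > 0)
        weights = weights.copy()
        weights[:, in_band] /= col[in_band]
    elif norm is not None:
        raise ValueError(f"unknown norm {norm!r}")
    return MelFilterbank(weights=weights, n_mels=n_mels,
                         f_low=f_low, f_high=f_high)


def mel_spectrum(ps: PowerSpectrogram, fb: MelFilterbank) -> FeatureMap:
    """Weighted sum of power-spectrum bins per Mel band:
    values[m, l] = sum_k weights[m, k] * power[l, k]."""
    if ps.values.shape[1] != fb.n_bins:
        raise ValueError(
            f"spectrogram has {ps.values.shape[1]} bins, filterbank expects "
            f"{fb.n_bins}")
    return FeatureMap(values=fb.weights @ ps.values.T, flavor="mel")


def log_mel_spectrum(mel: FeatureMap, epsilon: float | None = None) -> FeatureMap:
    """Elementwise natural log of (MelSpectrum + eps).

    By default eps is 1e-10 x the map's maximum (absolute floor 1e-300), which
    keeps silent bands finite without distorting the dynamic range.
    """
    if mel.flavor != "mel":
        raise ValueError("log_mel_spectrum expects a mel-flavor map")
    if epsilon is None:
        epsilon = max(1e-10 * float(mel.values.max(initial=0.0)), 1e-300)
    elif epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return FeatureMap(values=np.log(mel.values + epsilon), flavor="log_mel")


def to_model_input(fm: FeatureMap, target_shape: tuple[int, int] = (128, 128),
                   time_policy: str = "interpolate",
                   standardize: bool = True) -> FeatureMap:
    """Shape a feature map to the classifier input (128 x 128 by default).

    The frequency axis must already match; the time axis is linearly
    interpolated (default) or right-padded with the flavor's floor value.
    Per-map standardisation (zero mean, unit variance) is applied last so the
    two flavors reach the classifier at matched scales.
    """
    n_rows, n_cols = target_shape
    vals = fm.values
    if vals.shape[0] != n_rows:
        raise ValueError(f"expected {n_rows} Mel bands, got {vals.shape[0]}")
    if vals.shape[1] != n_cols:
        if time_policy == "interpolate":
            old = np.linspace(0.0, 1.0, vals.shape[1])
            new = np.linspace(0.0, 1.0, n_cols)
            vals = np.stack([np.interp(new, old, row) for row in vals])
        elif time_policy == "pad":
            if vals.shape[1] > n_cols:
                vals = vals[:, :n_cols]
            else:
                fill = 0.0 if fm.flavor == "mel" else float(vals.min())
                vals = np.pad(vals, ((0, 0), (0, n_cols - vals.shape[1])),
                              constant_values=fill)
        else:
            raise ValueError(f"unknown time_policy {time_policy!r}")
    out = FeatureMap(values=vals, flavor=fm.flavor)
    if standardize:
        mu, sd = vals.mean(), vals.std()
        vals = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
        out = FeatureMap(values=vals, flavor=fm.flavor, standardized=True)
    return out


def extract_feature_map(segment: AudioRecording, flavor: str = "log_mel",
                        stft_cfg: StftConfig | None = None,
                        fb: MelFilterbank | None = None,
                        target_shape: tuple[int, int] = (128, 128),
                        standardize: bool = True) -> FeatureMap:
    """Segment -> model-ready feature map (frame, STFT, Mel, [log], shape)."""
    stft_cfg = stft_cfg or StftConfig()
    if fb is None:
        fb = build_mel_filterbank(n_mels=target_shape[0], n_fft=stft_cfg.n_fft,
                                  fs=segment.fs)
    frames = frame_signal(segment, stft_cfg)
    ps = stft_power(frames, stft_cfg, fs=segment.fs)
    fm = mel_spectrum(ps, fb)
    if flavor == "log_mel":
        fm = log_mel_spectrum(fm)
    elif flavor != "mel":
        raise ValueError(f"unknown flavor {flavor!r}")
    return to_model_input(fm, target_shape=target_shape, standardize=standardize)


def save_feature_map(fm: FeatureMap, path: str | Path) -> None:
    """Persist as a .npy array with a JSON metadata sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), fm.values)
    meta = {"flavor": fm.flavor, "standardized": fm.standardized,
            "shape": list(fm.values.shape)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def export_png(fm: FeatureMap, path: str | Path) -> None:
    """Render a feature map as a PNG for visual inspection.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(fm.values, origin="lower", aspect="auto", cmap="magma")
    ax.set_xlabel("frame")
    ax.set_ylabel("Mel band")
    ax.set_title(fm.flavor)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_feature_map(path: str | Path) -> FeatureMap:
    path = Path(path)
    vals = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureMap(values=vals, flavor=meta["flavor"],
                      standardized=meta["standardized"])
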