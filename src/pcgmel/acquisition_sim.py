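"""Synthetic cardiac-sound acquisition model.

A recorded heart sound y(n) is modelled as the clean cardiac source s(n)
plus additive background noise a(n), convolved with the stethoscope impulse
response h(n):

    y(n) = (s(n) + a(n)) * h(n)

The clean source is a periodic train of S1/S2 valve-closure transients
(Gaussian-enveloped tones) with optional systolic murmur bursts (band-limited
noise between S1 and S2) marking the abnormal class.  Each acquisition
"domain" (device group) gets its own smooth low-order channel h, which is
what creates the domain shift the leave-one-domain-out protocol probes.

Default domain sizes follow the six sub-dataset structure of the 2016
PhysioNet/CinC heart-sound corpus (very unequal domains, ~66% in one of
them, class imbalance), scaled down for desk-scale experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io_preprocess import (ABNORMAL, NORMAL, AudioRecording, write_manifest,
                            write_wav)

__all__ = [
    "HeartSoundParams",
    "NoiseParams",
    "ChannelModel",
    "DatasetSpec",
    "TABLE2_COUNTS",
    "table2_spec",
    "synth_clean_pcg",
    "acquire",
    "make_domain_channels",
    "generate_dataset",
]

log = logging.getLogger(__name__)

# (normal recordings, abnormal recordings) per device-domain of the 2016
# PhysioNet/CinC corpus; used only as default *proportions*.
TABLE2_COUNTS: dict[str, tuple[int, int]] = {
    "a": (117, 292),
    "b": (386, 104),
    "c": (7, 24),
    "d": (27, 28),
    "e": (1958, 183),
    "f": (80, 34),
}


@dataclass(frozen=True)
class HeartSoundParams:
    """Parameters of the clean source s(n).

    S1/S2 are Gaussian-enveloped tones; a murmur is a band-limited noise
    burst between S1 and S2 (systolic), with amplitude ``murmur_gain``
    relative to the S1 peak.
    """

    heart_rate_bpm: float = 70.0
    s1_freq: float = 50.0
    s2_freq: float = 80.0
    s1_s2_interval_frac: float = 0.35
    transient_width_ms: float = 45.0
    murmur_present: bool = False
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_gain: float = 0.35
    hr_jitter_frac: float = 0.03

    def __post_init__(self) -> None:
        if not 30 <= self.heart_rate_bpm <= 200:
            raise ValueError("heart_rate_bpm must be in [30, 200]")
        if not 0 < self.murmur_band[0] < self.murmur_band[1]:
            raise ValueError("murmur_band must be an increasing positive pair")
        if self.murmur_gain < 0:
            raise ValueError("murmur_gain must be >= 0")
        if not 0 < self.s1_s2_interval_frac < 1:
            raise ValueError("s1_s2_interval_frac must be in (0, 1)")


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise a(n): background/breath/friction sounds at a target
    signal-to-noise ratio.  ``snr_db=inf`` disables the noise."""

    snr_db: float = 15.0
    noise_kind: str = "pink"
    band: tuple[float, float] = (50.0, 900.0)  # for noise_kind="band_limited"

    def __post_init__(self) -> None:
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")
        if self.noise_kind not in ("white", "pink", "band_limited"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


@dataclass(frozen=True)
class ChannelModel:
    """Stethoscope/channel impulse response h(n) for one domain."""

    domain_id: str
    impulse_response: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.impulse_response, dtype=np.float64)
        object.__setattr__(self, "impulse_response", h)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("impulse response must be a non-empty 1-D array")
        if not np.all(np.isfinite(h)) or not np.any(h):
            raise ValueError("impulse response must be finite and not all zero")

    def magnitude_db(self, freqs: np.ndarray, fs: float) -> np.ndarray:
        w, h = signal.freqz(self.impulse_response, worN=freqs, fs=fs)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-12))


@dataclass(frozen=True)
class DatasetSpec:
    """Per-domain recording counts for a synthetic multi-domain dataset."""

    domains: dict[str, tuple[int, int]]  # domain -> (n_normal, n_abnormal)
    seed: int = 0
    fs: float = 2000.0
    record_seconds: float = 3.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        for dom, (n_norm, n_abn) in self.domains.items():
            if n_norm < 0 or n_abn < 0:
                raise ValueError(f"negative count for domain {dom!r}")
        if self.fs <= 0 or self.record_seconds <= 0:
            raise ValueError("fs and record_seconds must be positive")

    @property
    def n_records(self) -> int:
        return sum(n + a for n, a in self.domains.values())


def table2_spec(scale: float = 1.0, seed: int = 0,
                record_seconds: float = 3.0,
                noise: NoiseParams | None = None) -> DatasetSpec:
    """Six-domain spec at the PhysioNet/CinC proportions, scaled by ``scale``
    (counts rounded, at least 1 per class per domain)."""
    domains = {
        dom: (max(1, round(n * scale)), max(1, round(a * scale)))
        for dom, (n, a) in TABLE2_COUNTS.items()
    }
    return DatasetSpec(domains=domains, seed=seed,
                       record_seconds=record_seconds,
                       noise=noise or NoiseParams())


def _gauss_tone(t: np.ndarray, center: float, freq: float, width_s: float,
                amplitude: float, phase: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / (width_s / 2.0)) ** 2)
    return amplitude * env * np.sin(2 * np.pi * freq * (t - center) + phase)


def synth_clean_pcg(params: HeartSoundParams, duration: float, fs: float,
                    seed: int) -> AudioRecording:
    """Synthesise a clean phonocardiogram s(n).

    Cycles start at t = 0.05 s; each cycle places an S1 transient at its
    start and an S2 at ``s1_s2_interval_frac`` of the (jittered) period.
    Abnormal signals add a murmur burst spanning the S1–S2 interval.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    period = 60.0 / params.heart_rate_bpm
    width_s = params.transient_width_ms / 1000.0

    murmur_src = np.zeros(n)
    if params.murmur_present:
        white = rng.standard_normal(n)
        sos = signal.butter(4, params.murmur_band, btype="bandpass",
                            fs=fs, output="sos")
        murmur_src = signal.sosfilt(sos, white)
        rms = np.sqrt(np.mean(murmur_src ** 2))
        if rms > 0:
            murmur_src /= rms

    t0 = 0.05
    while t0 < duration:
        this_period = period * (1.0 + params.hr_jitter_frac * rng.standard_normal())
        this_period = max(0.25, this_period)
        t_s2 = t0 + params.s1_s2_interval_frac * this_period
        a1 = 1.0 * (1.0 + 0.05 * rng.standard_normal())
        a2 = 0.8 * (1.0 + 0.05 * rng.standard_normal())
        x += _gauss_tone(t, t0, params.s1_freq, width_s, a1, rng.uniform(0, 2 * np.pi))
        if t_s2 < duration:
            x += _gauss_tone(t, t_s2, params.s2_freq, width_s, a2,
                             rng.uniform(0, 2 * np.pi))
        if params.murmur_present:
            m_start, m_end = t0 + 0.6 * width_s, t_s2 - 0.6 * width_s
            if m_end > m_start:
                window = np.zeros(n)
                sel = (t >= m_start) & (t <= m_end)
                if sel.sum() >= 4:
                    window[sel] = signal.windows.tukey(int(sel.sum()), alpha=0.5)
                x += params.murmur_gain * window * murmur_src
        t0 += this_period

    peak = np.abs(x).max()
    if peak > 0:
        x = 0.9 * x / peak
    label = ABNORMAL if params.murmur_present else NORMAL
    return AudioRecording(samples=x, fs=fs, label=label)


def _make_noise(kind: str, n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if kind == "white":
        return white
    if kind == "pink":
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = 1.0 / np.sqrt(f[1:])
        return np.fft.irfft(spec * shape, n=n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfilt(sos, white)


def acquire(clean: AudioRecording, noise: NoiseParams, channel: ChannelModel,
            seed: int) -> AudioRecording:
    """Apply the acquisition model: add noise at the stated SNR, then convolve
    with the channel impulse response (output truncated to the input length).
    """
    h = channel.impulse_response
    if h.size >= clean.samples.size:
        raise ValueError("channel impulse response must be shorter than the signal")
    s = clean.samples
    if math.isinf(noise.snr_db):
        noisy = s
    else:
        rng = np.random.default_rng(seed)
        a = _make_noise(noise.noise_kind, s.size, clean.fs, noise.band, rng)
        p_signal = np.mean(s ** 2)
        p_noise = np.mean(a ** 2)
        target = p_signal / (10.0 ** (noise.snr_db / 10.0))
        if p_noise > 0 and target > 0:
            a = a * np.sqrt(target / p_noise)
        noisy = s + a
    y = np.convolve(noisy, h, mode="full")[: s.size]
    out = clean.with_samples(y)
    return AudioRecording(samples=out.samples, fs=out.fs, label=clean.label,
                          domain_id=channel.domain_id or clean.domain_id,
                          record_id=clean.record_id)


def make_domain_channels(n_domains: int, seed: int, fs: float = 2000.0,
                         n_taps: int = 65) -> list[ChannelModel]:
    """One smooth, distinct channel per domain.

    Each channel is a linear-phase FIR fit to a smooth log-linear spectral
    tilt over the 25–950 Hz band (with a mild random resonance), emulating
    how different stethoscopes colour the signal.  The first channel is a
    near-flat reference; subsequent channels alternate increasingly strong
    positive/negative tilts, so magnitude responses are pairwise > 1 dB
    apart.  Deterministic per seed.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    rng = np.random.default_rng(seed)
    # tilt (dB across the band) sequence: 0, +6, -6, +10, -10, +14, ...
    tilts = [0.0]
    k = 1
    while len(tilts) < n_domains:
        mag = 6.0 + 4.0 * ((k - 1) // 2)
        tilts.append(mag if k % 2 == 1 else -mag)
        k += 1
    channels = []
    names = "abcdefghijklmnopqrstuvwxyz"
    f_lo, f_hi = 25.0, 950.0
    for i in range(n_domains):
        tilt_db = tilts[i] + (0.5 * rng.standard_normal() if i else 0.0)
        gain_db = rng.uniform(-3.0, 3.0) if i else 0.0
        res_f = rng.uniform(100.0, 600.0)
        res_db = rng.uniform(0.0, 2.0) if i else 0.0
        freqs = np.linspace(0.0, fs / 2, 257)
        log_span = np.log(f_hi / f_lo)
        frac = np.clip(np.log(np.maximum(freqs, f_lo) / f_lo) / log_span, 0, 1)
        mag_db = gain_db + tilt_db * (frac - 0.5)
        mag_db += res_db * np.exp(-0.5 * ((freqs - res_f) / 120.0) ** 2)
        mag = 10.0 ** (mag_db / 20.0)
        # roll off outside the instrument band
        mag[freqs < 5.0] *= freqs[freqs < 5.0] / 5.0
        h = signal.firwin2(n_taps, freqs, mag, fs=fs)
        dom = names[i] if i < len(names) else f"d{i}"
        channels.append(ChannelModel(
            domain_id=dom, impulse_response=h,
            description=f"tilt {tilt_db:+.1f} dB, gain {gain_db:+.1f} dB"))
    return channels


def _sample_params(rng: np.random.Generator, abnormal: bool) -> HeartSoundParams:
    return HeartSoundParams(
        heart_rate_bpm=rng.uniform(55.0, 100.0),
        s1_freq=rng.uniform(40.0, 70.0),
        s2_freq=rng.uniform(60.0, 100.0),
        s1_s2_interval_frac=rng.uniform(0.30, 0.40),
        transient_width_ms=rng.uniform(35.0, 55.0),
        murmur_present=abnormal,
        murmur_gain=rng.uniform(0.25, 0.45),
        hr_jitter_frac=0.03,
    )


def generate_dataset(spec: DatasetSpec, channels: list[ChannelModel],
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[AudioRecording], pd.DataFrame]:
    """Synthesise the full multi-domain dataset of ``spec``.

    Each record draws its own heart-sound parameters (murmur if and only if
    abnormal), passes through its domain's channel and the additive noise,
    and is fully reproducible from ``spec.seed``.  If ``out_dir`` is given,
    WAV files and a ``manifest.csv`` are written there.
    """
    by_domain = {ch.domain_id: ch for ch in channels}
    missing = set(spec.domains) - set(by_domain)
    if missing:
        raise ValueError(f"no channel for domains {sorted(missing)}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    records: list[AudioRecording] = []
    rows = []
    for d_idx, (dom, (n_norm, n_abn)) in enumerate(sorted(spec.domains.items())):
        for label, count in ((NORMAL, n_norm), (ABNORMAL, n_abn)):
            for i in range(count):
                # independent, reproducible stream per record
                ss = np.random.SeedSequence(
                    [spec.seed, d_idx, 0 if label == NORMAL else 1, i])
                s_param, s_clean, s_noise = ss.generate_state(3) % (2 ** 31)
                rng = np.random.default_rng(int(s_param))
                params = _sample_params(rng, abnormal=(label == ABNORMAL))
                clean = synth_clean_pcg(params, spec.record_seconds, spec.fs,
                                        seed=int(s_clean))
                rec_id = f"{dom}_{label[:3]}_{i:04d}"
                clean = AudioRecording(samples=clean.samples, fs=spec.fs,
                                       label=label, domain_id=dom,
                                       record_id=rec_id)
                rec = acquire(clean, spec.noise, by_domain[dom],
                              seed=int(s_noise))
                path = ""
                if out is not None:
                    path = str(out / f"{rec_id}.wav")
                    write_wav(path, rec)
                records.append(rec)
                rows.append({"record_id": rec_id, "path": path,
                             "label": label, "domain_id": dom})
        log.info("domain %s: %d normal / %d abnormal", dom, n_norm, n_abn)
    manifest = pd.DataFrame(rows)
    if out is not None:
        write_manifest(manifest, out / "manifest.csv")
    return records, manifest
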