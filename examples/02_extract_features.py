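"""From raw audio to model-ready MelSpectrum / Log-MelSpectrum maps.

The chain: resample to 2 kHz, 25-950 Hz Butterworth band-pass,
Savitzky-Golay smoothing, 2.5 s segments, Hanning-window STFT, 128
triangular Mel filters, optional log, then shaping to 128 x 128 with
per-map standardisation.
"""

from pcgmel import (HeartSoundParams, extract_feature_map, preprocess,
                    synth_clean_pcg)

rec = synth_clean_pcg(HeartSoundParams(heart_rate_bpm=75.0,
                                       murmur_present=True),
                      duration=6.0, fs=2000.0, seed=42)
segments = preprocess(rec)
print(f"{rec.duration:.1f} s recording -> {len(segments)} segments of 2.5 s")

for flavor in ("mel", "log_mel"):
    fm = extract_feature_map(segments[0], flavor=flavor)
    print(f"{flavor:8s}: shape {fm.values.shape}, "
          f"standardized mean {fm.values.mean():+.2e}, "
          f"std {fm.values.std():.3f}")
# both flavors reach the classifier at matched scale (mean 0, std 1);
# what differs is the *relative* weighting of quiet vs loud time-frequency
# cells, which is what the log compression changes.
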