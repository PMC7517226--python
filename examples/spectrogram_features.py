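"""From a 4-s crop of audio to the classifier's 513 x 125 input matrix.

The short-time Fourier transform runs every 32 ms over 64 ms Hamming windows
with 1024 FFT points; log magnitudes are min-max normalized per spectrogram.
"""

import speechdep as sd

rec = sd.generate_speaker_audio(label=0, duration_s=4.0, effect=1.0, seed=7)
raw = sd.compute_log_spectrogram(rec.samples)
norm = sd.minmax_normalize(raw)

print(f"crop: {rec.duration:.1f} s at {rec.rate} Hz -> matrix {raw.matrix.shape}")
print(f"raw log-magnitude range:  [{raw.matrix.min():.2f}, {raw.matrix.max():.2f}]")
print(f"normalized range:         [{norm.matrix.min():.2f}, {norm.matrix.max():.2f}]")
print("513 frequency bins (1024-point FFT of real audio) x 125 time frames")
print("(floor(64000 samples / 512-sample hop)); every crop shares this shape.")
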