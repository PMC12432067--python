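"""Log-mel spectrogram front-end for the audio backbone.

Frames the waveform with a Hann window, takes the power spectrum and maps
it through a Slaney-style triangular mel filterbank, then log-compresses.
The front-end is fixed (not trained); it replaces the first layers of an
AudioSet-style tagging network so that fixed-length heart-sound waveforms
can be consumed directly.
"""

from __future__ import annotations

import numpy as np


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filters, shape (n_mels, n_fft // 2 + 1)."""
    if fmax is None:
        fmax = fs / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, bin_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    # Slaney area normalization keeps filter response comparable across bands
    enorm = 2.0 / (hz_pts[2:] - hz_pts[:-2])
    fb *= enorm[:, None]
    return fb


class LogMelFrontend:
    """Waveform batch (N, L) -> log-mel image batch (N, n_mels, n_frames, 1)."""

    def __init__(self, fs: float, n_fft: int = 256, hop: int = 80,
                 n_mels: int = 64, eps: float = 1e-10) -> None:
        self.fs, self.n_fft, self.hop, self.n_mels, self.eps = fs, n_fft, hop, n_mels, eps
        self.window = np.hanning(n_fft)
        self.fb = mel_filterbank(n_mels, n_fft, fs)

    def n_frames(self, n_samples: int) -> int:
        return 1 + (n_samples - self.n_fft) // self.hop if n_samples >= self.n_fft else 0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        n = self.n_frames(x.shape[1])
        if n < 1:
            raise ValueError("signal shorter than one FFT frame")
        idx = np.arange(self.n_fft)[None, :] + self.hop * np.arange(n)[:, None]
        frames = x[:, idx] * self.window  # (N, n_frames, n_fft)
        power = np.abs(np.fft.rfft(frames, axis=2)) ** 2
        mel = power @ self.fb.T  # (N, n_frames, n_mels)
        logmel = np.log(mel + self.eps)
        return logmel.transpose(0, 2, 1)[:, :, :, None].astype(np.float32)
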