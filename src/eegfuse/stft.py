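"""Multichannel STFT analysis/synthesis with weighted overlap-add (WOLA).

All denoising in this package operates on one-sided short-time spectra of
real multichannel signals. Analysis and synthesis both apply a square-root
Hann taper, so identity processing is perfectly reconstructing at any hop
for which the shifted squared-window sum is strictly positive over the
signal support (guaranteed here by reflect padding of half a window at each
edge and explicit normalization by the window-overlap sum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = ["StftConfig", "MultichannelSpectrogram", "stft", "istft"]


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def _make_window(name: str, length: int) -> np.ndarray:
    if name == "sqrt_hann":
        w = np.sqrt(get_window("hann", length, fftbins=True))
    else:
        w = np.asarray(get_window(name, length, fftbins=True), dtype=float)
    return w.astype(np.float64)


@dataclass(frozen=True)
class StftConfig:
    """Framing parameters for the analysis/synthesis pair.

    ``window_ms`` is a physical duration; the number of samples per frame is
    ``round(window_ms * sample_rate / 1000)``, so at 200 Hz the default
    64 ms window is 13 samples.  The FFT length defaults to the next power
    of two at or above the window length (zero-padded analysis).
    """

    sample_rate: float
    window_ms: float = 64.0
    overlap_fraction: float = 0.5
    fft_length: int | None = None
    window_shape: str = "sqrt_hann"

    window_samples: int = field(init=False)
    hop_samples: int = field(init=False)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError(
                f"overlap_fraction must lie in [0, 1), got {self.overlap_fraction}"
            )
        win = int(round(self.window_ms * self.sample_rate / 1000.0))
        if win < 2:
            raise ValueError(
                f"window of {self.window_ms} ms at {self.sample_rate} Hz is "
                f"{win} samples; need at least 2"
            )
        hop = max(1, int(round(win * (1.0 - self.overlap_fraction))))
        object.__setattr__(self, "window_samples", win)
        object.__setattr__(self, "hop_samples", hop)
        nfft = self.fft_length if self.fft_length is not None else _next_pow2(win)
        if nfft < win:
            raise ValueError(
                f"fft_length ({nfft}) must be >= window_samples ({win})"
            )
        object.__setattr__(self, "fft_length", int(nfft))

    @property
    def n_bins(self) -> int:
        """One-sided spectrum size K = fft_length/2 + 1."""
        return self.fft_length // 2 + 1

    def window(self) -> np.ndarray:
        return _make_window(self.window_shape, self.window_samples)


@dataclass
class MultichannelSpectrogram:
    """Complex one-sided spectra, indexed (channel, frequency bin, frame).

    Frame ``l`` (0-based) covers time samples ``[l*hop - pad, l*hop - pad +
    window_samples)`` of the original signal, where ``pad`` is half a window
    of reflect padding applied on analysis.
    """

    values: np.ndarray  # complex, shape (M, K, T)
    config: StftConfig
    original_length: int

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("spectrogram values must be (channels, bins, frames)")
        if self.n_bins != self.config.fft_length // 2 + 1:
            raise ValueError(
                f"bin count {self.n_bins} inconsistent with fft_length "
                f"{self.config.fft_length} (expected {self.config.fft_length // 2 + 1})"
            )


def _frame_starts(n_padded: int, win: int, hop: int) -> np.ndarray:
    n_frames = max(1, int(np.ceil((n_padded - win) / hop)) + 1)
    return np.arange(n_frames) * hop


def stft(signal: np.ndarray, config: StftConfig) -> MultichannelSpectrogram:
    """One-sided STFT of a real (channels, samples) matrix.

    Raises ``ValueError`` if the signal is shorter than one analysis window
    or contains non-finite values.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if x.ndim != 2:
        raise ValueError("signal must be a (channels, samples) matrix")
    m, n = x.shape
    win = config.window_samples
    if n < win:
        raise ValueError(
            f"signal of length {n} is shorter than one analysis window; "
            f"need at least {win} samples"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf values")

    pad = win // 2
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    starts = _frame_starts(xp.shape[1], win, config.hop_samples)
    total = starts[-1] + win
    if total > xp.shape[1]:
        xp = np.pad(xp, ((0, 0), (0, total - xp.shape[1])))

    w = config.window()
    idx = starts[:, None] + np.arange(win)[None, :]
    frames = xp[:, idx] * w  # (M, T, win)
    spectra = np.fft.rfft(frames, n=config.fft_length, axis=-1)  # (M, T, K)
    return MultichannelSpectrogram(
        values=np.ascontiguousarray(spectra.transpose(0, 2, 1)),
        config=config,
        original_length=n,
    )


def istft(spec: MultichannelSpectrogram) -> np.ndarray:
    """Inverse STFT via windowed overlap-add, trimmed to the original length.

    With an unmodified spectrogram this inverts :func:`stft` to floating-point
    precision (the synthesis window matches the analysis window and the
    overlap-add is normalized by the shifted squared-window sum).
    """
    spec.validate()
    cfg = spec.config
    win = cfg.window_samples
    hop = cfg.hop_samples
    w = cfg.window()
    vals = spec.values.transpose(0, 2, 1)  # (M, T, K)
    frames = np.fft.irfft(vals, n=cfg.fft_length, axis=-1)[..., :win] * w

    m, n_frames, _ = frames.shape
    total = (n_frames - 1) * hop + win
    out = np.zeros((m, total))
    wsum = np.zeros(total)
    for l in range(n_frames):
        s = l * hop
        out[:, s : s + win] += frames[:, l]
        wsum[s : s + win] += w * w
    safe = np.where(wsum > 1e-12, wsum, 1.0)
    out /= safe

    pad = win // 2
    n = spec.original_length
    return out[:, pad : pad + n]
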