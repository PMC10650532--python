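"""Teager–Kaiser energy operator and spectrogram imaging of EEG channels.

The Teager–Kaiser energy operator (TKEO) estimates the instantaneous energy
of a signal and is sensitive to both amplitude and frequency, which makes it
a classic front end for seizure/normal discrimination. For a discrete series
g[n],

    Psi(g[n]) = g[n]^2 - g[n-1] * g[n+1]

and for a continuous signal g(t),

    Psi(g(t)) = g'(t)^2 - g(t) * g''(t)

(estimated here with central finite differences). For a pure sinusoid
A*cos(w n) the discrete operator is constant, A^2 sin^2(w), on the interior —
the closed form used as a test oracle.

Each channel is turned into a quantized 2D time–frequency image: TKEO (by
default) then short-time Fourier transform magnitude, log scale, min–max
normalized to 8-bit pixels, optionally resized to the square side a given
classifier expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import signal as sps

from .synthetic import EEGSegment

__all__ = [
    "TKEOSeries",
    "SpectrogramImage",
    "StftParams",
    "tkeo_discrete",
    "tkeo_continuous",
    "to_spectrogram",
    "resize_image",
    "save_png",
    "load_png",
]


@dataclass
class TKEOSeries:
    """Instantaneous-energy series (µV² scale).

    ``values`` has the same length as the input; ``valid_range`` is the
    index slice over which the operator is exactly defined. Samples outside
    it are filled by replicating the nearest interior value.
    """

    values: np.ndarray
    valid_range: slice


@dataclass
class SpectrogramImage:
    """Quantized 2D time–frequency image of one channel.

    ``pixels`` is a uint8 matrix (frequency bins x time frames, or N x N
    after a square resize).
    """

    pixels: np.ndarray
    source_channel: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixels must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def side(self) -> int | None:
        h, w = self.pixels.shape
        return h if h == w else None


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform parameters.

    Defaults: Hann window of sampling_rate/2 samples, 75% overlap, FFT
    length the next power of two >= the window, spectrogram cropped to the
    0-64 Hz band. The half-second window gives 2 Hz frequency resolution —
    enough to resolve the ~3 Hz discharge fundamental and its harmonics —
    and the band crop keeps the clinically relevant EEG range so that the
    seizure bands are not squeezed out of a small resized image.
    """

    window: str = "hann"
    nperseg: int | None = None       # default: sampling_rate // 2
    overlap_fraction: float = 0.75
    nfft: int | None = None          # default: next pow2 >= nperseg
    max_freq_hz: float | None = 64.0  # None: keep the full band

    def resolve(self, sampling_rate: float) -> tuple[int, int, int]:
        nperseg = self.nperseg or max(8, int(sampling_rate) // 2)
        noverlap = int(nperseg * self.overlap_fraction)
        nfft = self.nfft or int(2 ** np.ceil(np.log2(nperseg)))
        return nperseg, noverlap, nfft


def tkeo_discrete(x: np.ndarray) -> TKEOSeries:
    """Discrete TKEO: Psi[n] = x[n]^2 - x[n-1] x[n+1] on the interior.

    The two boundary samples replicate the nearest interior value.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample sequence")
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return TKEOSeries(psi, slice(1, x.size - 1))


def tkeo_continuous(x: np.ndarray, dt: float) -> TKEOSeries:
    """Continuous-signal TKEO, Psi = g'^2 - g g'', via central differences."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample sequence")
    if x.size < 5:
        raise ValueError("continuous TKEO needs at least 5 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    g1 = np.gradient(x, dt, edge_order=2)
    g2 = np.gradient(g1, dt, edge_order=2)
    psi = g1**2 - x * g2
    # two samples at each end involve one-sided differences
    psi[0] = psi[2]
    psi[1] = psi[2]
    psi[-1] = psi[-3]
    psi[-2] = psi[-3]
    return TKEOSeries(psi, slice(2, x.size - 2))


def to_spectrogram(
    segment: EEGSegment,
    channel: int = 0,
    stft_params: StftParams | None = None,
    apply_tkeo: bool = True,
) -> SpectrogramImage:
    """Convert one channel of a segment to a quantized spectrogram image.

    If ``apply_tkeo`` the TKEO energy series (not the raw trace) is
    transformed — the default pipeline ordering. The magnitude spectrogram
    is log-scaled then min–max normalized to integers in [0, 255]; a flat
    image (max == min) maps to all zeros.
    """
    params = stft_params or StftParams()
    if not 0 <= channel < segment.n_channels:
        raise ValueError(f"channel {channel} out of range")
    x = segment.samples[channel]
    if apply_tkeo:
        x = tkeo_discrete(x).values
    nperseg, noverlap, nfft = params.resolve(segment.sampling_rate)
    if nperseg > x.size:
        raise ValueError("STFT window longer than the segment")
    freqs, _, S = sps.spectrogram(
        x,
        fs=segment.sampling_rate,
        window=params.window,
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        mode="magnitude",
        detrend=False,
    )
    if params.max_freq_hz is not None:
        keep = freqs <= params.max_freq_hz
        if keep.any():
            S = S[keep]
    logS = np.log10(S + 1e-12)
    lo, hi = logS.min(), logS.max()
    if hi - lo < 1e-12:
        pixels = np.zeros_like(logS, dtype=np.uint8)
    else:
        pixels = np.round((logS - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return SpectrogramImage(pixels, source_channel=channel, label=segment.label)


def resize_image(image: SpectrogramImage, side: int) -> SpectrogramImage:
    """Bilinear resize to ``side`` x ``side`` (classifier input size)."""
    if side < 8:
        raise ValueError("side must be >= 8")
    h, w = image.pixels.shape
    if (h, w) == (side, side):
        return SpectrogramImage(image.pixels.copy(), image.source_channel, image.label)
    im = Image.fromarray(image.pixels, mode="L")
    out = np.asarray(im.resize((side, side), Image.BILINEAR))
    return SpectrogramImage(out, image.source_channel, image.label)


def save_png(image: SpectrogramImage, path: str | Path, sidecar: bool = True) -> Path:
    """Write an 8-bit grayscale PNG plus a JSON provenance sidecar."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="L").save(path)
    if sidecar:
        meta = {"label": image.label, "source_channel": image.source_channel}
        path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def load_png(path: str | Path) -> SpectrogramImage:
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("L"))
    meta_path = path.with_suffix(".json")
    label, channel = None, 0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        label = meta.get("label")
        channel = meta.get("source_channel", 0)
    return SpectrogramImage(pixels, source_channel=channel, label=label)
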