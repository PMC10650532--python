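"""Synthetic multichannel EEG with normal / preictal / ictal structure.

Real seizure-annotated EEG corpora cannot be redistributed, so the rest of
the pipeline is developed and tested against segments drawn from a seeded
generator that reproduces the spectral structure the classifier relies on:

* **normal** — 1/f ("pink") background activity only, modelled as a sum of
  ~40 random-phase sinusoids whose amplitudes decay as 1/f, plus a small
  white-noise floor.
* **preictal** — background plus a low-amplitude 7–9 Hz rhythmic drift,
  emulating the rhythmic buildup sometimes seen before seizure onset.
* **ictal** — background plus a high-amplitude ~3 Hz spike-wave train, the
  classic generalized seizure discharge morphology. The spike is a
  half-wave-rectified, sharpened sinusoid — a surrogate with a strong,
  learnable spectral signature rather than a biophysical model.

All randomness flows through ``numpy.random.Generator`` seeded from the
config, so identical configs yield bit-identical data.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LABELS",
    "GeneratorConfig",
    "EEGSegment",
    "generate_segment",
    "generate_dataset",
    "write_segments",
    "read_segments",
]

#: Recognised class labels, in canonical order.
LABELS = ("normal", "preictal", "ictal")

_N_BACKGROUND_COMPONENTS = 40
_BACKGROUND_BAND_HZ = (0.5, 45.0)
_PREICTAL_BAND_HZ = (7.0, 9.0)
_WHITE_NOISE_FRACTION = 0.1  # of background_amp


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic EEG generator.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz).
    n_channels : int
        Number of EEG channels, >= 1.
    segment_length_s : float
        Window length in seconds; the study protocol uses 1, 2 or 4 s.
    background_amp : float
        RMS scale (µV) of the 1/f background.
    ictal_spike_freq : float
        Spike-wave repetition rate (Hz); ~3 Hz for classic discharges.
    ictal_amp_ratio : float
        Spike-wave amplitude as a multiple (> 1) of ``background_amp``.
    preictal_drift_amp : float
        Amplitude (µV) of the preictal rhythmic drift.
    seed : int
        Base RNG seed; per-segment sub-seeds are derived from it.
    """

    sampling_rate: float = 256.0
    n_channels: int = 4
    segment_length_s: float = 4.0
    background_amp: float = 20.0
    ictal_spike_freq: float = 3.0
    ictal_amp_ratio: float = 5.0
    preictal_drift_amp: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        n = self.sampling_rate * self.segment_length_s
        if abs(n - round(n)) > 1e-9 or round(n) < 8:
            raise ValueError(
                "segment_length_s x sampling_rate must be an integer >= 8"
            )
        if self.ictal_amp_ratio <= 1:
            raise ValueError("ictal_amp_ratio must be > 1")
        if self.background_amp < 0 or self.preictal_drift_amp < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.segment_length_s))


@dataclass
class EEGSegment:
    """One labelled multichannel EEG window.

    ``samples`` is a (n_channels, n_samples) float array in µV.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _background(t: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """1/f background for one channel: random-phase sinusoids + white noise."""
    lo, hi = _BACKGROUND_BAND_HZ
    hi = min(hi, config.sampling_rate / 2 * 0.9)
    freqs = rng.uniform(lo, hi, _N_BACKGROUND_COMPONENTS)
    phases = rng.uniform(0.0, 2 * np.pi, _N_BACKGROUND_COMPONENTS)
    amps = 1.0 / freqs
    # normalize so the summed RMS is background_amp
    rms = np.sqrt(0.5 * np.sum(amps**2))
    if rms > 0:
        amps = amps * (config.background_amp / rms)
    x = np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    x += rng.normal(0.0, _WHITE_NOISE_FRACTION * config.background_amp, t.shape)
    return x


def _spike_wave(t: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Half-wave-rectified sharpened sinusoid: a spike-wave surrogate."""
    phase = rng.uniform(0.0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * config.ictal_spike_freq * t + phase)
    spikes = np.clip(carrier, 0.0, None) ** 3  # sharpen the positive lobe
    # slow after-wave component on the negative lobe
    wave = 0.4 * np.clip(-carrier, 0.0, None)
    s = spikes - wave
    s -= s.mean()
    peak = np.max(np.abs(s)) or 1.0
    return s / peak * config.ictal_amp_ratio * config.background_amp


def generate_segment(
    label: str,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> EEGSegment:
    """Generate one labelled EEG segment.

    ``seed`` overrides ``config.seed`` when given. Determinism: identical
    (label, config, seed) triplets give bit-identical samples.
    """
    config = config or GeneratorConfig()
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(config.n_samples) / config.sampling_rate
    channels = np.empty((config.n_channels, config.n_samples))
    for c in range(config.n_channels):
        x = _background(t, config, rng)
        if label == "preictal":
            f = rng.uniform(*_PREICTAL_BAND_HZ)
            phase = rng.uniform(0.0, 2 * np.pi)
            x = x + config.preictal_drift_amp * np.sin(2 * np.pi * f * t + phase)
        elif label == "ictal":
            x = x + _spike_wave(t, config, rng)
        channels[c] = x
    return EEGSegment(channels, config.sampling_rate, label, segment_id=f"{label}-seed{seed if seed is not None else config.seed}")


def generate_dataset(
    n_per_class: int, config: GeneratorConfig | None = None
) -> list[EEGSegment]:
    """Generate a balanced labelled dataset: ``n_per_class`` segments per label.

    Per-segment sub-seeds are derived deterministically from ``config.seed``
    via :class:`numpy.random.SeedSequence`, so the same config always yields
    the identical dataset.
    """
    config = config or GeneratorConfig()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(LABELS) * n_per_class)
    segments: list[EEGSegment] = []
    k = 0
    for label in LABELS:
        for i in range(n_per_class):
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            seg = generate_segment(label, config, seed=sub_seed)
            seg.segment_id = f"{label}-{i:04d}"
            segments.append(seg)
            k += 1
    return segments


# ---------------------------------------------------------------------------
# On-disk round trip: CSV (one row per sample, one column per channel) or EDF.
# ---------------------------------------------------------------------------

def write_segments(
    segments: Sequence[EEGSegment], path: str | Path, format: str = "csv"
) -> Path:
    """Write segments to ``path`` (a directory) with a JSON manifest.

    ``format`` is ``"csv"`` or ``"edf"``. One file per segment plus
    ``manifest.json`` mapping segment ids to labels and sampling rates.
    """
    if len(segments) == 0:
        raise ValueError("no segments to write")
    if format not in ("csv", "edf"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for seg in segments:
        fname = f"{seg.segment_id}.{format}"
        if format == "csv":
            _write_csv(seg, path / fname)
        else:
            _write_edf(seg, path / fname)
        manifest.append(
            {
                "segment_id": seg.segment_id,
                "label": seg.label,
                "sampling_rate": seg.sampling_rate,
                "file": fname,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_segments(path: str | Path) -> list[EEGSegment]:
    """Read back a directory written by :func:`write_segments`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    segments = []
    for entry in manifest:
        f = path / entry["file"]
        if f.suffix == ".csv":
            samples = _read_csv(f)
        elif f.suffix == ".edf":
            samples = _read_edf(f)
        else:  # pragma: no cover - manifest written by us
            raise ValueError(f"unsupported file {f}")
        segments.append(
            EEGSegment(samples, entry["sampling_rate"], entry["label"], entry["segment_id"])
        )
    return segments


def _write_csv(seg: EEGSegment, fname: Path) -> None:
    header = [f"ch{c}" for c in range(seg.n_channels)]
    with open(fname, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in seg.samples.T:
            w.writerow([f"{v:.9g}" for v in row])


def _read_csv(fname: Path) -> np.ndarray:
    data = np.loadtxt(fname, delimiter=",", skiprows=1, ndmin=2)
    return data.T


def edf_quantization_step(samples: np.ndarray) -> float:
    """Worst-case amplitude error of the 16-bit EDF encoding of ``samples``."""
    steps = []
    for ch in samples:
        pmin, pmax = float(ch.min()), float(ch.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        steps.append((pmax - pmin) / (32767 - (-32768)))
    return max(steps)


def _write_edf(seg: EEGSegment, fname: Path) -> None:
    """Minimal EDF writer: 16-bit samples, one data record per second.

    Classic EDF (not EDF+). Per-channel physical min/max come from the data
    itself, so quantization error is bounded by (max-min)/65535 per channel.
    """
    sr = seg.sampling_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    sr = int(round(sr))
    n_samp = seg.n_samples
    # pad to a whole number of 1 s records
    n_records = int(np.ceil(n_samp / sr))
    ns = seg.n_channels
    padded = np.zeros((ns, n_records * sr))
    padded[:, :n_samp] = seg.samples

    pmins, pmaxs, digital = [], [], []
    for ch in padded:
        pmin, pmax = float(ch.min()), float(ch.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled = (ch - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        digital.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),                      # version
            pad("X X X X", 80),               # patient id
            pad("Startdate X", 80),           # recording id
            pad("01.01.00", 8),               # start date
            pad("00.00.00", 8),               # start time
            pad(str(256 + ns * 256), 8),      # header bytes
            pad("", 44),                      # reserved
            pad(str(n_records), 8),
            pad("1", 8),                      # record duration (s)
            pad(str(ns), 4),
        ]
    )
    fields: list[bytes] = []
    for spec, width in [
        ([f"EEG ch{c}" for c in range(ns)], 16),   # labels
        (["" for _ in range(ns)], 80),             # transducer
        (["uV" for _ in range(ns)], 8),            # physical dimension
        ([f"{v:.6g}" for v in pmins], 8),
        ([f"{v:.6g}" for v in pmaxs], 8),
        (["-32768" for _ in range(ns)], 8),
        (["32767" for _ in range(ns)], 8),
        (["" for _ in range(ns)], 80),             # prefiltering
        ([str(sr) for _ in range(ns)], 8),         # samples per record
        (["" for _ in range(ns)], 32),             # reserved
    ]:
        fields.extend(pad(s, width) for s in spec)
    with open(fname, "wb") as fh:
        fh.write(header + b"".join(fields))
        for rec in range(n_records):
            for c in range(ns):
                fh.write(digital[c][rec * sr : (rec + 1) * sr].tobytes())


def _read_edf(fname: Path) -> np.ndarray:
    """Read an EDF file through MNE; returns samples in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(fname), preload=True, verbose="error")
    return raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned channels
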