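"""Chaotic permutation ciphers for spectrogram images.

Two classic measure-preserving chaotic maps are discretized to pixel
permutations of an N x N image:

* the **generalized baker map** — the unit square is cut into k vertical
  rectangles of widths n_1..n_k (sum = N); each rectangle is stretched
  horizontally and compressed vertically, sending columns to rows. With
  every n_i dividing N the discretized map

      r' = (N/n_i) (r - N_i) + s mod (N/n_i)
      s' = (n_i/N) (s - s mod (N/n_i)) + N_i

  (N_i = n_1 + ... + n_{i-1}, valid for N_i <= r < N_i + n_i) is a bijection
  of the grid;

* the **Arnold cat map** — (x, y) -> (x + y, x + 2y) mod N, an area-
  preserving torus automorphism. On a finite grid iterating it is a
  permutation with a finite period, so enough iterations return the
  original image.

These are permutation ciphers used as a pre-processing stage: pixel values
are relocated, never changed, so the image histogram is conserved exactly
and decryption is the exact inverse permutation. No diffusion stage or
security analysis is attempted.

Grid convention: 0-based (column r, row s) with the origin at the
bottom-left. When a permutation is applied to an image array (row 0 at the
top, as stored), rows are flipped to grid coordinates and back internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .features import SpectrogramImage

__all__ = [
    "BakerKey",
    "ArnoldKey",
    "PixelPermutation",
    "baker_continuous",
    "baker_discrete",
    "arnold_map",
    "arnold_period",
    "build_permutation",
    "encrypt_image",
    "decrypt_image",
    "key_to_json",
    "key_from_json",
]


@dataclass(frozen=True)
class BakerKey:
    """Discretized generalized baker-map key.

    ``partition`` n_1..n_k must sum to ``side`` and every n_i must divide
    ``side`` (required for the discretized map to be a bijection).
    """

    side: int
    partition: tuple[int, ...]
    iterations: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "partition", tuple(int(n) for n in self.partition))
        if self.side < 2:
            raise ValueError("side must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if sum(self.partition) != self.side:
            raise ValueError(
                f"partition {self.partition} must sum to side {self.side}"
            )
        for n in self.partition:
            if n < 1 or self.side % n != 0:
                raise ValueError(
                    f"every partition element must divide the side; got {n} for side {self.side}"
                )

    @property
    def offsets(self) -> tuple[int, ...]:
        """Cumulative offsets N_i = n_1 + ... + n_{i-1}."""
        return tuple(int(v) for v in np.concatenate([[0], np.cumsum(self.partition)[:-1]]))


@dataclass(frozen=True)
class ArnoldKey:
    """Arnold cat-map key: image side and iteration count."""

    side: int
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("side must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


Key = Union[BakerKey, ArnoldKey]


@dataclass
class PixelPermutation:
    """A bijection on the N x N pixel grid, with its exact inverse.

    ``mapping[i] = j`` means the pixel at grid-flat index i (= s*N + r)
    moves to grid-flat index j.
    """

    side: int
    mapping: np.ndarray
    inverse: np.ndarray

    @classmethod
    def from_mapping(cls, side: int, mapping: np.ndarray) -> "PixelPermutation":
        mapping = np.asarray(mapping, dtype=np.intp)
        n = side * side
        if mapping.shape != (n,) or not np.array_equal(np.sort(mapping), np.arange(n)):
            raise ValueError("mapping is not a bijection on the grid")
        inverse = np.empty_like(mapping)
        inverse[mapping] = np.arange(n)
        return cls(side, mapping, inverse)

    def inverted(self) -> "PixelPermutation":
        return PixelPermutation(self.side, self.inverse.copy(), self.mapping.copy())

    def apply(self, pixels: np.ndarray, inverse: bool = False) -> np.ndarray:
        """Apply the permutation to an image array (row 0 at the top)."""
        N = self.side
        if pixels.shape != (N, N):
            raise ValueError(f"image must be {N} x {N}, got {pixels.shape}")
        grid = np.flipud(pixels)  # grid coords: row index = s from the bottom
        mapping = self.inverse if inverse else self.mapping
        out = np.empty_like(grid).reshape(-1)
        out[mapping] = grid.reshape(-1)
        return np.flipud(out.reshape(N, N))


def baker_continuous(x: float, y: float) -> tuple[float, float]:
    """One step of the baker map of the unit square.

    (2x, y/2) on the left half, (2x - 1, y/2 + 1/2) on the right half.
    """
    if not (0 <= x < 1 and 0 <= y <= 1):
        raise ValueError("coordinates must satisfy 0 <= x < 1, 0 <= y <= 1")
    if x < 0.5:
        return 2 * x, y / 2
    return 2 * x - 1, y / 2 + 0.5


def baker_discrete(r: int, s: int, key: BakerKey) -> tuple[int, int]:
    """One step of the discretized generalized baker map on (column r, row s)."""
    N = key.side
    if not (0 <= r < N and 0 <= s < N):
        raise ValueError("indices out of range")
    for n_i, N_i in zip(key.partition, key.offsets):
        if N_i <= r < N_i + n_i:
            q = N // n_i
            r2 = q * (r - N_i) + s % q
            s2 = (s - s % q) // q + N_i
            return r2, s2
    raise AssertionError("partition does not cover the grid")  # pragma: no cover


def arnold_map(x: int, y: int, N: int) -> tuple[int, int]:
    """One step of the Arnold cat map on the N x N grid."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0 <= x < N and 0 <= y < N):
        raise ValueError("indices out of range")
    return (x + y) % N, (x + 2 * y) % N


def _single_step_mapping(key: Key) -> np.ndarray:
    """Grid-flat mapping array (index = s*N + r) for one map step."""
    N = key.side
    rr, ss = np.meshgrid(np.arange(N), np.arange(N))  # ss[s, r] = s
    r, s = rr.reshape(-1), ss.reshape(-1)
    if isinstance(key, ArnoldKey):
        r2 = (r + s) % N
        s2 = (r + 2 * s) % N
    else:
        r2 = np.empty_like(r)
        s2 = np.empty_like(s)
        for n_i, N_i in zip(key.partition, key.offsets):
            sel = (r >= N_i) & (r < N_i + n_i)
            q = N // n_i
            r2[sel] = q * (r[sel] - N_i) + s[sel] % q
            s2[sel] = (s[sel] - s[sel] % q) // q + N_i
    return s2 * N + r2


def build_permutation(key: Key) -> PixelPermutation:
    """Compose the key's single-step map ``iterations`` times."""
    if not isinstance(key, (BakerKey, ArnoldKey)):
        raise TypeError(f"unsupported key type {type(key).__name__}")
    step = _single_step_mapping(key)
    mapping = np.arange(key.side * key.side, dtype=np.intp)
    for _ in range(key.iterations):
        mapping = step[mapping]
    return PixelPermutation.from_mapping(key.side, mapping)


def arnold_period(N: int, max_iter: int = 10**6) -> int:
    """Period of the Arnold cat-map permutation on the N x N grid.

    Brute force: iterate the full-grid permutation until it returns to the
    identity.
    """
    step = _single_step_mapping(ArnoldKey(side=N, iterations=1))
    identity = np.arange(N * N, dtype=np.intp)
    mapping = step.copy()
    for k in range(1, max_iter + 1):
        if np.array_equal(mapping, identity):
            return k
        mapping = step[mapping]
    raise RuntimeError(f"period of N={N} exceeds {max_iter}")  # pragma: no cover


def encrypt_image(image: SpectrogramImage, permutation: PixelPermutation) -> SpectrogramImage:
    """Relocate pixels by the permutation; the pixel histogram is conserved."""
    if image.side != permutation.side:
        raise ValueError(
            f"image side {image.side} does not match key side {permutation.side}"
        )
    out = permutation.apply(image.pixels)
    return SpectrogramImage(out, image.source_channel, image.label)


def decrypt_image(image: SpectrogramImage, permutation: PixelPermutation) -> SpectrogramImage:
    """Exact inverse of :func:`encrypt_image` for the same permutation."""
    if image.side != permutation.side:
        raise ValueError(
            f"image side {image.side} does not match key side {permutation.side}"
        )
    out = permutation.apply(image.pixels, inverse=True)
    return SpectrogramImage(out, image.source_channel, image.label)


def key_to_json(key: Key, path: str | Path | None = None) -> str:
    """Serialize a key to JSON ({type, N, partition, iterations})."""
    if isinstance(key, BakerKey):
        obj = {"type": "baker", "N": key.side, "partition": list(key.partition),
               "iterations": key.iterations}
    else:
        obj = {"type": "arnold", "N": key.side, "iterations": key.iterations}
    text = json.dumps(obj)
    if path is not None:
        Path(path).write_text(text)
    return text


def key_from_json(source: str | Path) -> Key:
    """Load a key from a JSON string or file path."""
    p = Path(source) if not str(source).lstrip().startswith("{") else None
    text = p.read_text() if p is not None else str(source)
    obj = json.loads(text)
    if obj["type"] == "baker":
        return BakerKey(obj["N"], tuple(obj["partition"]), obj.get("iterations", 1))
    if obj["type"] == "arnold":
        return ArnoldKey(obj["N"], obj.get("iterations", 1))
    raise ValueError(f"unknown key type {obj['type']!r}")
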