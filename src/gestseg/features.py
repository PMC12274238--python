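"""Pluggable per-frame feature extraction.

The pipeline's trained component sits on top of a frozen image-to-vector
transform.  In the original design this is a pretrained vision transformer;
here extraction is a contract (:class:`FeatureExtractor`) with deterministic
built-in implementations that need no downloaded weights, plus a registry so
external adapters (e.g. a pretrained backbone) can be plugged in by name.

Extractors are pure functions of pixels: same frame in, same vector out,
constant output dimension, never trainable.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from .ingest import InputSequence


class FeatureExtractor(ABC):
    """Frozen frame -> feature-vector transform."""

    name: str = "base"
    input_range: tuple[float, float] = (-1.0, 1.0)
    output_dim: int = 0
    trainable: bool = False  # by contract, never updated during training

    @abstractmethod
    def extract(self, frame: np.ndarray) -> np.ndarray:
        """Feature vector of shape ``(output_dim,)`` for one preprocessed frame."""

    def extract_batch(self, frames: np.ndarray) -> np.ndarray:
        out = np.stack([self.extract(f) for f in frames])
        if out.shape[1] != self.output_dim:
            raise RuntimeError(
                f"extractor {self.name!r} produced dim {out.shape[1]}, "
                f"declared {self.output_dim}")
        return out


class HistogramExtractor(FeatureExtractor):
    """Per-channel 32-bin intensity histograms plus a gradient-magnitude
    histogram: 4 x 32 = 128 dimensions, each block normalized to sum to 1."""

    name = "histogram"
    output_dim = 128
    n_bins = 32

    def extract(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        lo, hi = self.input_range
        blocks = []
        for c in range(3):
            h, _ = np.histogram(frame[:, :, c], bins=self.n_bins, range=(lo, hi))
            blocks.append(h)
        gray = frame.mean(axis=2)
        gy, gx = np.gradient(gray)
        gmag = np.hypot(gx, gy)
        h, _ = np.histogram(gmag, bins=self.n_bins, range=(0.0, hi - lo))
        blocks.append(h)
        out = np.concatenate(blocks).astype(np.float64)
        n_px = frame.shape[0] * frame.shape[1]
        return out / n_px


class PatchStatExtractor(FeatureExtractor):
    """7x7 grid of per-patch mean and standard deviation per channel:
    7 x 7 x 2 x 3 = 294 dimensions.  Patch edges are symmetric so that a
    180-degree image rotation permutes the patch statistics."""

    name = "patchstat"
    output_dim = 294
    grid = 7

    @staticmethod
    def _edges(n: int, k: int) -> np.ndarray:
        return np.floor(np.linspace(0.0, n, k + 1) + 0.5).astype(int)

    def extract(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        ye = self._edges(frame.shape[0], self.grid)
        xe = self._edges(frame.shape[1], self.grid)
        feats = []
        for i in range(self.grid):
            for j in range(self.grid):
                patch = frame[ye[i]:ye[i + 1], xe[j]:xe[j + 1], :3]
                feats.extend(patch.mean(axis=(0, 1)))
                feats.extend(patch.std(axis=(0, 1)))
        return np.asarray(feats)


class ConstantExtractor(FeatureExtractor):
    """Emits the same vector for every frame; a no-signal control for
    extractor comparisons."""

    name = "constant"
    output_dim = 8

    def extract(self, frame: np.ndarray) -> np.ndarray:
        return np.ones(self.output_dim)


_BUILTINS = {
    "histogram": HistogramExtractor,
    "patchstat": PatchStatExtractor,
    "constant": ConstantExtractor,
}
_REGISTRY: dict[str, type[FeatureExtractor]] = dict(_BUILTINS)


def builtin_extractor(kind: str) -> FeatureExtractor:
    """Instantiate a registered extractor by name."""
    try:
        return _REGISTRY[kind]()
    except KeyError:
        raise ValueError(
            f"unknown extractor {kind!r}; available: {sorted(_REGISTRY)}") from None


def register_extractor(cls: type[FeatureExtractor]) -> type[FeatureExtractor]:
    """Register an adapter class (e.g. a pretrained-backbone wrapper) by its name."""
    _REGISTRY[cls.name] = cls
    return cls


@dataclass
class FeatureCache:
    """In-memory cache keyed by (video_id, start_frame, extractor name)."""

    store: dict[tuple[str, int, str], np.ndarray] = field(default_factory=dict)

    def get(self, key: tuple[str, int, str]) -> np.ndarray | None:
        return self.store.get(key)

    def put(self, key: tuple[str, int, str], value: np.ndarray) -> None:
        self.store[key] = value


def extract_sequence(extractor: FeatureExtractor, seq: InputSequence,
                     cache: FeatureCache | None = None) -> np.ndarray:
    """Feature sequence (window_len x output_dim) for one input sequence."""
    key = (seq.video_id, seq.start_frame, extractor.name)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    out = extractor.extract_batch(np.asarray(seq.frames))
    if cache is not None:
        cache.put(key, out)
    return out
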