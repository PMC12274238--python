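"""Whole-video inference: sliding windows, retained predictions, Bayes update.

Inference slides a 25-frame window over the video with a stride of 10
frames (15-frame overlap).  The first window contributes predictions for
all of its frames; every later window contributes only its last 10 frames.
The retained blocks tile the video, so each frame receives exactly one
prediction and no overlap resolution is needed afterwards.  Per-frame
softmax outputs are then refined sequentially with Bayes' theorem, using a
rolling mean of recent posteriors as the prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import DEFAULT_FPS, N_CLASSES, FrameLabelArray
from .ingest import chunk_sequences

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry; ``retain == window - overlap == stride``."""

    window: int = 25
    stride: int = 10
    retain: int = 10

    def __post_init__(self) -> None:
        if not (self.window > self.stride > 0):
            raise ValueError("require window > stride > 0")
        if self.retain != self.stride:
            raise ValueError("retain must equal stride (window - overlap)")


@dataclass
class ProbabilityTrack:
    """Per-frame class probabilities over one whole video; rows on the simplex."""

    video_id: str
    P: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[1] != N_CLASSES:
            raise ValueError(f"P must be (n_frames, {N_CLASSES})")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.P.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, P=self.P)
        path.with_suffix(".json").write_text(json.dumps(
            {"video_id": self.video_id, "fps": self.fps,
             "class_order": ["background", "G1", "G2", "G3", "G4", "G5"]}))

    @classmethod
    def load(cls, path: str | Path) -> "ProbabilityTrack":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path) as z:
            P = z["P"]
        return cls(video_id=meta["video_id"], P=P, fps=meta["fps"])


def sliding_window_predict(head, features: np.ndarray,
                           wc: WindowConfig = WindowConfig(),
                           video_id: str = "",
                           fps: float = DEFAULT_FPS) -> ProbabilityTrack:
    """Predict one probability row per frame of a whole video.

    ``features`` has shape ``(n_frames, dim)``.  Windows start at multiples
    of the stride; the first window's predictions are kept for all 25 frames,
    each later window only for its last ``retain`` frames; predictions on
    tail-padding frames are dropped.  The retained spans are contiguous and
    tile ``[0, n_frames)`` exactly.
    """
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    seqs = chunk_sequences(features, video_id=video_id,
                           window=wc.window, stride=wc.stride)
    X = np.stack([s.frames for s in seqs])
    probs = head.predict_proba(X)  # (n_windows, window, K)
    P = np.empty((n, probs.shape[2]))
    for wi, seq in enumerate(seqs):
        s = seq.start_frame
        first = 0 if wi == 0 else wc.window - wc.retain
        for j in range(first, wc.window):
            f = s + j
            if f < n:  # drop padded tail
                P[f] = probs[wi, j]
    return ProbabilityTrack(video_id=video_id, P=P, fps=fps)


def bayes_update(track: ProbabilityTrack, prior: np.ndarray | None = None,
                 window: int = 25) -> ProbabilityTrack:
    """Sequential Bayesian refinement of the per-frame probabilities.

    Frame ``f``'s posterior is proportional to ``prior_f * likelihood_f``,
    where the likelihood is the softmax row and ``prior_f`` is the
    renormalized mean of the preceding ``window`` posteriors (the supplied
    prior — uniform by default — for the first frame).  ``window=0`` keeps
    the supplied prior throughout, which under a uniform prior returns the
    input unchanged.  Rows are floored at 1e-12 before renormalization so a
    vanishing normalizer cannot occur.
    """
    K = track.P.shape[1]
    if prior is None:
        prior = np.full(K, 1.0 / K)
    prior = np.asarray(prior, dtype=np.float64)
    if prior.shape != (K,) or not np.isclose(prior.sum(), 1.0, atol=1e-6):
        raise ValueError("prior must be a length-6 simplex vector")
    post = np.empty_like(track.P)
    for f in range(track.n_frames):
        if window > 0 and f > 0:
            pf = post[max(0, f - window):f].mean(axis=0)
            pf = pf / pf.sum()
        else:
            pf = prior
        row = np.maximum(pf * track.P[f], PROB_FLOOR)
        post[f] = row / row.sum()
    return ProbabilityTrack(video_id=track.video_id, P=post, fps=track.fps)


def label_frames(track: ProbabilityTrack) -> FrameLabelArray:
    """Per-frame argmax labels; ties break toward the lower class index."""
    return FrameLabelArray(track.P.argmax(axis=1), fps=track.fps)
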