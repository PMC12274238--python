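"""From probability tracks to timestamped gesture segments.

Each class's one-vs-rest probability signal is mapped onto a normalized
1000-bin (per-mille) timeline, smoothed, and binarized with hysteresis
thresholding whose thresholds adapt to local prediction entropy: where the
signal is uncertain (high local entropy) the threshold relaxes, where it is
confident the criterion tightens.  The high/low hysteresis thresholds sit
0.1 above/below the adaptive threshold, which suppresses transient
high-frequency flips.  Maximal runs of the binary occupancy become
timestamped segments on the original video timeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import (
    DEFAULT_FPS,
    GESTURE_LABELS,
    AnnotationTrack,
    events_to_frame_labels,
)
from .inference import ProbabilityTrack


@dataclass(frozen=True)
class TimelineConfig:
    """Normalized-timeline segmentation parameters.

    ``entropy_mode`` selects the signal whose uncertainty modulates the
    threshold: ``"binary"`` uses the per-class binary entropy of the
    one-vs-rest signal itself; ``"full"`` uses the normalized entropy of the
    whole class distribution.
    """

    L: int = 1000
    smooth_window: int = 25
    entropy_window: int = 51
    base_threshold: float = 0.5
    gamma: float = 0.4
    hysteresis_offset: float = 0.1
    clamp: tuple[float, float] = (0.05, 0.95)
    entropy_mode: str = "binary"
    exclusive: bool = False

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("timeline length must be >= 2")
        if not 0.0 < self.base_threshold < 1.0:
            raise ValueError("base threshold must lie in (0, 1)")
        if self.entropy_mode not in ("binary", "full"):
            raise ValueError("entropy_mode must be 'binary' or 'full'")


@dataclass
class SegmentationResult:
    """Per-class binary occupancy on the per-mille timeline plus video-time segments."""

    video_id: str
    duration_s: float
    L: int
    occupancy: dict[int, np.ndarray] = field(default_factory=dict)
    segments: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    thresholds: dict[int, np.ndarray] = field(default_factory=dict)
    smoothed: dict[int, np.ndarray] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "video_id": self.video_id, "duration_s": self.duration_s, "L": self.L,
            "occupancy": {str(c): o.astype(int).tolist()
                          for c, o in self.occupancy.items()},
            "segments": {str(c): s for c, s in self.segments.items()},
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationResult":
        d = json.loads(Path(path).read_text())
        return cls(video_id=d["video_id"], duration_s=d["duration_s"], L=d["L"],
                   occupancy={int(c): np.asarray(o, dtype=np.int8)
                              for c, o in d["occupancy"].items()},
                   segments={int(c): [tuple(s) for s in segs]
                             for c, segs in d["segments"].items()})


def resample_permille(signal: np.ndarray, L: int = 1000) -> np.ndarray:
    """Linearly interpolate a per-frame signal onto ``L`` evenly spaced points.

    Constant signals are preserved exactly and a length-``L`` input is
    returned unchanged.  Fewer than two frames is degenerate (no timeline).
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.size
    if n < 2:
        raise ValueError("need at least two frames to build a normalized timeline")
    if n == L:
        return signal.copy()
    return np.interp(np.linspace(0.0, n - 1.0, L), np.arange(n), signal)


def smooth(signal: np.ndarray, window: int = 25) -> np.ndarray:
    """Centered moving average with reflected edges; ``window=1`` is identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    signal = np.asarray(signal, dtype=np.float64)
    if window == 1:
        return signal.copy()
    pad = window // 2
    padded = np.pad(signal, pad, mode="reflect")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p)
    return np.nan_to_num(h, nan=0.0)


def entropy_threshold(signal: np.ndarray, tc: TimelineConfig = TimelineConfig(),
                      entropy_signal: np.ndarray | None = None) -> np.ndarray:
    """Per-bin adaptive decision threshold from local prediction entropy.

    The local entropy H_b is the mean (binary, base-2, in [0, 1]) entropy of
    the signal over a centered window; the threshold is
    ``base + gamma * (0.5 - H_b)`` clamped to ``tc.clamp``.  Maximum local
    entropy therefore relaxes the threshold by ``gamma/2``; zero entropy
    tightens it by the same amount.
    """
    h = _binary_entropy(np.asarray(signal if entropy_signal is None
                                   else entropy_signal, dtype=np.float64))
    H = smooth(h, tc.entropy_window if tc.entropy_window % 2 else tc.entropy_window + 1)
    thr = tc.base_threshold + tc.gamma * (0.5 - H)
    return np.clip(thr, tc.clamp[0], tc.clamp[1])


def hysteresis_segment(signal: np.ndarray, threshold: np.ndarray,
                       offset: float = 0.1) -> np.ndarray:
    """Two-threshold hysteresis binarization.

    Scanning left to right from the OFF state: switch ON where the signal
    reaches ``threshold + offset`` (high threshold) and back OFF where it
    drops below ``threshold - offset`` (low threshold); dips that stay above
    the low threshold do not terminate a segment.
    """
    signal = np.asarray(signal, dtype=np.float64)
    threshold = np.asarray(threshold, dtype=np.float64)
    if signal.shape != threshold.shape:
        raise ValueError("signal and threshold trace must have the same length")
    out = np.zeros(signal.size, dtype=np.int8)
    on = False
    hi = threshold + offset
    lo = threshold - offset
    for b in range(signal.size):
        if not on and signal[b] >= hi[b]:
            on = True
        elif on and signal[b] < lo[b]:
            on = False
        out[b] = 1 if on else 0
    return out


def occupancy_to_segments(occupancy: np.ndarray, duration_s: float,
                          L: int | None = None) -> list[tuple[float, float]]:
    """Maximal runs of 1s mapped back to video time (bin b -> b * duration / L)."""
    occupancy = np.asarray(occupancy)
    L = L or occupancy.size
    change = np.flatnonzero(np.diff(occupancy)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [occupancy.size]])
    return [(s * duration_s / L, e * duration_s / L)
            for s, e in zip(starts, stops) if occupancy[s]]


def segment_video(track: ProbabilityTrack, tc: TimelineConfig = TimelineConfig(),
                  duration_s: float | None = None) -> SegmentationResult:
    """Full per-class post-processing of one video's probability track.

    For each gesture class: resample the one-vs-rest probability signal to
    the per-mille timeline, smooth, derive the entropy-adaptive threshold,
    apply hysteresis, and convert occupancy runs to timestamps.  In
    ``exclusive`` mode, bins claimed by several classes keep only the class
    with the largest smoothed probability there.
    """
    duration_s = (track.n_frames / track.fps) if duration_s is None else duration_s
    if tc.entropy_mode == "full":
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(track.P > 0, np.log2(track.P), 0.0)
        full_h = -(track.P * logp).sum(axis=1) / np.log2(track.P.shape[1])
        full_h_bins = smooth(resample_permille(full_h, tc.L), 1)
    res = SegmentationResult(video_id=track.video_id, duration_s=duration_s, L=tc.L)
    for c in GESTURE_LABELS:
        sig = resample_permille(track.P[:, c], tc.L)
        sm = smooth(sig, tc.smooth_window)
        if tc.entropy_mode == "full":
            thr = tc.base_threshold + tc.gamma * (0.5 - smooth(
                full_h_bins, tc.entropy_window if tc.entropy_window % 2
                else tc.entropy_window + 1))
            thr = np.clip(thr, tc.clamp[0], tc.clamp[1])
        else:
            thr = entropy_threshold(sm, tc)
        res.smoothed[c] = sm
        res.thresholds[c] = thr
        res.occupancy[c] = hysteresis_segment(sm, thr, tc.hysteresis_offset)
    if tc.exclusive:
        stack = np.stack([res.occupancy[c] for c in GESTURE_LABELS])
        strength = np.stack([res.smoothed[c] for c in GESTURE_LABELS])
        winner = strength.argmax(axis=0)
        multi = stack.sum(axis=0) > 1
        for ci, c in enumerate(GESTURE_LABELS):
            res.occupancy[c] = np.where(multi & (winner != ci), 0,
                                        res.occupancy[c]).astype(np.int8)
    for c in GESTURE_LABELS:
        res.segments[c] = occupancy_to_segments(res.occupancy[c], duration_s, tc.L)
    return res


def annotation_occupancy(track: AnnotationTrack, L: int = 1000,
                         fps: float = DEFAULT_FPS) -> dict[int, np.ndarray]:
    """Ground-truth per-class binary occupancy on the per-mille timeline."""
    labels = events_to_frame_labels(track, fps=fps).labels
    out = {}
    for c in GESTURE_LABELS:
        sig = resample_permille((labels == c).astype(np.float64), L)
        out[c] = (sig >= 0.5).astype(np.int8)
    return out
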