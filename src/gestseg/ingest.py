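"""Frame ingestion: decoding, normalization, and chunking into model inputs.

Videos are consumed as 25-fps frame streams.  Sources may be a directory of
numbered images, a ``.npy``/``.npz`` frame stack, or any container imageio
can decode.  Frames are resized to 299x299 RGB and scaled to the feature
extractor's declared input range, then chunked into 25-frame (1 s) input
sequences — non-overlapping for training, stride-10 for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

TARGET_SIZE = (299, 299)
SEQUENCE_LEN = 25

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class InputSequence:
    """A fixed-length window of consecutive preprocessed frames (or features).

    ``n_padded`` counts trailing frames that are repeats of the last real
    frame (tail padding); their predictions are dropped at assembly time.
    """

    video_id: str
    start_frame: int
    frames: np.ndarray
    n_padded: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("sequence must hold at least one frame")


def extract_frames(source: str | Path | np.ndarray, target_fps: float = 25.0,
                   source_fps: float | None = None) -> list[np.ndarray]:
    """Read frames from ``source`` and resample to ``target_fps``.

    Resampling picks the nearest source frame for each target time point —
    no frame interpolation, so every emitted frame is a real input frame.
    ``source_fps`` defaults to ``target_fps`` (no resampling).
    """
    if isinstance(source, np.ndarray):
        frames = list(source)
    else:
        path = Path(source)
        if not path.exists():
            raise IOError(f"unreadable frame source: {path}")
        if path.is_dir():
            files = sorted(p for p in path.iterdir()
                           if p.suffix.lower() in _IMAGE_SUFFIXES)
            import imageio.v3 as iio
            frames = [np.asarray(iio.imread(p)) for p in files]
        elif path.suffix == ".npy":
            frames = list(np.load(path))
        elif path.suffix == ".npz":
            with np.load(path) as z:
                frames = list(z[z.files[0]])
        else:
            import imageio.v3 as iio
            frames = [np.asarray(f) for f in iio.imiter(path)]
    if not frames:
        raise ValueError(f"no frames found in source {source!r}")

    if source_fps is None or source_fps == target_fps:
        return frames
    n_out = int(round(len(frames) * target_fps / source_fps))
    idx = np.clip(np.round(np.arange(n_out) * source_fps / target_fps).astype(int),
                  0, len(frames) - 1)
    return [frames[i] for i in idx]


def preprocess_frame(frame: np.ndarray, size: tuple[int, int] = TARGET_SIZE,
                     input_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Resize to ``size`` (bilinear) and scale uint8 RGB into ``input_range``."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 2:
        warnings.warn("grayscale frame: replicating channel to RGB", stacklevel=2)
        frame = np.repeat(frame[:, :, None], 3, axis=2)
    if frame.shape[2] > 3:
        frame = frame[:, :, :3]

    from skimage.transform import resize, resize_local_mean

    if frame.shape[:2] != size:
        downscale = frame.shape[0] > size[0] or frame.shape[1] > size[1]
        if downscale:
            # local-mean resampling conserves intensity under downscaling
            frame = resize_local_mean(frame.astype(np.float64), size,
                                      preserve_range=True)
        else:
            frame = resize(frame.astype(np.float64), size, order=1,
                           preserve_range=True)
    frame = frame.astype(np.float64)
    lo, hi = input_range
    return frame / 255.0 * (hi - lo) + lo


def chunk_sequences(frames: Sequence[np.ndarray] | np.ndarray, video_id: str = "",
                    window: int = SEQUENCE_LEN, stride: int = SEQUENCE_LEN
                    ) -> list[InputSequence]:
    """Chunk a frame (or feature) stream into fixed-length windows.

    Window starts advance by ``stride`` until every frame is covered; a final
    partial window is padded by repeating the last frame and flagged via
    ``n_padded``.  Training uses stride == window (non-overlapping); inference
    uses stride 10 (15-frame overlap).
    """
    frames = np.asarray(frames)
    n = len(frames)
    if n < 1:
        raise ValueError("need at least one frame")
    n_windows = 1 if n <= window else 1 + int(np.ceil((n - window) / stride))
    out = []
    for i in range(n_windows):
        s = i * stride
        chunk = frames[s:s + window]
        n_padded = window - len(chunk)
        if n_padded:
            chunk = np.concatenate([chunk, np.repeat(chunk[-1:], n_padded, axis=0)])
        out.append(InputSequence(video_id=video_id, start_frame=s,
                                 frames=chunk, n_padded=n_padded))
    return out
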