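"""Visual QA artifacts: timeline plots and misclassified/correct frame palettes.

Two kinds of figures support qualitative review: a four-panel per-class
timeline (probability with smoothed signal and adaptive threshold;
predicted occupancy; annotated occupancy; their overlap) and side-by-side
5x5 frame palettes pairing each misclassified sequence with a temporally
close correctly classified sequence of the same class and video.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages

from .annotation import AnnotationTrack, GestureClass
from .inference import ProbabilityTrack
from .postprocess import SegmentationResult, annotation_occupancy, resample_permille

logger = logging.getLogger(__name__)


def render_timeline_plot(track: ProbabilityTrack, seg: SegmentationResult,
                         truth: AnnotationTrack, gesture_label: int,
                         path: str | Path) -> Path:
    """Write the four-panel per-class timeline figure; x-axis in per-mille units."""
    c = gesture_label
    L = seg.L
    x = np.arange(L)
    sig = resample_permille(track.P[:, c], L)
    sm = seg.smoothed.get(c, sig)
    thr = seg.thresholds.get(c, np.full(L, np.nan))
    pred_occ = seg.occupancy[c].astype(bool)
    truth_occ = annotation_occupancy(truth, L=L, fps=track.fps)[c].astype(bool)
    overlap = pred_occ == truth_occ

    fig, axes = plt.subplots(4, 1, figsize=(10, 7), sharex=True,
                             gridspec_kw={"height_ratios": [3, 1, 1, 1]})
    ax = axes[0]
    ax.plot(x, sig, color="0.7", lw=0.6, label="P(x)")
    ax.plot(x, sm, color="black", lw=1.2, label="smoothed")
    ax.plot(x, thr, color="black", ls="--", lw=1.0, label="threshold")
    above = sm >= thr
    ax.fill_between(x, 0, sm, where=above, color="tab:green", alpha=0.3)
    ax.fill_between(x, 0, sm, where=~above, color="tab:red", alpha=0.2)
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    name = GestureClass.from_label(c)
    ax.set_title(f"{truth.video_id} — {name.name} ({name.display_name})")

    axes[1].fill_between(x, 0, 1, where=pred_occ, color="tab:orange", step="mid")
    axes[1].set_ylabel("predicted", fontsize=8)
    axes[2].fill_between(x, 0, 1, where=truth_occ, color="gold", step="mid")
    axes[2].set_ylabel("annotated", fontsize=8)
    axes[3].fill_between(x, 0, 1, where=overlap, color="black", step="mid")
    axes[3].set_ylabel("overlap", fontsize=8)
    for a in axes[1:]:
        a.set_yticks([])
    axes[3].set_xlabel("video progress (‰)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


@dataclass(frozen=True)
class SequenceRef:
    """Filename-style sequence metadata: class label, video id, sequence number."""

    class_label: int
    video_id: str
    seq_number: int


@dataclass
class PaletteMatcher:
    """Pairs misclassified sequences with unused correct ones.

    A match must share class label and video id and lie within ±10 sequence
    numbers (~10 s); the nearest |delta| wins, ties toward the earlier
    sequence, and each correct example is used at most once.
    """

    pool: Sequence[SequenceRef]
    max_delta: int = 10
    _used: set[SequenceRef] = field(default_factory=set)

    def match(self, mis: SequenceRef) -> SequenceRef | None:
        best = None
        for cand in self.pool:
            if cand in self._used:
                continue
            if cand.class_label != mis.class_label or cand.video_id != mis.video_id:
                continue
            d = abs(cand.seq_number - mis.seq_number)
            if d > self.max_delta:
                continue
            key = (d, cand.seq_number)
            if best is None or key < (abs(best.seq_number - mis.seq_number),
                                      best.seq_number):
                best = cand
        if best is not None:
            self._used.add(best)
        return best


def match_correct_example(mis: SequenceRef, pool: Sequence[SequenceRef],
                          used: set | None = None,
                          max_delta: int = 10) -> SequenceRef | None:
    """Functional form of :class:`PaletteMatcher` with caller-held ``used`` set."""
    m = PaletteMatcher(pool=pool, max_delta=max_delta, _used=used if used is not None else set())
    return m.match(mis)


def frames_to_palette(frames: np.ndarray, grid: tuple[int, int] = (5, 5)) -> np.ndarray:
    """Tile 25 consecutive frames into one image, row-major temporal order."""
    frames = np.asarray(frames)
    rows, cols = grid
    if len(frames) != rows * cols:
        raise ValueError(f"need {rows * cols} frames, got {len(frames)}")
    return np.concatenate(
        [np.concatenate(list(frames[r * cols:(r + 1) * cols]), axis=1)
         for r in range(rows)], axis=0)


def build_palette_document(pairs: Sequence[tuple[tuple[SequenceRef, np.ndarray],
                                                 tuple[SequenceRef, np.ndarray]]],
                           path: str | Path,
                           png_dir: str | Path | None = None) -> Path:
    """Write a multi-page PDF: one page per (misclassified, matched) pair.

    Each entry carries (metadata, 25 frames).  Pages that cannot be rendered
    (missing/short frame stacks) are skipped with a log entry.  An empty
    list yields a document with just the cover page.  With ``png_dir`` set,
    each palette is additionally saved as a standalone PNG whose filename
    encodes class/video/sequence metadata.
    """
    path = Path(path)
    png_dir = Path(png_dir) if png_dir else None
    with PdfPages(path) as pdf:
        fig = plt.figure(figsize=(8, 2))
        fig.text(0.5, 0.6, "Misclassified vs. correctly classified sequences",
                 ha="center", fontsize=14)
        fig.text(0.5, 0.3, f"{len(pairs)} pair(s)", ha="center", fontsize=10)
        pdf.savefig(fig)
        plt.close(fig)
        for (mis_ref, mis_frames), (cor_ref, cor_frames) in pairs:
            try:
                left = frames_to_palette(mis_frames)
                right = frames_to_palette(cor_frames)
            except (ValueError, TypeError) as exc:
                logger.warning("skipping palette page for %s: %s", mis_ref, exc)
                continue
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 6))
            for ax, img, ref, tag in ((ax1, left, mis_ref, "misclassified"),
                                      (ax2, right, cor_ref, "correct")):
                ax.imshow(img)
                ax.set_axis_off()
                ax.set_title(f"{tag}: G{ref.class_label} {ref.video_id} "
                             f"seq {ref.seq_number}", fontsize=9)
                if png_dir is not None:
                    png_dir.mkdir(parents=True, exist_ok=True)
                    import imageio.v3 as iio
                    iio.imwrite(png_dir / f"G{ref.class_label}_{ref.video_id}"
                                          f"_seq{ref.seq_number}_{tag}.png", img)
            pdf.savefig(fig)
            plt.close(fig)
    return path
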