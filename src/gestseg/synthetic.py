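"""Synthetic cohort, gesture-script, feature, and frame generation.

Emulates the study design the pipeline was built for: 10 novice and 7
experienced surgeons each performing up to three repetitions of the three
part-procedures of a robot-assisted radical prostatectomy (bladder-neck
dissection BND, neurovascular-bundle dissection NVBD, urethrovesical
anastomosis UVA).  Dissection gestures occur only in BND/NVBD, suturing
gestures only in UVA, and gesture durations average 9.6 s.  Every stage of
the pipeline can therefore be exercised without any external data.

Three generators are provided:

* :func:`generate_cohort` — ground-truth annotation tracks via a small
  Markov gesture grammar (lognormal gesture durations, exponential
  background gaps);
* :func:`generate_features` — per-frame feature matrices from a Gaussian
  class-conditional feature model (a stand-in for a frozen image encoder);
* :func:`render_frames` — procedural class-conditioned RGB frames so the
  image-based stages (ingest, extractors, palettes) can be tested on pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .annotation import (
    ALLOWED_CLASSES,
    DEFAULT_FPS,
    N_CLASSES,
    AnnotationEvent,
    AnnotationTrack,
    GestureClass,
    events_to_frame_labels,
)

#: default part-procedure video length: the emulated study's 161 videos span
#: 2565 minutes, i.e. ~956 s per video on average
DEFAULT_VIDEO_DURATION_S = 956.0

#: mean annotated gesture length in seconds
DEFAULT_MEAN_GESTURE_S = 9.6


@dataclass
class CohortSpec:
    """Who performs: cohort composition and determinism."""

    n_novice: int = 10
    n_experienced: int = 7
    repetitions: int = 3
    procedures: tuple[str, ...] = ("BND", "NVBD", "UVA")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_novice < 1 or self.n_experienced < 1 or self.repetitions < 1:
            raise ValueError("cohort counts must be >= 1")

    def surgeons(self) -> list[tuple[str, str]]:
        """(surgeon_id, experience) pairs, novices first."""
        return ([(f"N{i + 1:02d}", "novice") for i in range(self.n_novice)]
                + [(f"E{i + 1:02d}", "experienced") for i in range(self.n_experienced)])


@dataclass
class GestureGrammar:
    """What is performed: per-procedure gesture vocabulary and timing.

    Durations are lognormal with configurable mean (seconds) and log-scale
    sigma; right-skewed positive durations match how long surgical actions
    are distributed.  Background ("no gesture") gaps between events are
    exponential.  Transitions between gesture classes follow a uniform
    Markov chain over the procedure's allowed classes with a mild penalty
    on immediate self-repeats.
    """

    mean_gesture_s: float = DEFAULT_MEAN_GESTURE_S
    sigma_log: float = 0.5
    mean_gap_s: float = 2.0
    video_duration_s: float = DEFAULT_VIDEO_DURATION_S
    self_transition_weight: float = 0.25
    min_event_s: float = 0.5

    def allowed(self, procedure: str) -> tuple[GestureClass, ...]:
        return ALLOWED_CLASSES[procedure]

    def sample_duration(self, rng: np.random.Generator) -> float:
        mu = np.log(self.mean_gesture_s) - self.sigma_log ** 2 / 2.0
        return float(rng.lognormal(mean=mu, sigma=self.sigma_log))

    def sample_gap(self, rng: np.random.Generator) -> float:
        return float(rng.exponential(self.mean_gap_s)) if self.mean_gap_s > 0 else 0.0

    def sample_class(self, procedure: str, prev: GestureClass | None,
                     rng: np.random.Generator) -> GestureClass:
        classes = self.allowed(procedure)
        w = np.ones(len(classes))
        if prev in classes:
            w[classes.index(prev)] = self.self_transition_weight
        return classes[rng.choice(len(classes), p=w / w.sum())]


def _script_events(procedure: str, grammar: GestureGrammar,
                   rng: np.random.Generator) -> list[AnnotationEvent]:
    """Sample one video's gesture script: gap, gesture, gap, gesture, ..."""
    events: list[AnnotationEvent] = []
    t = grammar.sample_gap(rng)
    prev: GestureClass | None = None
    while True:
        dur = max(grammar.sample_duration(rng), grammar.min_event_s)
        stop = t + dur
        if stop > grammar.video_duration_s:
            # truncate the final gesture at the end of the video if enough remains
            if grammar.video_duration_s - t >= grammar.min_event_s:
                stop = grammar.video_duration_s
            else:
                break
        cls = grammar.sample_class(procedure, prev, rng)
        events.append(AnnotationEvent(cls, t, stop))
        prev = cls
        t = stop + grammar.sample_gap(rng)
        if t >= grammar.video_duration_s:
            break
    return events


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    grammar: GestureGrammar = GestureGrammar()) -> list[AnnotationTrack]:
    """Generate ground-truth tracks for the whole cohort.

    One track per (surgeon, procedure, repetition); fully reproducible under
    ``spec.seed`` (each track draws from an independently spawned stream, so
    changing cohort size does not reshuffle other tracks).
    """
    ss = np.random.SeedSequence(spec.seed)
    tracks: list[AnnotationTrack] = []
    for si, (surgeon_id, experience) in enumerate(spec.surgeons()):
        for pi, procedure in enumerate(spec.procedures):
            for rep in range(1, spec.repetitions + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=ss.entropy,
                                           spawn_key=(si, pi, rep)))
                events = _script_events(procedure, grammar, rng)
                tracks.append(AnnotationTrack(
                    video_id=f"{surgeon_id}_{procedure}_r{rep}",
                    duration_s=grammar.video_duration_s,
                    events=events, procedure=procedure, surgeon_id=surgeon_id,
                    experience=experience, repetition=rep))
    return tracks


@dataclass
class FeatureModel:
    """Gaussian class-conditional per-frame feature model.

    Stands in for the output of a frozen image encoder: each of the six
    states (background + 5 gestures) has a fixed mean direction in
    ``dim``-dimensional space at distance ``separation * noise_sd`` from the
    origin, and frames scatter around their state mean with isotropic noise
    of standard deviation ``noise_sd``.  Noise is temporally smoothed with a
    variance-preserving moving average so consecutive frames are correlated,
    as encoder features of consecutive video frames are; the class-mean
    signal itself stays crisp at gesture boundaries.
    """

    dim: int = 128
    separation: float = 3.0
    noise_sd: float = 1.0
    temporal_smoothing: int = 5
    class_means: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.class_means is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(0xFEA7,)))
            m = rng.standard_normal((N_CLASSES, self.dim))
            m /= np.linalg.norm(m, axis=1, keepdims=True)
            self.class_means = m * self.separation * self.noise_sd
        self.class_means = np.asarray(self.class_means, dtype=np.float64)
        if self.class_means.shape != (N_CLASSES, self.dim):
            raise ValueError("class_means must have shape (6, dim)")


def generate_features(track: AnnotationTrack, fm: FeatureModel,
                      seed: int, fps: float = DEFAULT_FPS) -> np.ndarray:
    """Per-frame feature matrix of shape ``(n_frames, fm.dim)`` for one track."""
    labels = events_to_frame_labels(track, fps=fps).labels
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((labels.size, fm.dim)) * fm.noise_sd
    w = int(fm.temporal_smoothing)
    if w > 1 and labels.size:
        kernel = np.ones(w) / np.sqrt(w)  # preserves per-frame noise variance
        pad = w // 2
        padded = np.pad(noise, ((pad, w - 1 - pad), (0, 0)), mode="reflect")
        noise = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="valid"), 0, padded)
    return fm.class_means[labels] + noise


# -- procedural frame rendering ------------------------------------------------

#: base RGB hue per state (background + G1..G5); chosen to be far apart so
#: color statistics separate the classes by construction
_CLASS_COLORS = np.array([
    [40, 40, 40],     # background: dark gray
    [200, 60, 60],    # G1: red
    [60, 200, 60],    # G2: green
    [60, 60, 200],    # G3: blue
    [200, 200, 60],   # G4: yellow
    [200, 60, 200],   # G5: magenta
], dtype=np.float64)


@dataclass
class RenderStyle:
    height: int = 64
    width: int = 64
    noise_amp: float = 10.0
    stripe_amp: float = 30.0
    stripe_period: int = 16


def render_frames(track: AnnotationTrack, style: RenderStyle = RenderStyle(),
                  seed: int = 0, fps: float = DEFAULT_FPS) -> Iterator[np.ndarray]:
    """Yield ``round(duration * fps)`` procedural RGB frames (uint8, HxWx3).

    Each gesture class gets a distinct base hue plus a moving stripe pattern
    (phase advances with the frame index) and seeded pixel noise — no attempt
    at photorealism, just class-separable, temporally coherent pixels.
    """
    labels = events_to_frame_labels(track, fps=fps).labels
    rng = np.random.default_rng(seed)
    yy = np.arange(style.height)[:, None] + np.zeros((1, style.width))
    for f, lab in enumerate(labels):
        base = _CLASS_COLORS[lab]
        phase = 2.0 * np.pi * (yy + f) / style.stripe_period
        stripes = style.stripe_amp * np.sin(phase)
        img = base[None, None, :] + stripes[:, :, None]
        img = img + rng.normal(0.0, style.noise_amp, size=img.shape)
        yield np.clip(img, 0, 255).astype(np.uint8)


def mean_gesture_duration(tracks: Sequence[AnnotationTrack]) -> float:
    """Empirical mean event duration over a cohort (seconds)."""
    durs = [ev.duration_s for t in tracks for ev in t.events]
    return float(np.mean(durs)) if durs else float("nan")
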