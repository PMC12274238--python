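"""Gesture taxonomy, annotation events, and event-list <-> frame-label conversion.

The annotation layer models what a human rater produces with event-logging
software such as BORIS: one timestamped row per gesture occurrence.  Five
surgical gesture classes are distinguished, three dissection gestures
(regular dissection, hemostatic control, clip application) and two suturing
gestures (needle handling, suturing).  Label ``0`` denotes background
("no gesture"), labels 1-5 the gesture classes G1-G5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FPS = 25.0

PROCEDURES = ("BND", "NVBD", "UVA")
EXPERIENCE_LEVELS = ("novice", "experienced")


class GestureGroup(str, Enum):
    DISSECTION = "dissection"
    SUTURING = "suturing"


class GestureClass(Enum):
    """The five-gesture taxonomy used for annotation.

    ``label`` is the integer code used in per-frame label arrays
    (background is 0 and is not a member of this enum).
    """

    G1 = (1, "Regular dissection", GestureGroup.DISSECTION,
          "Any instrument performs either blunt or sharp dissection")
    G2 = (2, "Hemostatic control", GestureGroup.DISSECTION,
          "Any instrument performs hemostatic control using monopolar or bipolar energy")
    G3 = (3, "Applications of clips", GestureGroup.DISSECTION,
          "A clip is applied to the tissue")
    G4 = (4, "Needle handling", GestureGroup.SUTURING,
          "One of the needle handlers is in touch with the needle")
    G5 = (5, "Suturing", GestureGroup.SUTURING,
          "The needle is in touch with the tissue")

    def __init__(self, label: int, display_name: str, group: GestureGroup,
                 definition: str) -> None:
        self.label = label
        self.display_name = display_name
        self.group = group
        self.definition = definition

    @classmethod
    def from_label(cls, label: int) -> "GestureClass":
        for g in cls:
            if g.label == int(label):
                return g
        raise ValueError(f"no gesture class with label {label!r}")

    @classmethod
    def from_code(cls, code: str) -> "GestureClass":
        code = str(code).strip().upper()
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown gesture code {code!r}") from None


BACKGROUND_LABEL = 0
N_CLASSES = 6  # background + 5 gestures
GESTURE_LABELS = tuple(g.label for g in GestureClass)

#: gesture classes permitted in each part-procedure (no suturing during the
#: dissection part-procedures, no dissection during the anastomosis)
ALLOWED_CLASSES = {
    "BND": (GestureClass.G1, GestureClass.G2, GestureClass.G3),
    "NVBD": (GestureClass.G1, GestureClass.G2, GestureClass.G3),
    "UVA": (GestureClass.G4, GestureClass.G5),
}


@dataclass(frozen=True)
class AnnotationEvent:
    """One timestamped gesture occurrence; the interval is half-open [start, stop)."""

    gesture: GestureClass
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"event start must be >= 0, got {self.start_s}")
        if self.stop_s <= self.start_s:
            raise ValueError(
                f"event stop ({self.stop_s}) must exceed start ({self.start_s})")

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class AnnotationTrack:
    """All gesture events of one video, with cohort metadata."""

    video_id: str
    duration_s: float
    events: list[AnnotationEvent] = field(default_factory=list)
    procedure: str = "BND"
    surgeon_id: str = ""
    experience: str = "novice"
    repetition: int = 1

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValueError(f"unknown experience level {self.experience!r}")
        if not 1 <= int(self.repetition) <= 3:
            raise ValueError("repetition must be in 1..3")
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.stop_s))
        for ev in self.events:
            if ev.stop_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"event {ev.gesture.name} [{ev.start_s}, {ev.stop_s}) extends "
                    f"past video duration {self.duration_s}")
        # events of the same class must not overlap each other
        last_stop: dict[GestureClass, float] = {}
        for ev in self.events:
            if ev.start_s < last_stop.get(ev.gesture, -np.inf) - 1e-9:
                raise ValueError(
                    f"overlapping {ev.gesture.name} events in video {self.video_id}")
            last_stop[ev.gesture] = max(last_stop.get(ev.gesture, -np.inf), ev.stop_s)

    def n_frames(self, fps: float = DEFAULT_FPS) -> int:
        return int(round(self.duration_s * fps))

    def to_dict(self) -> dict:
        return {
            "video_id": self.video_id,
            "duration_s": self.duration_s,
            "procedure": self.procedure,
            "surgeon_id": self.surgeon_id,
            "experience": self.experience,
            "repetition": self.repetition,
            "events": [
                {"gesture": ev.gesture.name, "start_s": ev.start_s, "stop_s": ev.stop_s}
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationTrack":
        events = [
            AnnotationEvent(GestureClass.from_code(e["gesture"]),
                            float(e["start_s"]), float(e["stop_s"]))
            for e in d.get("events", [])
        ]
        return cls(video_id=d["video_id"], duration_s=float(d["duration_s"]),
                   events=events, procedure=d.get("procedure", "BND"),
                   surgeon_id=d.get("surgeon_id", ""),
                   experience=d.get("experience", "novice"),
                   repetition=int(d.get("repetition", 1)))


@dataclass
class FrameLabelArray:
    """Per-frame integer labels (0 = background, 1..5 = gestures) at a fixed rate."""

    labels: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError("labels must lie in 0..5")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.labels.size / self.fps


@dataclass(frozen=True)
class TableDialect:
    """Column mapping / delimiter for BORIS-style event-table exports.

    Export layouts vary by software version, so the mapping is configuration,
    not a hard-coded schema.  Metadata columns are optional; when absent the
    corresponding track fields fall back to defaults.
    """

    delimiter: str = ","
    video_id: str = "video_id"
    gesture: str = "gesture"
    start: str = "start_s"
    stop: str = "stop_s"
    duration: str | None = "duration_s"
    procedure: str | None = "procedure"
    surgeon_id: str | None = "surgeon_id"
    experience: str | None = "experience"
    repetition: str | None = "repetition"


def read_annotation_events(path: str | Path,
                           dialect: TableDialect = TableDialect()) -> list[AnnotationTrack]:
    """Parse a delimited gesture-event table into one :class:`AnnotationTrack` per video.

    Raises a format error naming any missing required column and a row-level
    validation error (with 1-based data row numbers) for rows whose stop time
    does not exceed the start time.
    """
    df = pd.read_csv(path, sep=dialect.delimiter)
    required = {"video id": dialect.video_id, "gesture code": dialect.gesture,
                "start time": dialect.start, "stop time": dialect.stop}
    for role, col in required.items():
        if col not in df.columns:
            raise ValueError(f"annotation table is missing the {role} column {col!r}")

    bad = df[pd.to_numeric(df[dialect.stop], errors="coerce")
             <= pd.to_numeric(df[dialect.start], errors="coerce")]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad.index[:10])
        raise ValueError(f"rows with stop <= start in annotation table: rows {rows}")

    tracks: list[AnnotationTrack] = []
    for video_id, g in df.groupby(dialect.video_id, sort=True):
        events = [
            AnnotationEvent(GestureClass.from_code(r[dialect.gesture]),
                            float(r[dialect.start]), float(r[dialect.stop]))
            for _, r in g.iterrows()
        ]
        first = g.iloc[0]

        def opt(col: str | None, default):
            return first[col] if col and col in g.columns else default

        duration = float(opt(dialect.duration, max(e.stop_s for e in events)))
        tracks.append(AnnotationTrack(
            video_id=str(video_id), duration_s=duration, events=events,
            procedure=str(opt(dialect.procedure, "BND")),
            surgeon_id=str(opt(dialect.surgeon_id, "")),
            experience=str(opt(dialect.experience, "novice")),
            repetition=int(opt(dialect.repetition, 1)),
        ))
    return tracks


def write_annotation_events(tracks: Iterable[AnnotationTrack], path: str | Path,
                            dialect: TableDialect = TableDialect()) -> None:
    """Write tracks as a delimited event table readable by :func:`read_annotation_events`."""
    rows = []
    for t in tracks:
        for ev in t.events:
            rows.append({
                dialect.video_id: t.video_id,
                dialect.gesture: ev.gesture.name,
                dialect.start: ev.start_s,
                dialect.stop: ev.stop_s,
                **({dialect.duration: t.duration_s} if dialect.duration else {}),
                **({dialect.procedure: t.procedure} if dialect.procedure else {}),
                **({dialect.surgeon_id: t.surgeon_id} if dialect.surgeon_id else {}),
                **({dialect.experience: t.experience} if dialect.experience else {}),
                **({dialect.repetition: t.repetition} if dialect.repetition else {}),
            })
    columns = [c for c in (dialect.video_id, dialect.gesture, dialect.start,
                           dialect.stop, dialect.duration, dialect.procedure,
                           dialect.surgeon_id, dialect.experience, dialect.repetition)
               if c]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=dialect.delimiter, index=False)


def save_tracks_json(tracks: Iterable[AnnotationTrack], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in tracks], indent=1))


def load_tracks_json(path: str | Path) -> list[AnnotationTrack]:
    return [AnnotationTrack.from_dict(d) for d in json.loads(Path(path).read_text())]


def events_to_frame_labels(track: AnnotationTrack,
                           fps: float = DEFAULT_FPS) -> FrameLabelArray:
    """Rasterize a track onto per-frame labels.

    Frame ``f`` receives the label of the event containing its center time
    ``(f + 0.5) / fps``; frames covered by no event get background (0).
    Where events of different classes overlap, the later-starting event wins
    (the "current action" at that point in time); a warning is emitted.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = track.n_frames(fps)
    labels = np.zeros(n, dtype=np.int64)
    centers = (np.arange(n) + 0.5) / fps
    prev_stop = -np.inf
    for ev in track.events:  # sorted by start: later writers overwrite
        if ev.start_s < prev_stop - 1e-9:
            warnings.warn(
                f"overlapping events of different classes in video {track.video_id}; "
                "keeping the later-starting event", stacklevel=2)
        prev_stop = max(prev_stop, ev.stop_s)
        mask = (centers >= ev.start_s) & (centers < ev.stop_s)
        labels[mask] = ev.gesture.label
    return FrameLabelArray(labels, fps=fps)


def frame_labels_to_events(arr: FrameLabelArray) -> list[AnnotationEvent]:
    """Inverse of :func:`events_to_frame_labels`: maximal constant nonzero runs
    become events with frame-grid timestamps (needed to emit gesture timestamps).
    """
    labels = arr.labels
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    events = []
    for s, e in zip(starts, stops):
        lab = int(labels[s])
        if lab != BACKGROUND_LABEL:
            events.append(AnnotationEvent(GestureClass.from_label(lab),
                                          s / arr.fps, e / arr.fps))
    return events


def track_from_labels(arr: FrameLabelArray, video_id: str = "",
                      **metadata) -> AnnotationTrack:
    """Build a track whose events are the label runs of ``arr``."""
    return AnnotationTrack(video_id=video_id, duration_s=arr.duration_s,
                           events=frame_labels_to_events(arr), **metadata)
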