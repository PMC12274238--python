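"""Surgeon-grouped cross-validation and Monte-Carlo extractor comparison.

Videos of one surgeon are never split between train and test: the unit of
assignment is the surgeon.  The 7-fold plan places exactly one experienced
surgeon in each test fold and distributes novices round-robin so every test
fold keeps (to within one surgeon) the global experienced:novice ratio.
The fold's validation set reuses the next fold's test surgeons, keeping the
validation signal surgeon-disjoint from both train and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationTrack
from .head import LSTMGestureClassifier


@dataclass
class Fold:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class FoldPlan:
    k: int
    folds: list[Fold] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k,
             "folds": [{"train": list(f.train_ids), "val": list(f.val_ids),
                        "test": list(f.test_ids)} for f in self.folds]}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], folds=[
            Fold(tuple(f["train"]), tuple(f["val"]), tuple(f["test"]))
            for f in d["folds"]])


def _surgeon_table(tracks: Sequence[AnnotationTrack]) -> dict[str, str]:
    out: dict[str, str] = {}
    for t in tracks:
        prev = out.setdefault(t.surgeon_id, t.experience)
        if prev != t.experience:
            raise ValueError(f"surgeon {t.surgeon_id} has inconsistent experience")
    return out


def make_grouped_folds(tracks: Sequence[AnnotationTrack], k: int = 7,
                       seed: int = 0) -> FoldPlan:
    """Build a k-fold plan at surgeon granularity.

    Each fold's test set holds exactly one experienced surgeon plus a
    round-robin share of novices; the union of test sets covers every
    surgeon exactly once.  Raises a configuration error when fewer than
    ``k`` experienced surgeons are available.
    """
    surgeons = _surgeon_table(tracks)
    experienced = sorted(s for s, e in surgeons.items() if e == "experienced")
    novices = sorted(s for s, e in surgeons.items() if e == "novice")
    if len(experienced) < k:
        raise ValueError(
            f"need at least {k} experienced surgeons for a {k}-fold plan, "
            f"got {len(experienced)}")
    rng = np.random.default_rng(seed)
    experienced = list(rng.permutation(experienced))
    novices = list(rng.permutation(novices))

    test_sets: list[list[str]] = [[experienced[i]] for i in range(k)]
    for j, s in enumerate(experienced[k:]):
        test_sets[j % k].append(s)
    for j, s in enumerate(novices):
        test_sets[j % k].append(s)

    all_surgeons = set(surgeons)
    folds = []
    for i in range(k):
        test = tuple(sorted(test_sets[i]))
        val = tuple(sorted(test_sets[(i + 1) % k]))
        train = tuple(sorted(all_surgeons - set(test) - set(val)))
        folds.append(Fold(train_ids=train, val_ids=val, test_ids=test))
    return FoldPlan(k=k, folds=folds)


def tracks_for(tracks: Sequence[AnnotationTrack],
               surgeon_ids: Sequence[str]) -> list[AnnotationTrack]:
    ids = set(surgeon_ids)
    return [t for t in tracks if t.surgeon_id in ids]


def compare_extractors(extractors: Sequence,
                       sequences_by_extractor: Callable[[object], tuple[np.ndarray, np.ndarray, np.ndarray]],
                       n_splits: int = 5, split_fraction: float = 0.25,
                       seed: int = 0,
                       head_params: dict | None = None) -> pd.DataFrame:
    """Monte-Carlo cross-validation of candidate feature extractors.

    ``sequences_by_extractor(extractor)`` must return ``(X, y, groups)``:
    feature sequences ``(n, T, dim)``, frame labels ``(n, T)`` and a
    surgeon-id per sequence.  For each extractor, ``n_splits`` random
    surgeon-grouped train/validation splits are drawn and a fresh head is
    trained on each; the table reports mean and sd validation frame accuracy,
    ranked best-first.
    """
    if len(extractors) < 2:
        raise ValueError("need at least two extractors to compare")
    rng = np.random.default_rng(seed)
    params = {"epochs": 10, "patience": 3, **(head_params or {})}
    split_perms: list[np.ndarray] | None = None
    rows = []
    for ext in extractors:
        X, y, groups = sequences_by_extractor(ext)
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if split_perms is None:  # same surgeon splits for every extractor
            split_perms = [rng.permutation(len(uniq)) for _ in range(n_splits)]
        accs = []
        for split in range(n_splits):
            n_val = max(1, int(round(len(uniq) * split_fraction)))
            val_g = set(uniq[split_perms[split][:n_val]].tolist())
            val_mask = np.isin(groups, list(val_g))
            head = LSTMGestureClassifier(random_state=seed + split, **params)
            head.fit(X[~val_mask], y[~val_mask],
                     validation_data=(X[val_mask], y[val_mask]))
            accs.append(head.score(X[val_mask], y[val_mask]))
        name = getattr(ext, "name", str(ext))
        rows.append({"extractor": name, "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                     "n_splits": n_splits})
    return (pd.DataFrame(rows)
            .sort_values("mean_accuracy", ascending=False)
            .reset_index(drop=True))
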