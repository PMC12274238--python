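"""End-to-end synthetic experiments used for validation and benchmarking.

The headline experiment generates the default synthetic cohort (17 surgeons,
3 part-procedures) at a learnable class separation, trains the LSTM head on
one surgeon-grouped fold, runs sliding-window inference with Bayesian
aggregation on the held-out surgeons, and scores the retained-prediction
blocks: macro one-vs-rest AUC, macro F1, and per-class accuracy/specificity
over the five gesture classes.

Problem sizes default to a desk-scale reduction (2 repetitions of 90-s
videos) so a full run completes in minutes on one CPU; all sizes are
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import DEFAULT_FPS, GESTURE_LABELS, AnnotationTrack, events_to_frame_labels
from .crossval import make_grouped_folds, tracks_for
from .head import LSTMGestureClassifier
from .inference import WindowConfig, bayes_update, sliding_window_predict
from .ingest import chunk_sequences
from .metrics import class_metrics, macro_auc, macro_f1, to_retained_blocks
from .synthetic import CohortSpec, FeatureModel, GestureGrammar, generate_cohort


def _track_seed(base_seed: int, video_id: str) -> int:
    import zlib

    return (int(base_seed) * 1_000_003 + zlib.crc32(video_id.encode())) % (2 ** 31)


def sequences_from_tracks(tracks, fm: FeatureModel, base_seed: int,
                          window: int = 25, stride: int = 25,
                          fps: float = DEFAULT_FPS):
    """Training sequences (X, y, surgeon groups) for a list of tracks."""
    from .synthetic import generate_features

    Xs, ys, gs = [], [], []
    for t in tracks:
        feats = generate_features(t, fm, seed=_track_seed(base_seed, t.video_id),
                                  fps=fps)
        labels = events_to_frame_labels(t, fps=fps).labels
        for seq in chunk_sequences(feats, video_id=t.video_id,
                                   window=window, stride=stride):
            lab = labels[seq.start_frame:seq.start_frame + window]
            if len(lab) < window:  # pad labels like the features
                lab = np.concatenate([lab, np.repeat(lab[-1:], window - len(lab))])
            Xs.append(seq.frames)
            ys.append(lab)
            gs.append(t.surgeon_id)
    return np.stack(Xs), np.stack(ys), np.asarray(gs)


@dataclass
class HeadlineResult:
    auc: float
    f1: float
    accuracy_per_class: dict[int, float]
    specificity_per_class: dict[int, float]
    sensitivity_per_class: dict[int, float]
    n_blocks: int
    n_test_videos: int
    head: LSTMGestureClassifier | None = None
    extras: dict = field(default_factory=dict)

    @property
    def min_accuracy(self) -> float:
        return min(self.accuracy_per_class.values())

    @property
    def min_specificity(self) -> float:
        return min(self.specificity_per_class.values())


def run_headline_experiment(seed: int = 42, repetitions: int = 2,
                            video_duration_s: float = 90.0,
                            separation: float = 3.0, noise_sd: float = 1.0,
                            dim: int = 128, fold_index: int = 0,
                            epochs: int = 20, bayes_window: int = 25,
                            fps: float = DEFAULT_FPS) -> HeadlineResult:
    """Train on one grouped fold of the default cohort and score the held-out fold."""
    seed = int(seed) % (2 ** 31)
    spec = CohortSpec(n_novice=10, n_experienced=7, repetitions=repetitions,
                      seed=seed)
    grammar = GestureGrammar(video_duration_s=video_duration_s)
    tracks = generate_cohort(spec, grammar)
    fm = FeatureModel(dim=dim, separation=separation, noise_sd=noise_sd,
                      seed=seed)
    plan = make_grouped_folds(tracks, k=7, seed=seed)
    fold = plan.folds[fold_index]

    Xt, yt, _ = sequences_from_tracks(tracks_for(tracks, fold.train_ids), fm, seed,
                                      fps=fps)
    Xv, yv, _ = sequences_from_tracks(tracks_for(tracks, fold.val_ids), fm, seed,
                                      fps=fps)
    head = LSTMGestureClassifier(epochs=epochs, random_state=seed)
    head.fit(Xt, yt, validation_data=(Xv, yv))

    wc = WindowConfig()
    all_probs, all_preds, all_truth, all_vids = [], [], [], []
    test_tracks = tracks_for(tracks, fold.test_ids)
    from .synthetic import generate_features

    for t in test_tracks:
        feats = generate_features(t, fm, seed=_track_seed(seed, t.video_id),
                                  fps=fps)
        track_p = sliding_window_predict(head, feats, wc, video_id=t.video_id,
                                         fps=fps)
        track_p = bayes_update(track_p, window=bayes_window)
        truth = events_to_frame_labels(t, fps=fps).labels
        bp, bl, bt = to_retained_blocks(track_p.P, truth, block=wc.retain)
        all_probs.append(bp)
        all_preds.append(bl)
        all_truth.append(bt)
        all_vids.append(np.full(len(bl), t.video_id, dtype=object))
    probs = np.concatenate(all_probs)
    preds = np.concatenate(all_preds)
    truth = np.concatenate(all_truth)

    auc = macro_auc(probs, truth)
    f1 = macro_f1(preds, truth)
    acc, spec_, sens = {}, {}, {}
    for c in GESTURE_LABELS:
        cm = class_metrics(preds, truth, c)
        acc[c] = cm.accuracy
        spec_[c] = cm.specificity
        sens[c] = cm.sensitivity
    return HeadlineResult(auc=auc, f1=f1, accuracy_per_class=acc,
                          specificity_per_class=spec_, sensitivity_per_class=sens,
                          n_blocks=len(truth), n_test_videos=len(test_tracks),
                          head=head,
                          extras={"history": head.history_,
                                  "video_ids": np.concatenate(all_vids)})


def run_low_noise_segmentation(seed: int = 0, video_duration_s: float = 120.0,
                               noise_sd: float = 0.05, separation: float = 60.0,
                               fps: float = DEFAULT_FPS):
    """Near-noiseless end-to-end check: generate one video, train a small head
    quickly, infer, segment, and return per-class Total Agreement vs. truth.

    At vanishing feature noise the whole pipeline should recover the script's
    per-class occupancy almost exactly (boundaries blur by at most the
    smoothing window).
    """
    from .metrics import total_agreement
    from .postprocess import TimelineConfig, annotation_occupancy, segment_video

    seed = int(seed) % (2 ** 31)
    spec = CohortSpec(n_novice=2, n_experienced=7, repetitions=1, seed=seed)
    grammar = GestureGrammar(video_duration_s=video_duration_s)
    tracks = generate_cohort(spec, grammar)
    # keep separation/noise_sd ratio extreme so features are essentially clean
    fm = FeatureModel(dim=32, separation=separation, noise_sd=noise_sd, seed=seed)
    train_tracks = [t for t in tracks if t.surgeon_id != "E01"]
    test_track = next(t for t in tracks if t.surgeon_id == "E01"
                      and t.procedure == "BND")
    Xt, yt, _ = sequences_from_tracks(train_tracks, fm, seed, fps=fps)
    head = LSTMGestureClassifier(epochs=8, patience=3, random_state=seed)
    head.fit(Xt, yt)
    from .synthetic import generate_features

    feats = generate_features(test_track, fm,
                              seed=_track_seed(seed, test_track.video_id), fps=fps)
    ptrack = bayes_update(sliding_window_predict(
        head, feats, video_id=test_track.video_id, fps=fps))
    seg = segment_video(ptrack, TimelineConfig(),
                        duration_s=test_track.duration_s)
    truth_occ = annotation_occupancy(test_track, L=seg.L, fps=fps)
    return {c: total_agreement(seg.occupancy[c], truth_occ[c]).value
            for c in GESTURE_LABELS}
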