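"""Labelling HMM states against experimental conditions and scoring decoders.

A fitted behavioural HMM yields anonymous states; this module gives them
meaning.  For block designs each condition claims the state whose binarised
Viterbi path best overlaps (Jaccard index) the condition's cue boxcar, and
every unclaimed state joins a pooled "rest" meta-state.  For unconstrained
movement (dance), states are characterised by regressing their paths against
per-key-point speeds (heat maps) and pooled into limb meta-states.  Decoding
quality is quantified with per-frame confusion matrices, Dice/F1, one-vs-all
ROC AUC, circular-shift permutation p-values and split-half cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hmm import StateDecoding, binarize_state, fit_hmm, forward_backward, viterbi_path
from .telemetry import SpeedMatrix, concatenate_sessions

__all__ = [
    "ConditionTimeline",
    "StateLabelMap",
    "HeatMap",
    "DecodingReport",
    "jaccard",
    "label_states",
    "pool_meta_state",
    "state_heatmap",
    "fractional_occupancy",
    "confusion_and_f1",
    "roc_auc",
    "permutation_null",
    "split_half_cv",
    "movement_durations",
]

REST = "rest"


@dataclass
class ConditionTimeline:
    """Binary per-frame boxcars for each experimental condition."""

    conditions: list[str]
    boxcars: np.ndarray            # (frames, n_conditions) in {0, 1}
    frame_rate: float

    def __post_init__(self) -> None:
        self.boxcars = np.asarray(self.boxcars)
        if self.boxcars.ndim != 2 or self.boxcars.shape[1] != len(self.conditions):
            raise ValueError("boxcars must be (frames, n_conditions)")
        if not np.isin(self.boxcars, (0, 1)).all():
            raise ValueError("boxcars must be binary")

    @property
    def n_frames(self) -> int:
        return self.boxcars.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.boxcars[:, self.conditions.index(name)]

    @classmethod
    def from_events(cls, path: str | Path, frame_rate: float,
                    n_frames: int) -> "ConditionTimeline":
        """Build boxcars from a BIDS-style events table (onset, duration,
        trial_type; seconds)."""
        df = pd.read_csv(path, sep="\t")
        conditions = sorted(df["trial_type"].unique())
        box = np.zeros((n_frames, len(conditions)), dtype=int)
        for _, row in df.iterrows():
            c = conditions.index(row["trial_type"])
            a = int(round(row["onset"] * frame_rate))
            b = int(round((row["onset"] + row["duration"]) * frame_rate))
            box[max(a, 0):min(b, n_frames), c] = 1
        return cls(conditions, box, frame_rate)

    def to_events(self, path: str | Path) -> None:
        rows = []
        for ci, name in enumerate(self.conditions):
            x = np.r_[0, self.boxcars[:, ci], 0]
            on = np.flatnonzero(np.diff(x) == 1)
            off = np.flatnonzero(np.diff(x) == -1)
            for a, b in zip(on, off):
                rows.append({"onset": a / self.frame_rate,
                             "duration": (b - a) / self.frame_rate,
                             "trial_type": name})
        pd.DataFrame(rows).sort_values("onset").to_csv(path, sep="\t", index=False)


@dataclass
class StateLabelMap:
    """Condition -> HMM state assignment plus the rest meta-state."""

    mapping: dict[str, set[int]]
    rest_states: set[int]
    jaccard_scores: np.ndarray       # (n_conditions, k)
    conditions: list[str] = field(default_factory=list)


@dataclass
class HeatMap:
    """Per-key-point regression weight of z-speed on a binary state path."""

    coefficients: np.ndarray         # (keypoints,)
    state: object = None
    keypoint_names: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"keypoint": self.keypoint_names,
                      "coefficient": self.coefficients}).to_csv(path, index=False)


@dataclass
class DecodingReport:
    """Per-frame multi-class decoding quality summary."""

    classes: list[str]
    confusion: np.ndarray            # (n_classes, n_classes) counts, rows = truth
    per_class_dice: np.ndarray
    f1_macro: float
    auc_per_class: np.ndarray | None = None
    auc_macro: float | None = None
    permutation_p: float | None = None


# ---------------------------------------------------------------------------
# similarity and labelling


def jaccard(a, b) -> float:
    """Intersection-over-union of two binary sequences (0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float((a & b).sum() / union)


def label_states(decoding: StateDecoding,
                 timeline: ConditionTimeline) -> StateLabelMap:
    """Assign each condition the state with the highest Jaccard overlap.

    Overlap is computed between each state's binarised Viterbi path and the
    condition boxcar.  Conditions claim states greedily in descending Jaccard
    order, so two conditions never share a winner; everything unclaimed
    becomes the rest meta-state.
    """
    if decoding.n_frames != timeline.n_frames:
        raise ValueError("decoding and timeline frame counts differ")
    k = decoding.k
    n_cond = len(timeline.conditions)
    J = np.empty((n_cond, k))
    paths = np.stack([binarize_state(decoding, s) for s in range(k)])
    for c in range(n_cond):
        for s in range(k):
            J[c, s] = jaccard(timeline.boxcars[:, c], paths[s])

    mapping: dict[str, set[int]] = {}
    taken: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-J, axis=None), J.shape))[0]
    for c, s in order:
        name = timeline.conditions[c]
        if name in mapping or s in taken:
            continue
        mapping[name] = {int(s)}
        taken.add(int(s))
    missing = [c for c in timeline.conditions if c not in mapping]
    if missing:
        raise RuntimeError(f"no state available for condition(s) {missing}")
    rest = set(range(k)) - taken
    return StateLabelMap(mapping, rest, J, list(timeline.conditions))


def pool_meta_state(decoding: StateDecoding, states: set[int]) -> np.ndarray:
    """Logical OR of the binarised Viterbi paths of ``states``."""
    if not states:
        raise ValueError("empty state set")
    out = np.zeros(decoding.n_frames, dtype=int)
    for s in states:
        out |= binarize_state(decoding, s)
    return out


def state_heatmap(state_path, speeds: SpeedMatrix | np.ndarray,
                  state=None) -> HeatMap:
    """Regress each key-point's z-speed on a binary state regressor.

    With an intercept in the model the OLS slope equals
    mean(speed | state on) - mean(speed | state off), i.e. how much faster
    each body part moves when the state is active.
    """
    x = np.asarray(state_path, dtype=bool)
    values = speeds.values if isinstance(speeds, SpeedMatrix) else np.asarray(speeds)
    names = (speeds.keypoint_names if isinstance(speeds, SpeedMatrix)
             else [f"kp{j}" for j in range(values.shape[1])])
    if len(x) != values.shape[0]:
        raise ValueError("state path and speeds must have equal length")
    if x.all() or not x.any():
        raise ValueError("state never active or never inactive; "
                         "regression coefficient undefined")
    coef = values[x].mean(axis=0) - values[~x].mean(axis=0)
    return HeatMap(coef, state, list(names))


def fractional_occupancy(meta_paths: dict[str, np.ndarray] | list[np.ndarray]):
    """Per-frame across-session mean of each meta-state's binary path.

    ``meta_paths`` maps meta-state name -> (sessions, frames) binary array
    (or is a list of such arrays).  Returns a (frames, n_meta) array in
    [0, 1] (plus the names when a dict was given).
    """
    if isinstance(meta_paths, dict):
        names = list(meta_paths)
        arrays = [np.atleast_2d(np.asarray(meta_paths[n])) for n in names]
    else:
        names = None
        arrays = [np.atleast_2d(np.asarray(a)) for a in meta_paths]
    if not arrays:
        raise ValueError("no meta-states given")
    if any(a.shape[0] == 0 for a in arrays):
        raise ValueError("no sessions given")
    n_frames = {a.shape[1] for a in arrays}
    if len(n_frames) != 1:
        raise ValueError("sessions must be resampled to a common clock")
    fo = np.stack([a.mean(axis=0) for a in arrays], axis=1)
    return (fo, names) if names is not None else fo


# ---------------------------------------------------------------------------
# decoding quality


def _frame_labels(timeline: ConditionTimeline, include_rest: bool = True):
    """Collapse boxcars to one class label per frame (rest where none on)."""
    classes = list(timeline.conditions) + ([REST] if include_rest else [])
    lab = np.full(timeline.n_frames, -1, dtype=int)
    for c in range(len(timeline.conditions) - 1, -1, -1):
        lab[timeline.boxcars[:, c] == 1] = c
    if include_rest:
        lab[lab == -1] = len(timeline.conditions)
    elif (lab == -1).any():
        raise ValueError("frames without an active condition but no rest class")
    return lab, classes


def predicted_labels(decoding: StateDecoding, label_map: StateLabelMap,
                     include_rest: bool = True) -> np.ndarray:
    """Per-frame predicted class index from labelled Viterbi states."""
    conds = label_map.conditions
    lab = np.full(decoding.n_frames, len(conds) if include_rest else -1, dtype=int)
    for ci, name in enumerate(conds):
        on = pool_meta_state(decoding, label_map.mapping[name]).astype(bool)
        lab[on] = ci
    return lab


def confusion_and_f1(truth: np.ndarray, predicted: np.ndarray,
                     classes: list[str]) -> DecodingReport:
    """Per-frame multi-class confusion counts and macro F1 (mean Dice).

    ``truth``/``predicted`` are integer class labels per frame.  Per-class
    Dice = 2 TP / (2 TP + FP + FN); classes absent from the truth have an
    undefined Dice and are excluded from the macro average with a warning.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction must have equal length")
    n = len(classes)
    conf = np.zeros((n, n), dtype=int)
    np.add.at(conf, (truth, predicted), 1)
    dice = np.full(n, np.nan)
    for c in range(n):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        if conf[c].sum() == 0:
            warnings.warn(f"class {classes[c]!r} absent from truth; "
                          "excluded from macro F1")
            continue
        dice[c] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    f1 = float(np.nanmean(dice))
    return DecodingReport(list(classes), conf, dice, f1)


def roc_auc(scores: np.ndarray, truth: np.ndarray):
    """One-vs-all ROC AUC via the rank (Mann-Whitney) statistic.

    ``scores`` is (frames, n_classes) of class probabilities or any
    monotone score; ``truth`` is the integer class label per frame.  Ties
    are handled with midranks.  Returns (auc_per_class, auc_macro); classes
    with no positive or no negative frames are excluded with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    truth = np.asarray(truth)
    n_classes = scores.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = truth == c
        n_pos = int(pos.sum())
        n_neg = len(truth) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c} has no positives or no negatives; "
                          "AUC undefined")
            continue
        r = rankdata(scores[:, c])
        aucs[c] = (r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    valid = ~np.isnan(aucs)
    macro = float(aucs[valid].mean()) if valid.any() else float("nan")
    return aucs, macro


def permutation_null(metric, truth, path, n_perm: int = 999,
                     seed: int = 0) -> float:
    """Permutation p-value from circular time-shifts of the state path.

    Circular shifts destroy the alignment with the experimental timeline
    while preserving the path's run-length structure, giving a null for
    ``metric(truth, shifted_path)``.  p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    path = np.asarray(path)
    if len(path) < 2:
        raise ValueError("sequence too short to permute")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    observed = metric(truth, path)
    shifts = rng.integers(1, len(path), size=n_perm)
    null = np.array([metric(truth, np.roll(path, int(s))) for s in shifts])
    return float((1 + (null >= observed).sum()) / (1 + n_perm))


def movement_durations(path: np.ndarray, onsets_s: np.ndarray,
                       frame_rate: float, window_s: float = 8.0) -> np.ndarray:
    """Durations (s) of state-on runs attributable to cued trials.

    For each contiguous on-run of ``path``, the run is matched to a trial if
    it intersects [onset, onset + window_s); matched runs' lengths are
    returned (spurious runs between trials are ignored).  This estimates how
    long the subject actually moved per trial, cue-to-cessation.
    """
    x = np.r_[0, np.asarray(path, dtype=int), 0]
    on = np.flatnonzero(np.diff(x) == 1)
    off = np.flatnonzero(np.diff(x) == -1)
    durations = []
    for t0 in np.asarray(onsets_s, dtype=float):
        a = int(round(t0 * frame_rate))
        b = int(round((t0 + window_s) * frame_rate))
        runs = [(s, e) for s, e in zip(on, off) if s < b and e > a]
        if runs:
            total = sum(e - s for s, e in runs)
            durations.append(total / frame_rate)
    return np.asarray(durations)


# ---------------------------------------------------------------------------
# cross-validation


def _score_half(decoding: StateDecoding, label_map: StateLabelMap,
                timeline: ConditionTimeline) -> DecodingReport:
    truth, classes = _frame_labels(timeline)
    pred = predicted_labels(decoding, label_map)
    return confusion_and_f1(truth, pred, classes)


def split_half_cv(sessions: list[SpeedMatrix],
                  timelines: list[ConditionTimeline],
                  k: int, seed: int = 0, **fit_kw):
    """Split-half cross-validation of the decode-and-label pipeline.

    The HMM is fitted on the first half of the sessions and its states are
    labelled there; the held-out half is decoded with the *fitted* model
    (likelihood-based Viterbi assignment) and scored against its own
    timeline using the training labels.  Returns (train_report, test_report).
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for split-half CV")
    if len(sessions) != len(timelines):
        raise ValueError("one timeline per session required")
    half = len(sessions) // 2
    train = concatenate_sessions(sessions[:half])
    test = concatenate_sessions(sessions[half:])
    tl_train = ConditionTimeline(
        timelines[0].conditions,
        np.vstack([t.boxcars for t in timelines[:half]]),
        timelines[0].frame_rate)
    tl_test = ConditionTimeline(
        timelines[0].conditions,
        np.vstack([t.boxcars for t in timelines[half:]]),
        timelines[0].frame_rate)

    dec_train = fit_hmm(train, k, seed=seed, **fit_kw)
    label_map = label_states(dec_train, tl_train)

    post = forward_backward(dec_train.params, test)
    path = viterbi_path(dec_train.params, test)
    dec_test = StateDecoding(post, path, np.nan, dec_train.params)

    return _score_half(dec_train, label_map, tl_train), \
        _score_half(dec_test, label_map, tl_test)
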