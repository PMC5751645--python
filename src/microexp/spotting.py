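"""Micro-expression spotting: per-frame classification and interval post-processing.

Each frame is described by a 20-dimensional vector: the minimum and maximum of
every cell's mean motion-magnitude signal over a window of size tau centered on
the frame.  A discrete AdaBoost ensemble of depth-limited decision trees (35
weak learners by default) labels frames ME / non-ME.  Raw labels are then
post-processed: maximal ME runs are extracted, runs separated by a gap shorter
than ``max_dist`` are merged, runs shorter than ``min_micro_sz`` are dropped,
and each surviving interval's apex is its middle frame.

Spotting is scored per emotion event: a detected apex within delta*tau frames
of an unmatched ground-truth apex is a true positive, anything else a false
positive; the false-positive rate is FP divided by the number of ground-truth
micro-expressions.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .descriptors import CellSignal, DescriptorParams
from .errors import ModelFormatError, ShapeError, TrainingError
from .geometry import CELL_NAMES

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class MEInterval:
    """One detected or annotated micro-expression: inclusive frame interval + apex."""

    start: int
    end: int
    apex: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.start <= self.apex <= self.end:
            raise ShapeError(f"apex must lie in [start, end], got {self}")


@dataclass
class DetectorModel:
    """Boosted frame classifier plus the metadata needed to apply it safely."""

    classifier: AdaBoostClassifier
    cell_order: tuple[str, ...] = CELL_NAMES
    tau: int = 37
    n_estimators: int = 35
    tree_depth: int = 1
    seed: int = 0

    def save(self, path) -> None:
        payload = {
            "format": "microexp-detector",
            "version": _MODEL_FORMAT_VERSION,
            "cell_order": list(self.cell_order),
            "tau": self.tau,
            "n_estimators": self.n_estimators,
            "tree_depth": self.tree_depth,
            "seed": self.seed,
            "classifier": self.classifier,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if not isinstance(payload, dict) or payload.get("format") != "microexp-detector":
            raise ModelFormatError(f"{path}: not a detector model file")
        if payload.get("version") != _MODEL_FORMAT_VERSION:
            raise ModelFormatError(f"{path}: unsupported model version")
        if tuple(payload["cell_order"]) != CELL_NAMES:
            raise ModelFormatError(
                f"{path}: cell order {payload['cell_order']} does not match the "
                "canonical cell order"
            )
        return cls(
            classifier=payload["classifier"],
            cell_order=tuple(payload["cell_order"]),
            tau=payload["tau"],
            n_estimators=payload["n_estimators"],
            tree_depth=payload["tree_depth"],
            seed=payload["seed"],
        )


@dataclass
class SpottingScore:
    """Event-level spotting score: greedy one-to-one apex matching."""

    tp: int
    fp: int
    n_truth: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    # (truth index, detection index, |apex distance|) for each TP

    @property
    def detection_rate(self) -> float:
        if self.n_truth == 0:
            return 1.0 if self.fp == 0 else 0.0
        return self.tp / self.n_truth

    @property
    def false_positive_rate(self) -> float:
        """FP divided by the number of ground-truth micro-expressions."""
        if self.n_truth == 0:
            return 0.0 if self.fp == 0 else float("inf")
        return self.fp / self.n_truth


def extract_detection_feature(signals: CellSignal, t: int, tau: int) -> np.ndarray:
    """20-vector [min(w_c0), max(w_c0), ..., min(w_c9), max(w_c9)] at frame ``t``.

    The window [t - tau//2, t + tau//2] is clamped to the sequence.
    """
    T = len(signals)
    lo = max(t - tau // 2, 0)
    hi = min(t + tau // 2, T - 1)
    out = np.empty(20)
    for k, name in enumerate(CELL_NAMES):
        w = signals.series[name][lo:hi + 1]
        out[2 * k] = w.min()
        out[2 * k + 1] = w.max()
    return out


def detection_feature_matrix(signals: CellSignal, tau: int) -> np.ndarray:
    """(T, 20) matrix of detection features for every frame.

    Equivalent to stacking :func:`extract_detection_feature` over all t; uses
    sliding min/max filters with edge replication, which matches window
    clamping exactly (the replicated edge value is already in the window).
    """
    size = 2 * (tau // 2) + 1
    cols = []
    for name in CELL_NAMES:
        s = signals.series[name]
        cols.append(minimum_filter1d(s, size=size, mode="nearest"))
        cols.append(maximum_filter1d(s, size=size, mode="nearest"))
    return np.stack(cols, axis=1)


def label_frames(seq_len: int, apexes, tau: int, delta: float) -> np.ndarray:
    """Boolean ME/non-ME labels: frame t is ME iff |t - apex| < delta*tau
    for some ground-truth apex (strict inequality, real-valued threshold)."""
    labels = np.zeros(seq_len, dtype=bool)
    t = np.arange(seq_len)
    for apex in apexes:
        labels |= np.abs(t - apex) < delta * tau
    return labels


def balance_training_set(features: np.ndarray, labels: np.ndarray,
                         seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep all ME frames and subsample non-ME frames to the same count.

    Subsampling is without replacement and the combined set is shuffled, both
    driven by ``seed``.  If there are fewer non-ME than ME frames, all are
    kept and a warning is issued.
    """
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise TrainingError("no ME frames to train on")
    rng = np.random.default_rng(seed)
    me_idx = np.flatnonzero(labels)
    non_idx = np.flatnonzero(~labels)
    if len(non_idx) < len(me_idx):
        warnings.warn(
            f"only {len(non_idx)} non-ME frames for {len(me_idx)} ME frames; "
            "keeping all", stacklevel=2)
        keep_non = non_idx
    else:
        keep_non = rng.choice(non_idx, size=len(me_idx), replace=False)
    keep = np.concatenate([me_idx, keep_non])
    keep = keep[rng.permutation(len(keep))]
    return features[keep], labels[keep]


def train_spotter(features: np.ndarray, labels: np.ndarray,
                  n_estimators: int = 35, tree_depth: int = 1,
                  seed: int = 0, tau: int = 37) -> DetectorModel:
    """Train the discrete-boosting frame classifier (35 tree weak learners)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if features.ndim != 2 or features.shape[1] != 20:
        raise ShapeError(f"detection features must be (n, 20), got {features.shape}")
    if labels.all() or not labels.any():
        raise TrainingError("training data must contain both ME and non-ME frames")
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=tree_depth, random_state=0),
        n_estimators=n_estimators,
        random_state=seed,
    )
    clf.fit(features, labels.astype(int))
    return DetectorModel(classifier=clf, tau=tau, n_estimators=n_estimators,
                         tree_depth=tree_depth, seed=seed)


def predict_frames(model: DetectorModel, signals: CellSignal,
                   tau: int | None = None) -> np.ndarray:
    """Per-frame ME/non-ME prediction; the zero-signal prefix is forced non-ME."""
    tau = model.tau if tau is None else tau
    X = detection_feature_matrix(signals, tau)
    pred = model.classifier.predict(X).astype(bool)
    pred[: int(np.ceil(tau / 2))] = False
    return pred


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) pairs."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        return []
    d = np.diff(labels.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if labels[0]:
        starts.insert(0, 0)
    if labels[-1]:
        ends.append(len(labels) - 1)
    return list(zip(starts, ends))


def postprocess_intervals(raw: np.ndarray, min_micro_sz: int,
                          max_dist: int, merge_rule: str = "gap") -> list[MEInterval]:
    """Turn raw per-frame labels into micro-expression intervals.

    1. extract maximal ME runs; 2. repeatedly merge adjacent runs until no
    merge applies; 3. drop intervals with (end - start) < min_micro_sz;
    4. apex = floor((start + end) / 2).

    ``merge_rule="gap"`` (default) merges runs whose gap (s_i - e_{i-1}) is
    < max_dist — the reading where max_dist is a distance between clusters.
    ``merge_rule="printed"`` merges when the difference of the two run
    lengths is < max_dist, kept for fidelity experiments.
    """
    if merge_rule not in ("gap", "printed"):
        raise ValueError(f"unknown merge_rule {merge_rule!r}")
    intervals = _runs(raw)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(intervals)):
            s0, e0 = intervals[i - 1]
            s1, e1 = intervals[i]
            if merge_rule == "gap":
                do_merge = (s1 - e0) < max_dist
            else:
                do_merge = ((e1 - s1) - (e0 - s0)) < max_dist
            if do_merge:
                intervals[i - 1:i + 1] = [(s0, e1)]
                changed = True
                break
    return [
        MEInterval(start=s, end=e, apex=(s + e) // 2)
        for s, e in intervals
        if (e - s) >= min_micro_sz
    ]


def score_spotting(detected: list[MEInterval], truth_apexes, tau: int,
                   delta: float) -> SpottingScore:
    """Greedy nearest-first one-to-one matching of detected to truth apexes.

    A detection is a TP when it is matched to a truth apex with
    |apex_gt - apex_d| <= delta * tau; each truth apex matches at most one
    detection; unmatched detections are FPs.
    """
    truth = list(truth_apexes)
    thr = delta * tau
    pairs = sorted(
        (abs(ti_apex - det.apex), ti, di)
        for ti, ti_apex in enumerate(truth)
        for di, det in enumerate(detected)
    )
    matched_truth: set[int] = set()
    matched_det: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for dist, ti, di in pairs:
        if dist > thr:
            break
        if ti in matched_truth or di in matched_det:
            continue
        matched_truth.add(ti)
        matched_det.add(di)
        matches.append((ti, di, float(dist)))
    tp = len(matches)
    fp = len(detected) - tp
    return SpottingScore(tp=tp, fp=fp, n_truth=len(truth), matches=matches)
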