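"""Pipeline orchestration: training, detection, recognition and LOSO evaluation.

The evaluation protocol is leave-one-subject-out (LOSO): one fold per subject,
where the spotter and the recognizer are trained on every other subject's
sequences and tested on the held-out subject.  Reported metrics mirror the
standard micro-expression evaluation set: a per-frame ME/non-ME confusion
matrix (before and after interval post-processing), per-emotion detection rate
and false-positive rate from apex matching, and a 3-class recognition
confusion with accuracy and macro precision/recall/F1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import precision_recall_fscore_support

from .dataset import Dataset, SequenceRecord
from .descriptors import (CellSignal, DescriptorParams, DisplacementFeature,
                          compute_cell_signals, displacement_features)
from .errors import ParameterError
from .geometry import FacialCellGrid, define_cells, estimate_roll, normalize_roll
from .recognition import (CLASSES, ClassScore, ExpressionModel,
                          classify_expression, fit_expression_models)
from .spotting import (DetectorModel, MEInterval, SpottingScore,
                       balance_training_set, detection_feature_matrix,
                       label_frames, postprocess_intervals, predict_frames,
                       score_spotting, train_spotter)
from .utils import round_half_up

logger = logging.getLogger("microexp")


@dataclass(frozen=True)
class SpottingParams:
    """Spotting-stage knobs; min_micro_sz/max_dist default to tau//4 and 2*tau."""

    min_micro_sz: int | None = None
    max_dist: int | None = None
    n_estimators: int = 35
    tree_depth: int = 2
    merge_rule: str = "gap"

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ParameterError("n_estimators must be >= 1")
        if self.tree_depth < 1:
            raise ParameterError("tree_depth must be >= 1")
        if self.merge_rule not in ("gap", "printed"):
            raise ParameterError("merge_rule must be 'gap' or 'printed'")


@dataclass(frozen=True)
class RecognitionParams:
    pooling: str = "pool"
    cov_floor: float = 1e-6
    apex_source: str = "annotation"  # or "detected"

    def __post_init__(self) -> None:
        if self.pooling not in ("pool", "mean"):
            raise ParameterError("pooling must be 'pool' or 'mean'")
        if self.cov_floor <= 0:
            raise ParameterError("cov_floor must be > 0")
        if self.apex_source not in ("annotation", "detected"):
            raise ParameterError("apex_source must be 'annotation' or 'detected'")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters; nested dataclasses re-validate on construction."""

    descriptor: DescriptorParams = field(default_factory=DescriptorParams)
    spotting: SpottingParams = field(default_factory=SpottingParams)
    recognition: RecognitionParams = field(default_factory=RecognitionParams)
    seed: int = 0
    log_level: str = "INFO"

    @property
    def min_micro_sz(self) -> int:
        return (self.spotting.min_micro_sz
                if self.spotting.min_micro_sz is not None
                else self.descriptor.tau // 4)

    @property
    def max_dist(self) -> int:
        return (self.spotting.max_dist
                if self.spotting.max_dist is not None
                else 2 * self.descriptor.tau)

    def to_dict(self) -> dict:
        return {
            "descriptor": asdict(self.descriptor),
            "spotting": asdict(self.spotting),
            "recognition": asdict(self.recognition),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            descriptor=DescriptorParams(**d.get("descriptor", {})),
            spotting=SpottingParams(**d.get("spotting", {})),
            recognition=RecognitionParams(**d.get("recognition", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def loso_split(subjects) -> list[tuple[list[str], str]]:
    """One (train subjects, test subject) fold per subject."""
    subjects = sorted(set(subjects))
    if len(subjects) < 2:
        raise ParameterError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


def prepare_sequence(record: SequenceRecord,
                     config: PipelineConfig) -> tuple["np.ndarray", FacialCellGrid, CellSignal]:
    """Roll-normalize, place cells and compute cell signals for one sequence."""
    theta = estimate_roll(record.landmarks)
    if abs(theta) < 1e-9:
        frames, landmarks = record.frames, record.landmarks
    else:
        rotated = [normalize_roll(record.frames.frames[t], record.landmarks)[0]
                   for t in range(len(record.frames))]
        landmarks = normalize_roll(record.frames.frames[0], record.landmarks)[1]
        frames = replace(record.frames, frames=np.stack(rotated))
    grid = define_cells(landmarks)
    signals = compute_cell_signals(frames, grid, config.descriptor)
    return frames.frames, grid, signals


class _SequenceCache:
    """Per-sequence derived data, computed once and shared across folds."""

    def __init__(self, dataset: Dataset, config: PipelineConfig):
        self.config = config
        self.records: list[SequenceRecord] = []
        self.grids: dict[str, FacialCellGrid] = {}
        self.signals: dict[str, CellSignal] = {}
        self.features: dict[str, np.ndarray] = {}
        self.frame_labels: dict[str, np.ndarray] = {}
        tau = config.descriptor.tau
        for rec in dataset:
            if len(rec.frames) < tau:
                logger.warning("sequence %s shorter than tau=%d; skipped",
                               rec.sequence_id, tau)
                continue
            _, grid, signals = prepare_sequence(rec, config)
            self.records.append(rec)
            self.grids[rec.sequence_id] = grid
            self.signals[rec.sequence_id] = signals
            self.features[rec.sequence_id] = detection_feature_matrix(signals, tau)
            apexes = rec.annotations["apex"].tolist() if len(rec.annotations) else []
            self.frame_labels[rec.sequence_id] = label_frames(
                len(rec.frames), apexes, tau, config.descriptor.delta)

    def displacement(self, rec: SequenceRecord, apex: int) -> DisplacementFeature:
        return displacement_features(
            rec.frames, self.grids[rec.sequence_id], apex, self.config.descriptor)


def train_spotting_model(cache: _SequenceCache, train_records,
                         config: PipelineConfig, seed: int) -> DetectorModel:
    X = np.concatenate([cache.features[r.sequence_id] for r in train_records])
    y = np.concatenate([cache.frame_labels[r.sequence_id] for r in train_records])
    Xb, yb = balance_training_set(X, y, seed)
    return train_spotter(Xb, yb, n_estimators=config.spotting.n_estimators,
                         tree_depth=config.spotting.tree_depth, seed=seed,
                         tau=config.descriptor.tau)


def train_recognition_model(cache: _SequenceCache, train_records,
                            config: PipelineConfig) -> ExpressionModel:
    feats: dict[str, list[DisplacementFeature]] = {c: [] for c in CLASSES}
    for rec in train_records:
        for _, row in rec.annotations.iterrows():
            if row["label"] in feats:
                feats[row["label"]].append(cache.displacement(rec, int(row["apex"])))
    present = {c: f for c, f in feats.items() if f}
    missing = [c for c in CLASSES if c not in present]
    if missing:
        warnings.warn(f"classes {missing} absent from training fold; "
                      "recognizer trained on remaining classes", stacklevel=2)
    return fit_expression_models(present, cov_floor=config.recognition.cov_floor,
                                 pooling=config.recognition.pooling,
                                 classes=tuple(c for c in CLASSES if c in present))


def train_spotter_on_dataset(dataset: Dataset, config: PipelineConfig,
                             seed: int | None = None) -> DetectorModel:
    """Train the frame-level spotting model on a whole annotated dataset."""
    cache = _SequenceCache(dataset, config)
    return train_spotting_model(cache, cache.records, config,
                                config.seed if seed is None else seed)


def train_recognizer_on_dataset(dataset: Dataset,
                                config: PipelineConfig) -> ExpressionModel:
    """Fit the expression recognizer on a whole annotated dataset."""
    cache = _SequenceCache(dataset, config)
    return train_recognition_model(cache, cache.records, config)


def run_detection(dataset: Dataset, config: PipelineConfig,
                  model: DetectorModel) -> dict[str, list[MEInterval]]:
    """Detect micro-expression intervals in every (long enough) sequence."""
    cache = _SequenceCache(dataset, config)
    out: dict[str, list[MEInterval]] = {}
    for rec in cache.records:
        out[rec.sequence_id] = _detect_one(cache, rec, config, model)[1]
    return out


def _detect_one(cache: _SequenceCache, rec: SequenceRecord,
                config: PipelineConfig, model: DetectorModel
                ) -> tuple[np.ndarray, list[MEInterval]]:
    raw = predict_frames(model, cache.signals[rec.sequence_id],
                         config.descriptor.tau)
    intervals = postprocess_intervals(
        raw, config.min_micro_sz, config.max_dist,
        merge_rule=config.spotting.merge_rule)
    return raw, intervals


def run_full_pipeline(dataset: Dataset, config: PipelineConfig,
                      spotter: DetectorModel,
                      recognizer: ExpressionModel) -> pd.DataFrame:
    """Detect MEs and classify each detection; one output row per detected ME."""
    cache = _SequenceCache(dataset, config)
    rows = []
    for rec in cache.records:
        _, intervals = _detect_one(cache, rec, config, spotter)
        for iv in intervals:
            feature = cache.displacement(rec, iv.apex)
            score = classify_expression(feature, recognizer)
            row = {"sequence_id": rec.sequence_id, "start": iv.start,
                   "end": iv.end, "apex": iv.apex}
            row.update(score.as_row())
            rows.append(row)
    columns = ["sequence_id", "start", "end", "apex", "predicted_class",
               *(f"score_{c}" for c in CLASSES)]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class EvalReport:
    """Aggregated LOSO evaluation results.

    Confusion matrices are stored as raw counts; the ``summary`` view
    row-normalizes them to percentages (2 decimals, half-up) the way results
    tables are usually printed.
    """

    seed: int
    n_sequences: int
    n_events: int
    frame_confusion_raw: np.ndarray    # 2x2 counts, rows = actual (ME, non-ME)
    frame_confusion_post: np.ndarray
    detection_per_class: dict[str, dict[str, float]]
    detection_tp: int
    detection_fp: int
    recognition_true: list[str]
    recognition_pred: list[str]
    folds: list[dict] = field(default_factory=list)

    # -- detection ---------------------------------------------------------
    @property
    def detection_rate(self) -> float:
        return self.detection_tp / self.n_events if self.n_events else 1.0

    @property
    def false_positive_rate(self) -> float:
        return self.detection_fp / self.n_events if self.n_events else 0.0

    def frame_accuracy(self, stage: str = "post") -> float:
        m = self.frame_confusion_post if stage == "post" else self.frame_confusion_raw
        total = m.sum()
        return float(np.trace(m) / total) if total else float("nan")

    # -- recognition -------------------------------------------------------
    @property
    def recognition_accuracy(self) -> float:
        if not self.recognition_true:
            return float("nan")
        hits = sum(t == p for t, p in zip(self.recognition_true, self.recognition_pred))
        return hits / len(self.recognition_true)

    def recognition_confusion(self) -> np.ndarray:
        m = np.zeros((3, 3), dtype=int)
        idx = {c: i for i, c in enumerate(CLASSES)}
        for t, p in zip(self.recognition_true, self.recognition_pred):
            m[idx[t], idx[p]] += 1
        return m

    def recognition_prf(self) -> tuple[float, float, float]:
        if not self.recognition_true:
            return float("nan"), float("nan"), float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f, _ = precision_recall_fscore_support(
                self.recognition_true, self.recognition_pred,
                labels=list(CLASSES), average="macro", zero_division=0)
        return float(p), float(r), float(f)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        p, r, f = self.recognition_prf()

        def pct_rows(m: np.ndarray) -> list[list[float]]:
            rows = []
            for row in m:
                s = row.sum()
                rows.append([round_half_up(100.0 * v / s, 2) if s else 0.0
                             for v in row])
            return rows

        return {
            "seed": self.seed,
            "n_sequences": self.n_sequences,
            "n_events": self.n_events,
            "per_frame": {
                "confusion_raw_counts": self.frame_confusion_raw.tolist(),
                "confusion_post_counts": self.frame_confusion_post.tolist(),
                "confusion_raw_pct": pct_rows(self.frame_confusion_raw),
                "confusion_post_pct": pct_rows(self.frame_confusion_post),
                "accuracy_raw_pct": round_half_up(100 * self.frame_accuracy("raw"), 2),
                "accuracy_post_pct": round_half_up(100 * self.frame_accuracy("post"), 2),
            },
            "detection": {
                "per_class": self.detection_per_class,
                "tp": self.detection_tp,
                "fp": self.detection_fp,
                "detection_rate_pct": round_half_up(100 * self.detection_rate, 2),
                "false_positive_rate_pct": round_half_up(
                    100 * self.false_positive_rate, 2),
            },
            "recognition": {
                "confusion_counts": self.recognition_confusion().tolist(),
                "confusion_pct": pct_rows(self.recognition_confusion()),
                "accuracy_pct": round_half_up(100 * self.recognition_accuracy, 2)
                if self.recognition_true else None,
                "precision_macro_pct": round_half_up(100 * p, 2),
                "recall_macro_pct": round_half_up(100 * r, 2),
                "f1_macro_pct": round_half_up(100 * f, 2),
                "n_scored": len(self.recognition_true),
            },
            "folds": self.folds,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"LOSO evaluation over {self.n_sequences} sequences / "
            f"{self.n_events} micro-expressions (seed {self.seed})",
            f"  per-frame accuracy (post-processed): "
            f"{d['per_frame']['accuracy_post_pct']}%",
            f"  detection rate: {d['detection']['detection_rate_pct']}%   "
            f"false-positive rate: {d['detection']['false_positive_rate_pct']}%",
        ]
        for cls, stats in self.detection_per_class.items():
            lines.append(f"    {cls:9s} rate: "
                         f"{round_half_up(100 * stats['rate'], 2)}% "
                         f"({int(stats['tp'])}/{int(stats['n'])})")
        rec = d["recognition"]
        lines.append(f"  recognition accuracy: {rec['accuracy_pct']}%   "
                     f"macro P/R/F1: {rec['precision_macro_pct']}/"
                     f"{rec['recall_macro_pct']}/{rec['f1_macro_pct']}%")
        return "\n".join(lines)


def _frame_confusion(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """2x2 counts with rows = actual (ME, non-ME), cols = predicted."""
    return np.array([
        [int(np.sum(pred & truth)), int(np.sum(~pred & truth))],
        [int(np.sum(pred & ~truth)), int(np.sum(~pred & ~truth))],
    ])


def evaluate(dataset: Dataset, config: PipelineConfig,
             seed: int | None = None) -> EvalReport:
    """Full LOSO loop over a dataset; deterministic given the seed."""
    seed = config.seed if seed is None else seed
    cache = _SequenceCache(dataset, config)
    if not cache.records:
        raise ParameterError("no usable sequences (all shorter than tau?)")
    subjects = sorted({r.subject_id for r in cache.records})
    folds = loso_split(subjects)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                  for s in np.random.SeedSequence(seed).spawn(len(folds))]

    conf_raw = np.zeros((2, 2), dtype=int)
    conf_post = np.zeros((2, 2), dtype=int)
    det_per_class = {c: {"tp": 0, "n": 0} for c in CLASSES}
    det_tp = det_fp = 0
    rec_true: list[str] = []
    rec_pred: list[str] = []
    fold_rows: list[dict] = []
    tau, delta = config.descriptor.tau, config.descriptor.delta

    for (train_subj, test_subj), fold_seed in zip(folds, fold_seeds):
        train_recs = [r for r in cache.records if r.subject_id != test_subj]
        test_recs = [r for r in cache.records if r.subject_id == test_subj]
        spotter = train_spotting_model(cache, train_recs, config, fold_seed)
        recognizer = train_recognition_model(cache, train_recs, config)

        fold_tp = fold_fp = fold_truth = 0
        for rec in test_recs:
            raw, intervals = _detect_one(cache, rec, config, spotter)
            truth_labels = cache.frame_labels[rec.sequence_id]
            post = np.zeros(len(truth_labels), dtype=bool)
            for iv in intervals:
                post[iv.start:iv.end + 1] = True
            conf_raw += _frame_confusion(raw, truth_labels)
            conf_post += _frame_confusion(post, truth_labels)

            ann = rec.annotations
            truth_apexes = ann["apex"].tolist() if len(ann) else []
            truth_classes = ann["label"].tolist() if len(ann) else []
            sc = score_spotting(intervals, truth_apexes, tau, delta)
            det_tp += sc.tp
            det_fp += sc.fp
            fold_tp += sc.tp
            fold_fp += sc.fp
            fold_truth += sc.n_truth
            matched = {ti for ti, _, _ in sc.matches}
            for ti, cls in enumerate(truth_classes):
                det_per_class[cls]["n"] += 1
                if ti in matched:
                    det_per_class[cls]["tp"] += 1

            # recognition on the held-out subject
            if config.recognition.apex_source == "annotation":
                to_score = [(int(row["apex"]), row["label"])
                            for _, row in ann.iterrows()]
            else:
                by_det = {di: ti for ti, di, _ in sc.matches}
                to_score = [(iv.apex, truth_classes[by_det[di]])
                            for di, iv in enumerate(intervals) if di in by_det]
            for apex, true_cls in to_score:
                feature = cache.displacement(rec, apex)
                result = classify_expression(feature, recognizer)
                rec_true.append(true_cls)
                rec_pred.append(result.predicted)

        fold_rows.append({
            "test_subject": test_subj,
            "n_truth": fold_truth,
            "tp": fold_tp,
            "fp": fold_fp,
        })

    for c in det_per_class:
        n = det_per_class[c]["n"]
        det_per_class[c]["rate"] = det_per_class[c]["tp"] / n if n else 1.0

    n_events = sum(v["n"] for v in det_per_class.values())
    return EvalReport(
        seed=seed,
        n_sequences=len(cache.records),
        n_events=n_events,
        frame_confusion_raw=conf_raw,
        frame_confusion_post=conf_post,
        detection_per_class=det_per_class,
        detection_tp=det_tp,
        detection_fp=det_fp,
        recognition_true=rec_true,
        recognition_pred=rec_pred,
        folds=fold_rows,
    )


def loso_recognition(dataset: Dataset, config: PipelineConfig,
                     permute_labels_seed: int | None = None
                     ) -> tuple[float, list[str], list[str]]:
    """Recognition-only LOSO on annotation apexes.

    Classifies every annotated event of each held-out subject with models
    fitted on the other subjects.  ``permute_labels_seed`` shuffles the event
    class labels globally first (a permutation null for the classifier).
    Returns (accuracy, y_true, y_pred).
    """
    cache = _SequenceCache(dataset, config)
    records = cache.records
    if permute_labels_seed is not None:
        # shuffle event labels globally, without touching the input dataset
        rng = np.random.default_rng(permute_labels_seed)
        all_labels = [row["label"] for rec in records
                      for _, row in rec.annotations.iterrows()]
        shuffled = list(rng.permutation(all_labels))
        k = 0
        permuted: list[SequenceRecord] = []
        for rec in records:
            ann = rec.annotations.copy()
            if len(ann):
                ann["label"] = shuffled[k:k + len(ann)]
                k += len(ann)
            permuted.append(SequenceRecord(
                subject_id=rec.subject_id, sequence_id=rec.sequence_id,
                frames=rec.frames, landmarks=rec.landmarks, annotations=ann))
        records = permuted
        cache.records = records

    subjects = sorted({r.subject_id for r in records})
    y_true: list[str] = []
    y_pred: list[str] = []
    for train_subj, test_subj in loso_split(subjects):
        train_recs = [r for r in records if r.subject_id != test_subj]
        model = train_recognition_model(cache, train_recs, config)
        for rec in records:
            if rec.subject_id != test_subj:
                continue
            for _, row in rec.annotations.iterrows():
                feature = cache.displacement(rec, int(row["apex"]))
                y_true.append(row["label"])
                y_pred.append(classify_expression(feature, model).predicted)
    acc = (sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
           if y_true else float("nan"))
    return acc, y_true, y_pred
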