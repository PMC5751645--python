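"""Micro-expression recognition via per-class, per-cell 2D Gaussian models.

Training pools the weighted-centroid displacement pairs of every training
sequence, per class and per cell, and fits a bivariate Gaussian (sample mean,
unbiased sample covariance plus a small diagonal floor) to each pool.  A new
sequence is classified by summing, over cells and displacement pairs, the
bivariate normal log-densities under each class model and taking the argmax;
log-densities keep the product of many small probabilities numerically stable.

Classes follow the simplified three-way taxonomy used for spontaneous
micro-expression data: positive (happiness), negative (disgust, anger, fear,
sadness, contempt pooled) and surprise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DisplacementFeature
from .errors import ModelFormatError, ShapeError, TrainingError
from .geometry import CELL_NAMES

#: Fixed class order; also the deterministic tie-break order (first maximal wins).
CLASSES: tuple[str, ...] = ("positive", "negative", "surprise")

_MODEL_FORMAT_VERSION = 1


@dataclass
class ExpressionModel:
    """Per class and per cell: mean 2-vector and 2x2 covariance of displacements."""

    means: dict[str, dict[str, np.ndarray]]   # class -> cell -> (2,)
    covs: dict[str, dict[str, np.ndarray]]    # class -> cell -> (2, 2)
    counts: dict[str, int]                    # class -> number of pooled pairs
    cell_order: tuple[str, ...] = CELL_NAMES
    pooling: str = "pool"
    cov_floor: float = 1e-6

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.means)

    def save(self, path) -> None:
        payload = {
            "format": "microexp-expression-model",
            "version": _MODEL_FORMAT_VERSION,
            "cell_order": list(self.cell_order),
            "pooling": self.pooling,
            "cov_floor": self.cov_floor,
            "counts": self.counts,
            "means": {c: {n: m.tolist() for n, m in cells.items()}
                      for c, cells in self.means.items()},
            "covs": {c: {n: s.tolist() for n, s in cells.items()}
                     for c, cells in self.covs.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ExpressionModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "microexp-expression-model":
            raise ModelFormatError(f"{path}: not an expression model file")
        if payload.get("version") != _MODEL_FORMAT_VERSION:
            raise ModelFormatError(f"{path}: unsupported model version")
        if tuple(payload["cell_order"]) != CELL_NAMES:
            raise ModelFormatError(f"{path}: cell order mismatch")
        return cls(
            means={c: {n: np.asarray(m, dtype=float) for n, m in cells.items()}
                   for c, cells in payload["means"].items()},
            covs={c: {n: np.asarray(s, dtype=float) for n, s in cells.items()}
                  for c, cells in payload["covs"].items()},
            counts={c: int(n) for c, n in payload["counts"].items()},
            cell_order=tuple(payload["cell_order"]),
            pooling=payload["pooling"],
            cov_floor=float(payload["cov_floor"]),
        )


@dataclass
class ClassScore:
    """Per-class total log-probability and the argmax prediction."""

    scores: dict[str, float]
    predicted: str

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"predicted_class": self.predicted}
        for cls in self.scores:
            row[f"score_{cls}"] = self.scores[cls]
        return row


def _observations(feature: DisplacementFeature, cell: str, pooling: str) -> np.ndarray:
    """The (k, 2) observation block a single sequence contributes for one cell."""
    pairs = feature.pairs[cell]
    if pooling == "mean":
        return pairs.mean(axis=0, keepdims=True)
    return pairs


def fit_expression_models(features_by_class: dict[str, list[DisplacementFeature]],
                          cov_floor: float = 1e-6,
                          pooling: str = "pool",
                          classes: tuple[str, ...] = CLASSES) -> ExpressionModel:
    """Fit the per-class, per-cell bivariate Gaussians.

    ``pooling="pool"`` treats every displacement pair of every training
    sequence as one observation; ``pooling="mean"`` first averages the pairs
    of each sequence into a single observation.  The covariance is the
    unbiased sample covariance plus ``cov_floor`` times the identity, which
    keeps it positive definite even for degenerate pools.  ``classes`` may
    restrict the model to a subset (e.g. when a training fold lacks a class).
    """
    if pooling not in ("pool", "mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    means: dict[str, dict[str, np.ndarray]] = {}
    covs: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, int] = {}
    for cls in classes:
        feats = features_by_class.get(cls, [])
        if len(feats) == 0:
            raise TrainingError(f"no training sequences for class {cls!r}")
        means[cls] = {}
        covs[cls] = {}
        n_obs = None
        for cell in CELL_NAMES:
            obs = np.concatenate([_observations(f, cell, pooling) for f in feats])
            if obs.shape[0] < 2:
                raise TrainingError(
                    f"class {cls!r} has {obs.shape[0]} observation(s); need >= 2")
            means[cls][cell] = obs.mean(axis=0)
            covs[cls][cell] = np.cov(obs.T, ddof=1) + cov_floor * np.eye(2)
            n_obs = obs.shape[0]
        counts[cls] = int(n_obs)
    return ExpressionModel(means=means, covs=covs, counts=counts,
                           pooling=pooling, cov_floor=cov_floor)


def mvn_logpdf(x, mu, sigma) -> float:
    """Log of the standard bivariate normal density.

    -log(2*pi) - 0.5*log det(Sigma) - 0.5 (x-mu)^T Sigma^{-1} (x-mu).
    Raises a numeric error for a non-positive-definite covariance.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    L = np.linalg.cholesky(sigma)  # LinAlgError if not SPD
    z = np.linalg.solve(L, x - mu)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return -math.log(2.0 * math.pi) - 0.5 * logdet - 0.5 * float(z @ z)


def classify_expression(feature: DisplacementFeature,
                        model: ExpressionModel) -> ClassScore:
    """Score a sequence under every class model and take the argmax.

    score(e) = sum over cells c, sum over the cell's displacement
    observations x, of the bivariate normal log-density of x under
    (mu_{e,c}, Sigma_{e,c}).  Ties break on the fixed class order
    positive < negative < surprise (first maximal wins).
    """
    if tuple(feature.pairs) != model.cell_order:
        raise ShapeError("feature cell order does not match the model")
    scores: dict[str, float] = {}
    for cls in model.classes:
        total = 0.0
        for cell in model.cell_order:
            obs = _observations(feature, cell, model.pooling)
            mu = model.means[cls][cell]
            sigma = model.covs[cls][cell]
            for x in obs:
                total += mvn_logpdf(x, mu, sigma)
        scores[cls] = total
    best = max(scores.values())
    predicted = next(c for c in model.classes if scores[c] == best)
    return ClassScore(scores=scores, predicted=predicted)
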