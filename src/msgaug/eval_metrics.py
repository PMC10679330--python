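"""Evaluation battery: IS, FID, KID, classification metrics, paired t-test.

The three generative metrics operate on feature vectors produced by a
pluggable extractor.  Tests and desk-scale runs use raw image moments
(per-channel mean/sd plus gradient energy); users reproducing
published-scale numbers plug in a pretrained network's penultimate layer.
A value that a degenerate denominator would make meaningless (e.g.
precision of a class never predicted, the t statistic of zero-variance
differences) is reported as NaN rather than raised.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .data import LabeledImageSet

__all__ = [
    "FeatureExtractor",
    "IdentityFeatures",
    "RawMomentFeatures",
    "ConfusionMatrix",
    "MetricReport",
    "inception_score",
    "fid",
    "kid",
    "confusion_from_predictions",
    "classification_metrics",
    "paired_t_test",
]


# ---------------------------------------------------------------------------
# Feature extractors
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Contract: ``__call__(images) -> (N, d) float array``.

    ``images`` is an (N, H, W, 3) array in [-1, 1] or a LabeledImageSet.
    Real and generated images must be featurised by the same extractor.
    """

    def __call__(self, images) -> np.ndarray:
        raise NotImplementedError


class IdentityFeatures(FeatureExtractor):
    """Flatten images (or pass vectors through); for tests and tiny inputs."""

    def __call__(self, images) -> np.ndarray:
        arr = images.images if isinstance(images, LabeledImageSet) else np.asarray(images)
        return arr.reshape(len(arr), -1).astype(np.float64)


class RawMomentFeatures(FeatureExtractor):
    """Cheap image statistics: per-channel mean and sd, plus per-channel
    horizontal/vertical gradient energy (9 + 3 = 12 dimensions).  A stand-in
    feature space for desk-scale runs; no learned weights involved."""

    def __call__(self, images) -> np.ndarray:
        arr = images.images if isinstance(images, LabeledImageSet) else np.asarray(images)
        arr = arr.astype(np.float64)
        mean = arr.mean(axis=(1, 2))
        sd = arr.std(axis=(1, 2))
        gx = np.diff(arr, axis=2)
        gy = np.diff(arr, axis=1)
        grad = np.sqrt((gx ** 2).mean(axis=(1, 2)) + (gy ** 2).mean(axis=(1, 2)))
        # channel covariance magnitudes add colour-texture coupling
        flat = arr.reshape(len(arr), -1, 3)
        cov = np.einsum("nij,nik->njk", flat - mean[:, None, :],
                        flat - mean[:, None, :]) / flat.shape[1]
        off = cov[:, [0, 0, 1], [1, 2, 2]]
        return np.concatenate([mean, sd, grad, off], axis=1)


# ---------------------------------------------------------------------------
# Inception Score
# ---------------------------------------------------------------------------

def inception_score(probs: np.ndarray, n_splits: int = 10) -> tuple[float, float]:
    """exp(mean KL(p(y|x) || p_bar(y))) per split; returns (mean, std).

    Bounded by [1, K]; equals 1 when every conditional equals the marginal
    and K when rows are one-hot and balanced over K classes.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("probs must be (N, K)")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1")
    n = len(probs)
    if n < n_splits:
        raise ValueError(f"need at least n_splits={n_splits} samples, got {n}")
    scores = []
    for part in np.array_split(probs, n_splits):
        marginal = part.mean(axis=0, keepdims=True)
        kl = np.where(part > 0, part * (np.log(part + 1e-16) - np.log(marginal + 1e-16)), 0.0)
        scores.append(np.exp(kl.sum(axis=1).mean()))
    return float(np.mean(scores)), float(np.std(scores))


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Square root of a symmetric PSD matrix by eigendecomposition;
    small negative eigenvalues from rounding are clamped to zero."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(real: np.ndarray, fake: np.ndarray) -> float:
    """Frechet distance between Gaussians fitted to the two feature sets:

        ||mu_r - mu_f||^2 + Tr(S_r + S_f - 2 (S_r S_f)^{1/2})

    Sample covariances use the unbiased (N-1) normaliser.  The cross term
    is computed as Tr((A S_f A)^{1/2}) with A = S_r^{1/2}, which keeps the
    argument symmetric PSD.
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    fake = np.atleast_2d(np.asarray(fake, dtype=np.float64))
    if real.shape[1] != fake.shape[1]:
        raise ValueError("feature dimensions differ")
    if len(real) < 2 or len(fake) < 2:
        raise ValueError("need at least 2 samples per side")
    mu_r, mu_f = real.mean(axis=0), fake.mean(axis=0)
    cov_r = np.cov(real, rowvar=False).reshape(real.shape[1], real.shape[1])
    cov_f = np.cov(fake, rowvar=False).reshape(fake.shape[1], fake.shape[1])
    a = _sqrtm_psd(cov_r)
    cross = _sqrtm_psd(a @ cov_f @ a)
    val = float(np.sum((mu_r - mu_f) ** 2)
                + np.trace(cov_r) + np.trace(cov_f) - 2.0 * np.trace(cross))
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# KID
# ---------------------------------------------------------------------------

def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(real: np.ndarray, fake: np.ndarray,
        block_size: int | None = None) -> float:
    """Unbiased squared MMD with the cubic polynomial kernel
    k(x, y) = (x.y/d + 1)^3; may be slightly negative by construction.

    With ``block_size`` b, the estimator is averaged over consecutive
    disjoint blocks of b samples per side (the usual variance-reduction
    device at large N).
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    fake = np.atleast_2d(np.asarray(fake, dtype=np.float64))
    if real.shape[1] != fake.shape[1]:
        raise ValueError("feature dimensions differ")
    m, n = len(real), len(fake)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples per side")
    if block_size is not None:
        if block_size < 2:
            raise ValueError("block_size must be >= 2")
        n_blocks = min(m, n) // block_size
        if n_blocks < 1:
            raise ValueError("block_size larger than the sample")
        vals = [kid(real[i * block_size:(i + 1) * block_size],
                    fake[i * block_size:(i + 1) * block_size])
                for i in range(n_blocks)]
        return float(np.mean(vals))
    kxx = _poly_kernel(real, real)
    kyy = _poly_kernel(fake, fake)
    kxy = _poly_kernel(real, fake)
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    sum_xy = 2.0 * kxy.sum() / (m * n)
    return float(sum_xx + sum_yy - sum_xy)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix:
    counts: np.ndarray       # (K, K), rows = true class, cols = predicted
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be ({k}, {k}), got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               class_names: list[str]) -> ConfusionMatrix:
    counts = _sk_confusion_matrix(y_true, y_pred,
                                  labels=np.arange(len(class_names)))
    return ConfusionMatrix(counts, list(class_names))


@dataclasses.dataclass
class MetricReport:
    """Container for the full evaluation battery; any field may be NaN."""

    overall_accuracy: float = np.nan
    per_class: pd.DataFrame | None = None        # precision/recall/specificity
    confusion: ConfusionMatrix | None = None
    is_mean: float = np.nan
    is_std: float = np.nan
    fid: float = np.nan
    kid: float = np.nan

    def to_dict(self) -> dict:
        out = {
            "overall_accuracy": _jsonable(self.overall_accuracy),
            "is_mean": _jsonable(self.is_mean),
            "is_std": _jsonable(self.is_std),
            "fid": _jsonable(self.fid),
            "kid": _jsonable(self.kid),
        }
        if self.per_class is not None:
            out["per_class"] = {
                row["class"]: {k: _jsonable(row[k])
                               for k in ("precision", "recall", "specificity")}
                for _, row in self.per_class.iterrows()
            }
        if self.confusion is not None:
            out["confusion"] = self.confusion.counts.tolist()
            out["class_names"] = self.confusion.class_names
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _jsonable(x):
    x = float(x)
    return None if not np.isfinite(x) else x


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class precision, recall and specificity plus overall accuracy.

    precision = TP/(TP+FP), recall = TP/(TP+FN), specificity = TN/(TN+FP);
    a zero denominator yields NaN, never an exception.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for c, name in enumerate(cm.class_names):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        tn = total - tp - fp - fn
        rows.append({
            "class": name,
            "precision": _safe_div(tp, tp + fp),
            "recall": _safe_div(tp, tp + fn),
            "specificity": _safe_div(tn, tn + fp),
        })
    return MetricReport(
        overall_accuracy=float(np.trace(counts) / total),
        per_class=pd.DataFrame(rows),
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on matched observations.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and the (n-1) sample sd;
    p from Student's t with n-1 degrees of freedom.  Zero-variance
    differences give (NaN, NaN).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return (np.nan, np.nan)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(p))
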