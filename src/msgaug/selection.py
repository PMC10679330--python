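"""Confidence-threshold selection of synthetic images.

Generated images can carry ambiguous class information: a sample produced
by the class-k generator may not actually look like class k, and adding it
to the training set with label k hurts the downstream classifier.  The
filter here scores every generated image with a classifier trained on the
original (non-augmented) data and keeps only images whose predicted
probability for their intended class strictly exceeds a threshold alpha
(default 0.85, the value that maximises downstream accuracy in the
reference ablation; alpha = 0 disables selection entirely).  The scoring
classifier is never retrained after augmentation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import SmallCnnClassifier, predict_proba
from .data import LabeledImageSet

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "score_generated",
    "select",
    "build_augmented_set",
]

DEFAULT_ALPHA = 0.85


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    alpha: float = DEFAULT_ALPHA
    intended_class: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.intended_class < 0:
            raise ValueError("intended_class must be >= 0")


@dataclasses.dataclass
class SelectionResult:
    probabilities: np.ndarray  # P(intended class) per image
    alpha: float
    kept_mask: np.ndarray = dataclasses.field(init=False)
    n_kept: int = dataclasses.field(init=False)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64).ravel()
        self.kept_mask = self.probabilities > self.alpha  # strictly greater
        self.n_kept = int(self.kept_mask.sum())

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept_mask)


def score_generated(images: LabeledImageSet, classifier: SmallCnnClassifier,
                    intended_class: int) -> np.ndarray:
    """Per-image probability of the intended class under the baseline scorer."""
    if not classifier.fitted:
        raise RuntimeError("selection requires a trained (baseline) classifier")
    if not 0 <= intended_class < classifier.config.n_classes:
        raise ValueError(f"intended_class {intended_class} out of range")
    return predict_proba(classifier, images)[:, intended_class]


def select(probabilities: np.ndarray, config: SelectionConfig) -> SelectionResult:
    """Keep exactly the images with probability strictly above alpha.

    Order is preserved among kept images; an image whose probability equals
    alpha is dropped.  alpha = 0 keeps everything (no selection).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64).ravel()
    if probabilities.size and (probabilities.min() < 0 or probabilities.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return SelectionResult(probabilities, config.alpha)


def build_augmented_set(
    original: LabeledImageSet,
    generated_per_class: list[LabeledImageSet],
    classifier: SmallCnnClassifier,
    alpha: float,
) -> tuple[LabeledImageSet, pd.DataFrame]:
    """Filter each class's generated set and append the keepers to the data.

    Returns the augmented set and a per-class report with columns
    (class, n_generated, n_kept, alpha, mean_probability_kept).
    """
    pieces = [original]
    rows = []
    for gen in generated_per_class:
        if len(gen) == 0:
            continue
        classes = np.unique(gen.labels)
        if len(classes) != 1:
            raise ValueError("each generated set must contain a single class")
        if gen.class_names != original.class_names[:len(gen.class_names)] \
                and gen.class_names != original.class_names:
            raise ValueError("generated class names do not align with original")
        intended = int(classes[0])
        if intended >= original.n_classes:
            raise ValueError(f"generated class {intended} not in original data")
        probs = score_generated(gen, classifier, intended)
        result = select(probs, SelectionConfig(alpha=alpha, intended_class=intended))
        kept = gen.subset(result.kept_indices)
        if len(kept):
            pieces.append(LabeledImageSet(kept.images, kept.labels,
                                          original.class_names))
        rows.append((
            original.class_names[intended], len(gen), result.n_kept, alpha,
            float(probs[result.kept_mask].mean()) if result.n_kept else np.nan,
        ))
    report = pd.DataFrame(rows, columns=[
        "class", "n_generated", "n_kept", "alpha", "mean_probability_kept"])
    return LabeledImageSet.concatenate(pieces), report


def write_selection_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)
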