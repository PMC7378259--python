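"""Evaluation metrics and visual overlays for label matrices.

Per-class precision/recall/F-score are computed one-vs-rest over blocks,
with a class absent from both prediction and truth reported as
*undefined* (None) rather than 0 and excluded from the macro average.
The confusion matrix is 7x7 over the full label vocabulary, rows =
truth, columns = prediction.

Overlays follow the established colour scheme: heart green, loose
connective blue, muscular artery violet, large vein yellow, elastic
artery orange, light region fuchsia, epithelium pink; hit/miss panels
paint correct blocks green and wrong blocks red.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import confusion_matrix as _sk_confusion

from .grid_classify import BLOCK_SIZE, LABELS, LabelMatrix

__all__ = [
    "PALETTE",
    "EvalReport",
    "confusion_matrix",
    "f_score",
    "evaluate",
    "render_overlay",
]

#: Class colours (RGB).
PALETTE = {
    "HE": (46, 160, 67),     # green
    "LC": (58, 110, 220),    # blue
    "MA": (140, 60, 190),    # violet
    "LV": (235, 210, 50),    # yellow
    "EA": (240, 140, 40),    # orange
    "LR": (230, 40, 200),    # fuchsia
    "EP": (250, 170, 190),   # pink
}

_HIT = (40, 180, 60)
_MISS = (210, 40, 40)


def confusion_matrix(pred: LabelMatrix, truth: LabelMatrix) -> pd.DataFrame:
    """7x7 count matrix; entry (i, j) = cells with truth i predicted j."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    counts = _sk_confusion(
        truth.labels.ravel(), pred.labels.ravel(), labels=list(LABELS)
    )
    return pd.DataFrame(counts, index=list(LABELS), columns=list(LABELS))


def _prf(cm: pd.DataFrame, label: str):
    tp = cm.loc[label, label]
    fp = cm[label].sum() - tp
    fn = cm.loc[label].sum() - tp
    if tp + fp + fn == 0:
        return None, None, None  # class absent everywhere: undefined
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall \
        else 0.0
    return float(precision), float(recall), float(f)


def f_score(pred: LabelMatrix, truth: LabelMatrix, label: str):
    """One-vs-rest F-score of one class over blocks.

    Returns None (undefined) when the class occurs in neither prediction
    nor truth; 0.0 when it occurs but has no correct prediction.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    return _prf(confusion_matrix(pred, truth), label)[2]


@dataclass
class EvalReport:
    """Per-class metrics plus the confusion matrix for one comparison."""

    precision: dict
    recall: dict
    f: dict
    confusion: pd.DataFrame
    n_blocks: int

    @property
    def macro_f(self) -> float:
        defined = [v for v in self.f.values() if v is not None]
        return float(np.mean(defined)) if defined else float("nan")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion.values)) / self.n_blocks

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f,
            "macro_f": self.macro_f,
            "accuracy": self.accuracy,
            "n_blocks": self.n_blocks,
            "confusion": {
                t: {p: int(self.confusion.loc[t, p]) for p in LABELS}
                for t in LABELS
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_csv(self, path) -> None:
        rows = pd.DataFrame({
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f,
        })
        rows.index.name = "label"
        rows.to_csv(path)


def evaluate(pred: LabelMatrix, truth: LabelMatrix) -> EvalReport:
    """Full per-class report of a prediction against ground truth."""
    cm = confusion_matrix(pred, truth)
    precision, recall, f = {}, {}, {}
    for lab in LABELS:
        precision[lab], recall[lab], f[lab] = _prf(cm, lab)
    return EvalReport(
        precision=precision, recall=recall, f=f, confusion=cm,
        n_blocks=int(cm.values.sum()),
    )


def render_overlay(
    image: np.ndarray,
    pred: LabelMatrix,
    truth: LabelMatrix | None = None,
    block_size: int = BLOCK_SIZE,
    alpha: float = 0.45,
):
    """Block-wise translucent class-colour overlay, plus a hit/miss panel.

    Returns ``(class_panel, hitmiss_panel)`` as PIL images, each with the
    input image's dimensions; ``hitmiss_panel`` is None without truth.
    """
    arr = np.asarray(image)
    m, n = pred.shape
    if arr.shape[0] // block_size != m or arr.shape[1] // block_size != n:
        raise ValueError(
            f"image {arr.shape[1]}x{arr.shape[0]} does not tile to the "
            f"{m}x{n} label matrix at block size {block_size}"
        )
    if truth is not None and truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")

    def _paint(colors: np.ndarray) -> Image.Image:
        out = arr[:m * block_size, :n * block_size].astype(np.float64).copy()
        tint = np.repeat(np.repeat(colors, block_size, 0), block_size, 1)
        out = (1 - alpha) * out + alpha * tint
        return Image.fromarray(np.clip(np.rint(out), 0, 255).astype(np.uint8))

    class_colors = np.zeros((m, n, 3))
    for lab, rgb in PALETTE.items():
        class_colors[pred.labels == lab] = rgb
    class_panel = _paint(class_colors)

    hit_panel = None
    if truth is not None:
        hm = np.where(
            (pred.labels == truth.labels)[..., None], _HIT, _MISS
        ).astype(np.float64)
        hit_panel = _paint(hm)
    return class_panel, hit_panel
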