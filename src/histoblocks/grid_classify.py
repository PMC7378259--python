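"""Block grids, label matrices and the cascade SVM block classifier.

An image acquired at the reference geometry (2048x1536 px, 10x objective)
is tiled into non-overlapping 100x100 blocks — 20 columns by 15 rows,
trailing partial rows/columns discarded — and every block is classified
into one of six tissue classes:

======  ==================================
label   tissue
======  ==================================
``EA``  smooth muscle of the elastic artery
``LV``  smooth muscle of the large vein
``MA``  smooth muscle of the muscular artery
``HE``  cardiac muscle of the heart
``LC``  loose connective tissue
``LR``  light region (lumen / background)
======  ==================================

A seventh label, ``EP`` (epithelial tissue), is never emitted by the
classifier; it is produced downstream by the ontology refinement stage.

The classifier is a two-stage cascade: a linear-kernel SVM separates five
classes — with elastic artery and large vein merged into one class,
because their smooth-muscle textures are near-identical — and a binary
polynomial-kernel SVM then splits that merged class into EA vs LV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import DESCRIPTOR_LENGTH, describe_block

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "CLASSIFIER_LABELS",
    "DISCRIMINANT_LABELS",
    "BLOCK_SIZE",
    "CascadeConfig",
    "BlockGrid",
    "LabelMatrix",
    "CascadeModel",
    "ModelFormatError",
    "tile_image",
    "train_cascade",
    "classify_block",
    "classify_image",
    "save_model",
    "load_model",
]

#: All seven tissue labels, EP included.
LABELS = ("EA", "LV", "MA", "HE", "LC", "LR", "EP")
#: Labels the cascade can emit.
CLASSIFIER_LABELS = ("EA", "LV", "MA", "HE", "LC", "LR")
#: Labels uniquely implicating an organ.
DISCRIMINANT_LABELS = ("EA", "LV", "MA", "HE")

#: Merged stage-1 class standing for EA ∪ LV.
_MERGED = "C1"

BLOCK_SIZE = 100

_MODEL_SCHEMA = "histoblocks-cascade-v1"

_PROVENANCE = ("classifier", "corrected", "epithelium", "truth")


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of the two cascade stages.

    Defaults: C=10 for both stages (L1-normalised histogram descriptors
    have small pairwise kernel values, so C=1 under-fits even cleanly
    separable data), polynomial degree 3 with variance-scaled gamma for
    stage 2; all overridable per run.
    """

    stage1_C: float = 10.0
    stage2_C: float = 10.0
    stage2_degree: int = 3
    stage2_gamma: str | float = "scale"
    seed: int = 0


@dataclass(frozen=True)
class BlockGrid:
    """Floor-division tiling of an image into square blocks.

    Block ``(i, j)`` covers pixel rows ``[i*s, (i+1)*s)`` and columns
    ``[j*s, (j+1)*s)``; leftover pixels past the last full block are
    discarded.
    """

    image: np.ndarray = field(repr=False)
    block_size: int
    n_rows: int
    n_cols: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def block(self, i: int, j: int) -> np.ndarray:
        s = self.block_size
        return self.image[i * s:(i + 1) * s, j * s:(j + 1) * s]

    def __iter__(self):
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield i, j, self.block(i, j)


def tile_image(image: np.ndarray, block_size: int = BLOCK_SIZE) -> BlockGrid:
    """Tile an image into a grid of ``block_size`` squares (row-major).

    A 2048x1536 image yields 15 rows x 20 columns of 100-px blocks.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if h < block_size or w < block_size:
        raise ValueError(
            f"image {w}x{h} is smaller than one {block_size}px block"
        )
    return BlockGrid(
        image=arr,
        block_size=block_size,
        n_rows=h // block_size,
        n_cols=w // block_size,
    )


class LabelMatrix:
    """An m x n grid of tissue labels with per-cell provenance.

    Provenance is one of ``classifier`` (raw cascade output),
    ``corrected`` (organ label rewritten to LC by the rule engine),
    ``epithelium`` (LR rewritten to EP) or ``truth`` (ground truth).
    """

    def __init__(self, labels, provenance=None):
        labels = np.asarray(labels, dtype="U2")
        if labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got ndim={labels.ndim}")
        bad = set(np.unique(labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        if provenance is None:
            provenance = np.full(labels.shape, "classifier", dtype="U10")
        else:
            provenance = np.asarray(provenance, dtype="U10")
            if provenance.shape != labels.shape:
                raise ValueError("provenance shape must match labels shape")
        self.labels = labels
        self.provenance = provenance

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "LabelMatrix":
        return LabelMatrix(self.labels.copy(), self.provenance.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelMatrix) and bool(
            np.array_equal(self.labels, other.labels)
        )

    def hamming(self, other: "LabelMatrix") -> int:
        """Number of cells whose labels disagree with ``other``."""
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        return int((self.labels != other.labels).sum())

    # -- serialization -------------------------------------------------

    def to_csv(self, path) -> None:
        """One text row per grid row, comma-separated label mnemonics."""
        Path(path).write_text(
            "\n".join(",".join(row) for row in self.labels) + "\n"
        )

    @classmethod
    def from_csv(cls, path) -> "LabelMatrix":
        rows = [
            line.split(",")
            for line in Path(path).read_text().strip().splitlines()
        ]
        return cls(np.array(rows))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "labels": self.labels.tolist(),
            "provenance": self.provenance.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "LabelMatrix":
        doc = json.loads(Path(path).read_text())
        return cls(np.array(doc["labels"]), np.array(doc["provenance"]))


@dataclass
class CascadeModel:
    """Trained two-stage block classifier.

    ``stage1`` discriminates {C1, MA, HE, LC, LR} (C1 = EA ∪ LV merged);
    ``stage2`` splits C1 into EA vs LV and is consulted only when stage 1
    outputs C1.  ``stage2`` may be None when the training set lacked one
    of EA/LV, in which case ``fallback`` (the label that was present) is
    emitted for C1 blocks.
    """

    stage1: SVC
    stage2: SVC | None
    config: CascadeConfig
    fallback: str | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorised cascade prediction for an (n, 292) descriptor array."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != DESCRIPTOR_LENGTH:
            raise ValueError(
                f"descriptors must have {DESCRIPTOR_LENGTH} columns, "
                f"got {X.shape[1]}"
            )
        out = self.stage1.predict(X).astype("U2")
        merged = out == _MERGED
        if merged.any():
            if self.stage2 is not None:
                out[merged] = self.stage2.predict(X[merged])
            else:
                out[merged] = self.fallback or "EA"
        return out


def train_cascade(
    descriptors,
    labels,
    config: CascadeConfig = CascadeConfig(),
) -> CascadeModel:
    """Fit the cascade on labelled block descriptors.

    Stage 1 is fit on the 5-class relabelling (EA, LV -> C1); stage 2 on
    the EA/LV subset only.  Training is deterministic for a fixed config
    seed.  If either EA or LV is absent, stage 2 is skipped with a
    warning and a stage-1-only model is returned.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    y = np.asarray(labels, dtype="U2")
    if X.ndim != 2 or X.shape[1] != DESCRIPTOR_LENGTH:
        raise ValueError(
            f"descriptors must be (n, {DESCRIPTOR_LENGTH}), got {X.shape}"
        )
    if X.shape[0] != y.shape[0]:
        raise ValueError("one label per descriptor required")
    bad = set(np.unique(y)) - set(CLASSIFIER_LABELS)
    if bad:
        raise ValueError(f"labels outside the classifier vocabulary: {sorted(bad)}")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train")

    y1 = y.copy()
    y1[np.isin(y1, ("EA", "LV"))] = _MERGED
    stage1 = SVC(kernel="linear", C=config.stage1_C, random_state=config.seed)
    stage1.fit(X, y1)

    sub = np.isin(y, ("EA", "LV"))
    present = set(np.unique(y[sub]))
    stage2 = None
    fallback = None
    if present == {"EA", "LV"}:
        stage2 = SVC(
            kernel="poly",
            degree=config.stage2_degree,
            C=config.stage2_C,
            gamma=config.stage2_gamma,
            random_state=config.seed,
        )
        stage2.fit(X[sub], y[sub])
    else:
        fallback = present.pop() if present else None
        logger.warning(
            "EA/LV subset incomplete (%s): stage 2 skipped, "
            "stage-1-only model returned", fallback or "neither present"
        )
    return CascadeModel(stage1=stage1, stage2=stage2, config=config,
                        fallback=fallback)


def classify_block(model: CascadeModel, descriptor: np.ndarray) -> str:
    """Label one 292-value descriptor through the cascade."""
    return str(model.predict(np.asarray(descriptor))[0])


def classify_image(
    model: CascadeModel,
    image: np.ndarray,
    block_size: int = BLOCK_SIZE,
) -> LabelMatrix:
    """Tile, describe and classify a whole image into a LabelMatrix."""
    grid = tile_image(image, block_size)
    X = np.stack([describe_block(b) for _, _, b in grid])
    labels = model.predict(X).reshape(grid.shape)
    return LabelMatrix(labels)


class ModelFormatError(RuntimeError):
    """Raised when a model archive is missing or has the wrong schema."""


def save_model(model: CascadeModel, path) -> None:
    """Persist the cascade as a versioned joblib archive."""
    joblib.dump({"schema": _MODEL_SCHEMA, "model": model}, path)


def load_model(path) -> CascadeModel:
    """Load a cascade archive, validating the schema version."""
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    try:
        doc = joblib.load(path)
    except Exception as exc:  # corrupt archive
        raise ModelFormatError(f"cannot read model archive {path}: {exc}") from exc
    schema = doc.get("schema") if isinstance(doc, dict) else None
    if schema != _MODEL_SCHEMA:
        raise ModelFormatError(
            f"unsupported model schema {schema!r} (expected {_MODEL_SCHEMA!r})"
        )
    return doc["model"]
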