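"""Synthetic histology fixtures: separable textures, organ layouts, datasets.

Real cardiovascular slides are not redistributable with the package, so
tests and examples run on generated images that reproduce the two
properties the pipeline actually depends on:

* **texture separability** — each tissue class is an oriented sinusoidal
  grating plus noise, with pairwise-distinct (orientation, frequency)
  pairs, so LBP/LBPri histograms differ across classes by construction
  (statistical separability, not visual fidelity to H&E staining);
* **organ-like layout** — a light-region lumen disk, a muscle annulus of
  the organ's discriminant class, a loose-connective surround, with the
  ground truth marking lumen cells that touch muscle as epithelium (EP),
  exactly where endothelium/endocardium sits.

Label corruption is available at two levels:

* :func:`generate_organ_image` can swap the *texture* of randomly chosen
  muscle cells to a foreign organ class (truth unchanged), creating
  genuine classifier errors;
* :func:`corrupt_matrix` injects foreign-organ *labels* directly into a
  classifier-style matrix at cells whose truth is loose connective —
  emulating the observed behaviour of organ false positives, which is
  what the rule-based correction was designed around.

Everything is bit-exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_classify import (
    BLOCK_SIZE,
    CLASSIFIER_LABELS,
    DISCRIMINANT_LABELS,
    LabelMatrix,
)
from .knowledge_base import ORGANS, label_of

__all__ = [
    "TextureSpec",
    "TEXTURES",
    "OrganLayout",
    "GroundTruth",
    "SyntheticDataset",
    "generate_block",
    "generate_organ_image",
    "generate_dataset",
    "corrupt_matrix",
    "generate_calibration_matrices",
]

#: Reference acquisition geometry: 2048x1536 px at the 10x objective.
DEFAULT_IMAGE_SIZE = (2048, 1536)  # (width, height)


@dataclass(frozen=True)
class TextureSpec:
    """Grating parameters of one tissue class.

    ``angle`` in degrees, ``jitter`` the per-block uniform angle
    perturbation, ``freq`` in cycles per 100 px, ``amplitude`` and
    ``noise`` in gray levels, ``base`` an RGB stain tone.
    """

    angle: float
    jitter: float
    freq: float
    amplitude: float
    base: tuple[int, int, int]
    noise: float


#: Per-class texture parameters.  (orientation, frequency) pairs are
#: pairwise distinct; LR has by far the lowest variance (near-white lumen).
TEXTURES: dict[str, TextureSpec] = {
    "HE": TextureSpec(angle=0, jitter=4, freq=8, amplitude=55,
                      base=(190, 95, 120), noise=6),    # cardiac muscle, pink
    "MA": TextureSpec(angle=45, jitter=4, freq=13, amplitude=55,
                      base=(150, 90, 160), noise=6),    # smooth muscle, violet
    "EA": TextureSpec(angle=90, jitter=4, freq=5, amplitude=55,
                      base=(200, 130, 90), noise=6),    # smooth muscle, orange-ish
    "LV": TextureSpec(angle=135, jitter=4, freq=18, amplitude=45,
                      base=(195, 175, 110), noise=6),   # smooth muscle, yellow-ish
    "LC": TextureSpec(angle=20, jitter=8, freq=2, amplitude=20,
                      base=(175, 190, 215), noise=10),  # loose connective, pale blue
    "LR": TextureSpec(angle=0, jitter=0, freq=1, amplitude=2,
                      base=(246, 246, 248), noise=1),   # lumen, near-white
}

_CLASS_INDEX = {lab: k for k, lab in enumerate(CLASSIFIER_LABELS)}


def generate_block(label: str, seed: int, size: int = BLOCK_SIZE) -> np.ndarray:
    """One deterministic RGB texture block for a classifier class.

    EP is rejected: epithelium is a derived label with no texture of its
    own at this magnification.
    """
    if label not in TEXTURES:
        raise ValueError(
            f"no texture for label {label!r}; expected one of {CLASSIFIER_LABELS}"
        )
    spec = TEXTURES[label]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, _CLASS_INDEX[label]])
    theta = np.deg2rad(spec.angle + spec.jitter * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    carrier = (xx * np.cos(theta) + yy * np.sin(theta)) * (
        2 * np.pi * spec.freq / 100.0
    )
    pattern = spec.amplitude * np.sin(carrier + phase)
    noise = spec.noise * rng.standard_normal((size, size))
    rgb = np.array(spec.base, dtype=np.float64) + (pattern + noise)[..., None]
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class OrganLayout:
    """Geometry of one synthetic organ image, in block units.

    The lumen is a disk of light-region blocks centred at
    ``lumen_center`` (row, col) with radius ``lumen_radius``; the
    ``annulus_width``-block ring around it carries the organ's
    discriminant muscle class; everything else is loose connective.
    ``corruption_rate`` is the fraction of annulus cells whose *texture*
    is swapped to a foreign organ class (ground truth unchanged).
    """

    organ: str
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE  # (width, height) px
    lumen_center: tuple[float, float] = (7.0, 9.5)    # (row, col) blocks
    lumen_radius: float = 3.4
    annulus_width: float = 2.2
    corruption_rate: float = 0.0
    seed: int = 0
    min_lumen_blocks: int = 10

    @property
    def grid_shape(self) -> tuple[int, int]:
        w, h = self.image_size
        return (h // BLOCK_SIZE, w // BLOCK_SIZE)


@dataclass
class GroundTruth:
    """A synthetic image with its true label matrix and corruption record.

    ``truth`` uses the full 7-label vocabulary (EP marks the lumen/muscle
    interface); ``texture_labels`` records the classifier-level class
    actually rendered in each block (EP cells are rendered as LR, and
    corrupted cells as their foreign class) — the labels a perfect block
    classifier would emit.
    """

    image: np.ndarray = field(repr=False)
    truth: LabelMatrix
    texture_labels: LabelMatrix
    corrupted: list
    layout: OrganLayout


def _layout_matrices(layout: OrganLayout) -> tuple[np.ndarray, np.ndarray]:
    """(truth, texture) label arrays for a layout, before corruption."""
    m, n = layout.grid_shape
    ci, cj = layout.lumen_center
    ii, jj = np.mgrid[0:m, 0:n]
    dist = np.hypot(ii - ci, jj - cj)
    lumen = dist <= layout.lumen_radius
    annulus = (dist <= layout.lumen_radius + layout.annulus_width) & ~lumen
    if not lumen.any():
        raise ValueError("lumen radius too small: no lumen blocks")
    edge = lumen[0, :].any() or lumen[-1, :].any() or lumen[:, 0].any() \
        or lumen[:, -1].any() or annulus[0, :].any() or annulus[-1, :].any() \
        or annulus[:, 0].any() or annulus[:, -1].any()
    if edge:
        raise ValueError(
            f"lumen+annulus overflow the {m}x{n} grid for layout {layout}"
        )
    if int(lumen.sum()) < layout.min_lumen_blocks:
        raise ValueError(
            f"lumen has {int(lumen.sum())} blocks, "
            f"fewer than the required {layout.min_lumen_blocks}"
        )
    muscle = label_of(layout.organ)
    texture = np.full((m, n), "LC", dtype="U2")
    texture[annulus] = muscle
    texture[lumen] = "LR"
    truth = texture.copy()
    # Epithelium lines the lumen: lumen cells 4-adjacent to muscle.
    for i, j in zip(*np.nonzero(lumen)):
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if annulus[i + di, j + dj]:
                truth[i, j] = "EP"
                break
    return truth, texture


def generate_organ_image(layout: OrganLayout) -> GroundTruth:
    """Render a full organ image block-wise, with ground truth.

    Deterministic for a fixed layout (per-cell seeds are derived from the
    layout seed and the cell coordinates).  Corruption swaps the rendered
    texture of randomly chosen annulus cells to a different organ's
    muscle class, recording ``(cell, foreign_label)`` pairs; the ground
    truth keeps the organ's own label, so corrupted cells are built-in
    classifier errors for the refinement stage to fix.
    """
    truth_arr, texture_arr = _layout_matrices(layout)
    m, n = truth_arr.shape
    rng = np.random.default_rng([layout.seed & 0x7FFFFFFF, 0xC0FFEE])

    corrupted = []
    if layout.corruption_rate > 0:
        muscle = label_of(layout.organ)
        cells = list(zip(*np.nonzero(texture_arr == muscle)))
        k = int(round(layout.corruption_rate * len(cells)))
        foreign = [label_of(o) for o in ORGANS if o != layout.organ]
        for idx in rng.choice(len(cells), size=k, replace=False):
            cell = cells[idx]
            swap = foreign[rng.integers(len(foreign))]
            texture_arr[cell] = swap
            corrupted.append((tuple(int(c) for c in cell), swap))

    # Render the full acquisition geometry: trailing partial rows/columns
    # (e.g. 2048 = 20*100 + 48 px) are filled with the connective surround
    # and later discarded by floor-division tiling.
    w_px, h_px = layout.image_size
    m_r = -(-h_px // BLOCK_SIZE)  # ceil
    n_r = -(-w_px // BLOCK_SIZE)
    image = np.empty((m_r * BLOCK_SIZE, n_r * BLOCK_SIZE, 3), dtype=np.uint8)
    for i in range(m_r):
        for j in range(n_r):
            lab = texture_arr[i, j] if i < m and j < n else "LC"
            cell_seed = (layout.seed * 1_000_003 + i * 1009 + j) & 0x7FFFFFFF
            block = generate_block(lab, cell_seed)
            image[i * BLOCK_SIZE:(i + 1) * BLOCK_SIZE,
                  j * BLOCK_SIZE:(j + 1) * BLOCK_SIZE] = block
    image = image[:h_px, :w_px]

    provenance = np.full((m, n), "truth", dtype="U10")
    return GroundTruth(
        image=image,
        truth=LabelMatrix(truth_arr, provenance),
        texture_labels=LabelMatrix(texture_arr.copy(),
                                   np.full((m, n), "truth", dtype="U10")),
        corrupted=corrupted,
        layout=layout,
    )


@dataclass
class SyntheticDataset:
    """K organ images with ground truth, split at the image level."""

    images: list  # GroundTruth
    train_idx: list
    validation_idx: list

    def split(self, which: str) -> list:
        idx = self.train_idx if which == "train" else self.validation_idx
        return [self.images[k] for k in idx]


def generate_dataset(
    K: int = 20,
    split: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    corruption_rate: float = 0.0,
) -> SyntheticDataset:
    """Generate K organ images (round-robin over the four organs).

    The train/validation split is assigned per image *before* tiling —
    ``floor(split[0] * K)`` leading images train, the remainder validate
    — so no block ever leaks across splits.  At the default geometry,
    K=20 images yield 6000 blocks in total (300 each).
    """
    if K < 2:
        raise ValueError("need at least two images to split")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    grid_m = image_size[1] // BLOCK_SIZE
    grid_n = image_size[0] // BLOCK_SIZE
    images = []
    for k in range(K):
        organ = ORGANS[k % len(ORGANS)]
        radius = float(rng.uniform(2.6, 3.4))
        width = float(rng.uniform(1.6, 2.2))
        margin = radius + width + 1.0
        if grid_m - 1 - margin <= margin or grid_n - 1 - margin <= margin:
            raise ValueError(
                f"image grid {grid_m}x{grid_n} too small for the organ "
                f"layout geometry (needs at least 15x15 blocks); use "
                f"generate_organ_image with an explicit OrganLayout instead"
            )
        ci = float(rng.uniform(margin, grid_m - 1 - margin))
        cj = float(rng.uniform(margin, grid_n - 1 - margin))
        layout = OrganLayout(
            organ=organ,
            image_size=image_size,
            lumen_center=(ci, cj),
            lumen_radius=radius,
            annulus_width=width,
            corruption_rate=corruption_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images.append(generate_organ_image(layout))
    n_train = int(np.floor(split[0] * K))
    return SyntheticDataset(
        images=images,
        train_idx=list(range(n_train)),
        validation_idx=list(range(n_train, K)),
    )


def corrupt_matrix(
    truth: LabelMatrix,
    rate: float,
    seed: int,
    dominant_organ: str,
) -> tuple[LabelMatrix, list]:
    """Classifier-style matrix with foreign-organ false positives injected.

    Starts from the classifier-level view of the truth (EP cells appear
    as LR — the classifier cannot emit EP) and rewrites a fraction
    ``rate`` of the loose-connective cells to the discriminant label of
    an organ other than ``dominant_organ``.  This mirrors how organ
    false positives arise in practice: connective-tissue blocks
    misread as a foreign organ's muscle.  Returns the corrupted matrix
    and the ``(cell, foreign_label)`` record.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    pred = truth.copy()
    pred.labels[pred.labels == "EP"] = "LR"
    pred.provenance[:] = "classifier"
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    lc_cells = list(zip(*np.nonzero(pred.labels == "LC")))
    k = int(round(rate * len(lc_cells)))
    foreign = [label_of(o) for o in ORGANS if o != dominant_organ]
    record = []
    for idx in rng.choice(len(lc_cells), size=k, replace=False):
        cell = lc_cells[idx]
        swap = foreign[rng.integers(len(foreign))]
        pred.labels[cell] = swap
        record.append((tuple(int(c) for c in cell), swap))
    return pred, record


def generate_calibration_matrices(
    seed: int,
    true_min_size: int = 10,
    shape: tuple[int, int] = (15, 20),
) -> tuple[LabelMatrix, LabelMatrix]:
    """(classifier output, ground truth) pair for threshold calibration.

    Several rectangular light regions — one of ``true_min_size - 1``
    cells, one of exactly ``true_min_size``, plus extras of random size —
    are placed on a muscular-artery background so each is muscle-
    adjacent.  The ground truth marks the muscle-touching ring of every
    component of at least ``true_min_size`` cells as EP, i.e. the truth
    was produced with threshold ``true_min_size``; sweeping candidate
    thresholds over such pairs should recover it.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    m, n = shape
    sizes = [true_min_size - 1, true_min_size,
             int(rng.integers(2, true_min_size - 1)),
             int(rng.integers(true_min_size + 1, min(2 * true_min_size, n - 2)))]
    sizes.sort(reverse=True)  # place the large rectangles first

    for _attempt in range(50):
        labels = np.full((m, n), "MA", dtype="U2")
        occupied = np.zeros((m, n), dtype=bool)
        placed = 0
        for size in sizes:
            # random rectangle of `size` cells: pick a height dividing size
            hs = [h for h in range(1, size + 1)
                  if size % h == 0 and size // h <= n - 2 and h <= m - 2]
            h = int(rng.choice(hs))
            w = size // h
            for _ in range(200):
                i0 = int(rng.integers(1, m - h))
                j0 = int(rng.integers(1, n - w))
                # 1-cell separation so rectangles stay distinct components
                if not occupied[max(0, i0 - 1):i0 + h + 1,
                                max(0, j0 - 1):j0 + w + 1].any():
                    labels[i0:i0 + h, j0:j0 + w] = "LR"
                    occupied[i0:i0 + h, j0:j0 + w] = True
                    placed += 1
                    break
        if placed == len(sizes):
            break
    else:
        raise RuntimeError("could not place calibration rectangles")

    pred = LabelMatrix(labels.copy())
    # Ground truth: EP ring on every LR component of >= true_min_size cells.
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    comp, ncomp = ndimage.label(labels == "LR", structure=four)
    truth_arr = labels.copy()
    for k in range(1, ncomp + 1):
        cells = list(zip(*np.nonzero(comp == k)))
        if len(cells) < true_min_size:
            continue
        for i, j in cells:
            touches = any(
                0 <= i + di < m and 0 <= j + dj < n
                and labels[i + di, j + dj] == "MA"
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
            )
            if touches:
                truth_arr[i, j] = "EP"
    truth = LabelMatrix(truth_arr, np.full((m, n), "truth", dtype="U10"))
    return pred, truth
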