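"""Local binary pattern (LBP) texture descriptors for histology blocks.

A block of grayscale pixels is summarised by the classic 3x3 LBP operator:
each interior pixel's eight neighbours are thresholded against the pixel's
own value and the comparison bits are packed into an 8-bit code.  Two
histograms are built — the raw 256-bin LBP histogram and the 36-bin
rotation-invariant (LBPri) histogram obtained by canonicalising each code
to the minimum over its cyclic bit rotations — and concatenated into the
292-value descriptor used by the block classifier.

Conventions (fixed, so raw LBP bins are comparable across runs):

* neighbour ``p = 0`` is the east pixel, proceeding counter-clockwise
  (E, NE, N, NW, W, SW, S, SE);
* the comparison is ``s(g_p - g_c) = 1`` iff ``g_p >= g_c``;
* border pixels without a full 8-neighbourhood are skipped, so a
  ``100x100`` block contributes ``98 * 98 = 9604`` codes;
* grayscale conversion uses rounded ITU-R 601 luminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "LbpParams",
    "RiMapping",
    "DESCRIPTOR_LENGTH",
    "DESCRIPTOR_COLUMNS",
    "to_grayscale",
    "lbp_code",
    "min_rotation",
    "build_ri_mapping",
    "lbp_codes",
    "lbp_histogram",
    "lbpri_histogram",
    "describe_block",
]

#: ITU-R 601 luma weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])

#: (row, col) offsets of the 8-neighbour ring, p = 0 east, counter-clockwise.
#: Row axis points down, so "north" is a negative row offset.
NEIGHBOR_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1),
                    (0, -1), (1, -1), (1, 0), (1, 1))

DESCRIPTOR_LENGTH = 292
DESCRIPTOR_COLUMNS = tuple(f"lbp_{i:03d}" for i in range(256)) + tuple(
    f"ri_{i:02d}" for i in range(36)
)


@dataclass(frozen=True)
class LbpParams:
    """Neighbourhood parameters of the LBP operator.

    ``P`` is the number of ring neighbours and ``R`` the ring radius in
    pixels.  The reference configuration is ``P=8, R=1`` (the dense 3x3
    neighbourhood); ``P=4`` uses the axial subset of the ring.
    """

    P: int = 8
    R: int = 1

    def __post_init__(self) -> None:
        if self.P not in (4, 8):
            raise ValueError(f"P must be 4 or 8, got {self.P}")
        if self.R != 1:
            raise ValueError(f"only R=1 is supported, got {self.R}")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self.P == 8:
            return NEIGHBOR_OFFSETS
        return NEIGHBOR_OFFSETS[::2]


@dataclass(frozen=True)
class RiMapping:
    """Lookup table sending each LBP code to its rotation class index.

    Class indices are contiguous, assigned by ascending canonical
    (minimum-rotation) code; for ``P=8`` there are 36 classes.
    """

    P: int
    table: np.ndarray = field(repr=False)

    @property
    def n_classes(self) -> int:
        return int(self.table.max()) + 1


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to rounded ITU-R 601 luminance.

    A 2-D array is assumed to be grayscale already and passed through
    unchanged (after dtype normalisation).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image: expected at least one pixel")
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(
            f"expected HxWx3 RGB or HxW gray image, got shape {arr.shape}"
        )
    lum = arr[..., :3].astype(np.float64) @ _LUMA
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


def lbp_code(center: int, neighbors) -> int:
    """LBP code of one pixel: pack ``neighbor >= center`` bits, p-th bit
    weighted ``2**p``.  ``s(0) = 1`` (ties count as set bits)."""
    neighbors = list(neighbors)
    if len(neighbors) not in (4, 8):
        raise ValueError(f"expected 4 or 8 neighbors, got {len(neighbors)}")
    return sum((1 << p) for p, g in enumerate(neighbors) if g >= center)


def min_rotation(code: int, P: int = 8) -> int:
    """Canonicalise ``code`` to the minimum over its P cyclic bit rotations."""
    if not 0 <= code < (1 << P):
        raise ValueError(f"code {code} out of range for P={P}")
    mask = (1 << P) - 1
    return min(((code >> r) | (code << (P - r))) & mask for r in range(P))


@lru_cache(maxsize=None)
def build_ri_mapping(P: int = 8) -> RiMapping:
    """Partition the 2**P codes into cyclic-rotation orbits.

    Each orbit gets a contiguous class index, ordered by ascending
    canonical code.  For P=8 there are exactly 36 orbits.
    """
    canon = np.array([min_rotation(c, P) for c in range(1 << P)])
    classes = np.unique(canon)  # sorted ascending
    index = {c: i for i, c in enumerate(classes)}
    table = np.array([index[c] for c in canon], dtype=np.int64)
    table.setflags(write=False)
    return RiMapping(P=P, table=table)


def _validate_block(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D gray block, got ndim={gray.ndim}")
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(
            f"block must be at least 3x3 to have interior pixels, got {gray.shape}"
        )
    return gray


def lbp_codes(gray: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """Vectorised LBP codes of every interior pixel of a gray block.

    Returns an ``(H-2) x (W-2)`` integer array; border pixels are skipped
    because their ring is incomplete.
    """
    gray = _validate_block(gray)
    h, w = gray.shape
    center = gray[1:-1, 1:-1].astype(np.int16)
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dy, dx) in enumerate(params.offsets):
        neigh = gray[1 + dy:h - 1 + dy, 1 + dx:w - 1 + dx].astype(np.int16)
        codes |= (neigh >= center).astype(np.int64) << p
    return codes


def lbp_histogram(block: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """256-bin (2**P-bin) count histogram of LBP codes over interior pixels."""
    codes = lbp_codes(to_grayscale(block), params)
    return np.bincount(codes.ravel(), minlength=1 << params.P)


def lbpri_histogram(
    block: np.ndarray,
    params: LbpParams = LbpParams(),
    mapping: RiMapping | None = None,
) -> np.ndarray:
    """Rotation-invariant histogram: LBP codes binned through their orbit class."""
    if mapping is None:
        mapping = build_ri_mapping(params.P)
    codes = lbp_codes(to_grayscale(block), params)
    return np.bincount(mapping.table[codes.ravel()], minlength=mapping.n_classes)


def describe_block(
    block: np.ndarray,
    params: LbpParams = LbpParams(),
    mapping: RiMapping | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """292-value block descriptor: LBP histogram ++ LBPri histogram.

    Each sub-histogram is L1-normalised (sums to 1) unless
    ``normalize=False``, in which case raw counts are concatenated.
    Works on RGB or gray blocks of any size >= 3x3; the reference block
    size is 100x100.
    """
    if mapping is None:
        mapping = build_ri_mapping(params.P)
    gray = to_grayscale(block)
    codes = lbp_codes(gray, params).ravel()
    h_lbp = np.bincount(codes, minlength=1 << params.P).astype(np.float64)
    h_ri = np.bincount(
        mapping.table[codes], minlength=mapping.n_classes
    ).astype(np.float64)
    if normalize:
        h_lbp /= h_lbp.sum()
        h_ri /= h_ri.sum()
    return np.concatenate([h_lbp, h_ri])
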