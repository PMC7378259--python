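"""Ontology-driven refinement of block label matrices.

Two corrections are applied to a classifier-produced label matrix, in
order:

1. **Organ correction.**  Occurrences of the four discriminant classes
   (EA, LV, MA, HE — each implicating one organ) are counted; organs are
   ranked by count; for every higher-rank/lower-rank organ pair a
   ``(subject, hasPresenceOf, object)`` query is posed to the knowledge
   base.  An empty answer means the object organ cannot co-occur with
   the subject organ in one sample, so every block carrying the object
   organ's label is reclassified to loose connective tissue (LC) — the
   class false organ positives actually come from.  A non-empty answer
   validates the initial classification and leaves it untouched.

2. **Epithelium detection.**  Epithelial lining is invisible to the
   texture classifier at the 10x objective, but it coats lumina: large
   light regions (4-connected LR components of ten or more blocks) whose
   neighbourhood contains muscle are candidate lumina.  If the knowledge
   base links the image's dominant organ to an epithelium type, the LR
   cells sitting on the LR/muscle boundary are relabelled EP.

The minimum light-region size is a calibratable threshold ``t``:
:func:`calibrate_threshold` recovers it by exhaustively minimising the
total cell-wise disagreement (Hamming distance) between refined outputs
and ground-truth matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid_classify import DISCRIMINANT_LABELS, LabelMatrix
from .knowledge_base import KnowledgeBase, HAS_PRESENCE_OF, label_of, organ_of

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MIN_LR_BLOCKS",
    "DEFAULT_QUALIFYING_CLASSES",
    "Rule",
    "LightComponent",
    "CalibrationProblem",
    "count_occurrences",
    "rank_organs",
    "build_rules",
    "apply_rules",
    "find_light_components",
    "qualifies_for_epithelium",
    "detect_epithelium",
    "refine",
    "calibrate_threshold",
]

#: Light regions below this many 4-connected blocks are too small to be lumina.
DEFAULT_MIN_LR_BLOCKS = 10

#: Classes whose adjacency qualifies a light region as a lumen.  The three
#: smooth-muscle classes plus cardiac muscle: endocardium lines the heart's
#: chambers just as endothelium lines vessels.
DEFAULT_QUALIFYING_CLASSES = ("EA", "LV", "MA", "HE")

#: Organ priority for breaking occurrence-count ties (heart first).
_TIE_PRIORITY = ("HE", "MA", "EA", "LV")

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class Rule:
    """One presence query, with the occurrence ranks that produced it."""

    subject: str            # organ term, the higher-ranked
    predicate: str          # always hasPresenceOf
    obj: str                # organ term, the lower-ranked
    subject_rank: int = 0
    object_rank: int = 1


@dataclass(frozen=True)
class LightComponent:
    """A 4-connected set of LR grid cells."""

    cells: frozenset

    @property
    def size(self) -> int:
        return len(self.cells)

    def boundary(self) -> frozenset:
        """Member cells with at least one 4-neighbour outside the component."""
        out = set()
        for i, j in self.cells:
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if (i + di, j + dj) not in self.cells:
                    out.add((i, j))
                    break
        return frozenset(out)


def count_occurrences(matrix: LabelMatrix) -> dict[str, int]:
    """Block count of each discriminant class; LC/LR/EP are ignored."""
    return {
        lab: int((matrix.labels == lab).sum()) for lab in DISCRIMINANT_LABELS
    }


def rank_organs(table: dict[str, int]) -> list[str]:
    """Organs with count > 0, descending by count.

    Ties are broken by a fixed priority (heart, muscular artery, elastic
    artery, large vein) with a logged warning, so the ranking — and hence
    the rule set — is deterministic.
    """
    present = [(lab, n) for lab, n in table.items() if n > 0]
    counts = [n for _, n in present]
    if len(set(counts)) < len(counts):
        logger.warning(
            "occurrence tie in %s: breaking by fixed priority %s",
            table, _TIE_PRIORITY,
        )
    present.sort(key=lambda item: (-item[1], _TIE_PRIORITY.index(item[0])))
    return [organ_of(lab) for lab, _ in present]


def build_rules(ranked: Sequence[str]) -> list[Rule]:
    """Presence queries for every higher-rank -> lower-rank organ pair.

    ``k`` ranked organs yield ``k(k-1)/2`` rules, ordered by subject rank
    then object rank; a single ranked organ yields none.
    """
    rules = []
    for a in range(len(ranked)):
        for b in range(a + 1, len(ranked)):
            rules.append(Rule(
                subject=ranked[a], predicate=HAS_PRESENCE_OF, obj=ranked[b],
                subject_rank=a, object_rank=b,
            ))
    return rules


def apply_rules(
    matrix: LabelMatrix,
    rules: Sequence[Rule],
    kb: KnowledgeBase,
) -> LabelMatrix:
    """Reclassify impossible organ labels to loose connective tissue.

    A single pass in rule order: for each rule whose presence query
    answers empty, every cell bearing the object organ's discriminant
    label becomes LC with provenance ``corrected``.  Non-empty answers
    leave cells untouched.  Occurrence counts are not recomputed
    mid-pass.
    """
    out = matrix.copy()
    for rule in rules:
        if kb.ask_presence(rule.subject, rule.obj):
            continue  # presence asserted: initial classification validated
        target = label_of(rule.obj)
        hit = out.labels == target
        out.labels[hit] = "LC"
        out.provenance[hit] = "corrected"
    return out


def find_light_components(
    matrix: LabelMatrix,
    min_size: int = DEFAULT_MIN_LR_BLOCKS,
) -> list[LightComponent]:
    """4-connected LR components of at least ``min_size`` cells.

    Sorted by size descending (ties by first cell, for determinism).
    """
    mask = matrix.labels == "LR"
    labelled, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
    comps = []
    for k in range(1, n + 1):
        cells = frozenset(zip(*np.nonzero(labelled == k)))
        if len(cells) >= min_size:
            comps.append(LightComponent(cells=cells))
    comps.sort(key=lambda c: (-c.size, min(c.cells)))
    return comps


def _adjacent_cells(component: LightComponent, shape) -> set:
    """Grid cells 4-adjacent to the component but outside it."""
    m, n = shape
    out = set()
    for i, j in component.cells:
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (i + di, j + dj)
            if 0 <= q[0] < m and 0 <= q[1] < n and q not in component.cells:
                out.add(q)
    return out


def qualifies_for_epithelium(
    component: LightComponent,
    matrix: LabelMatrix,
    qualifying_classes: Sequence[str] = DEFAULT_QUALIFYING_CLASSES,
) -> bool:
    """Is the light region bordered by muscle tissue?

    True iff at least one cell 4-adjacent to the component carries a
    qualifying (muscle) label.  Light regions embedded in loose
    connective tissue — or touching only the matrix border — do not
    qualify, which suppresses false epithelium between connective
    tissue or near the adventitia.
    """
    qualifying = set(qualifying_classes)
    return any(
        matrix.labels[q] in qualifying
        for q in _adjacent_cells(component, matrix.shape)
    )


def detect_epithelium(
    matrix: LabelMatrix,
    kb: KnowledgeBase,
    min_size: int = DEFAULT_MIN_LR_BLOCKS,
    qualifying_classes: Sequence[str] = DEFAULT_QUALIFYING_CLASSES,
) -> LabelMatrix:
    """Relabel lumen-boundary light regions as epithelial tissue.

    For each qualifying LR component the knowledge base is asked which
    epithelium lines the image's dominant organ; a non-empty answer
    relabels every component cell that touches muscle (4-adjacency) to
    EP with provenance ``epithelium``.  An empty answer — no dominant
    organ or no epithelium fact — leaves the matrix unchanged.
    """
    ranked = rank_organs(count_occurrences(matrix))
    if not ranked:
        return matrix.copy()
    if kb.epithelium_of(ranked[0]) is None:
        return matrix.copy()
    qualifying = set(qualifying_classes)
    out = matrix.copy()
    for comp in find_light_components(matrix, min_size):
        if not qualifies_for_epithelium(comp, matrix, qualifying_classes):
            continue
        for i, j in comp.cells:
            touches_muscle = any(
                0 <= i + di < matrix.shape[0]
                and 0 <= j + dj < matrix.shape[1]
                and matrix.labels[i + di, j + dj] in qualifying
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
            )
            if touches_muscle:
                out.labels[i, j] = "EP"
                out.provenance[i, j] = "epithelium"
    return out


def refine(
    matrix: LabelMatrix,
    kb: KnowledgeBase,
    min_size: int = DEFAULT_MIN_LR_BLOCKS,
    qualifying_classes: Sequence[str] = DEFAULT_QUALIFYING_CLASSES,
) -> LabelMatrix:
    """Full refinement: organ correction, then epithelium detection.

    Idempotent on its own output: after the first pass only the dominant
    organ's label survives among discriminant classes (so no further
    rules fire) and lumen interiors no longer touch muscle (so no
    further EP cells appear).
    """
    table = count_occurrences(matrix)
    corrected = apply_rules(matrix, build_rules(rank_organs(table)), kb)
    return detect_epithelium(corrected, kb, min_size, qualifying_classes)


@dataclass
class CalibrationProblem:
    """Inputs of the light-region threshold calibration.

    ``pairs`` holds (classifier-output matrix, ground-truth matrix)
    couples; ``run`` produces the refined matrix for one input at a
    candidate threshold ``t`` (defaults to :func:`refine` against
    ``kb``).
    """

    candidates: Sequence[int]
    pairs: Sequence[tuple[LabelMatrix, LabelMatrix]]
    kb: KnowledgeBase
    qualifying_classes: Sequence[str] = DEFAULT_QUALIFYING_CLASSES
    run: Callable[[LabelMatrix, int], LabelMatrix] | None = field(default=None)

    def output_at(self, matrix: LabelMatrix, t: int) -> LabelMatrix:
        if self.run is not None:
            return self.run(matrix, t)
        return refine(matrix, self.kb, min_size=t,
                      qualifying_classes=self.qualifying_classes)


def calibrate_threshold(problem: CalibrationProblem) -> int:
    """Exhaustively minimise the aggregate refinement error over ``t``.

    The error of a candidate ``t`` is the summed Hamming distance (count
    of disagreeing cells) between each ground-truth matrix and the
    refined output produced with threshold ``t``.  The smallest ``t``
    wins ties.
    """
    candidates = sorted(set(int(t) for t in problem.candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    if not problem.pairs:
        raise ValueError("at least one (output, ground-truth) pair required")
    best_t, best_err = None, None
    for t in candidates:
        err = sum(
            truth.hamming(problem.output_at(matrix, t))
            for matrix, truth in problem.pairs
        )
        if best_err is None or err < best_err:
            best_t, best_err = t, err
    logger.info("calibrated min light-region size t*=%d (Ae=%d)", best_t, best_err)
    return best_t
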