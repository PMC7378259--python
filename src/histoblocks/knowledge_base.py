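"""Closed-world triple store of cardiovascular histology facts.

The refinement stage asks two kinds of question: "does organ A have
presence of organ B?" and "what epithelium lines organ X?".  Both reduce
to membership of ``(subject, predicate, object)`` triples in a finite
fact set — an absent fact answers *empty*, which downstream is read as
"impossible configuration, reclassify".  No subsumption inference is
performed: the fact set is small and the queries only ever exploit
emptiness vs non-emptiness, so direct closed-world membership gives the
same answers a DL reasoner would on this vocabulary.

Facts are serialised as Turtle with a fixed namespace prefix; loading
enforces the controlled vocabulary (unknown organs, predicates or
epithelium types are rejected, not silently kept).
"""

from __future__ import annotations

from pathlib import Path

from rdflib import Graph, Namespace, URIRef

__all__ = [
    "ORGANS",
    "TISSUES",
    "EPITHELIA",
    "PREDICATES",
    "HAS_PRESENCE_OF",
    "HAS_EPITHELIUM",
    "VocabularyError",
    "IntegrityError",
    "KnowledgeBase",
    "default_kb",
    "load_kb",
    "save_kb",
    "organ_of",
    "label_of",
]

NS = Namespace("https://histoblocks.readthedocs.io/vocab#")

ORGANS = ("Heart", "ElasticArtery", "MuscularArtery", "LargeVein")
TISSUES = ("CardiacMuscle", "SmoothMuscle", "LooseConnective", "EpithelialLining")
EPITHELIA = ("FlatSimpleEpithelium",)
HAS_PRESENCE_OF = "hasPresenceOf"
HAS_EPITHELIUM = "hasEpithelium"
PREDICATES = (HAS_PRESENCE_OF, HAS_EPITHELIUM)

_VOCABULARY = frozenset(ORGANS) | frozenset(TISSUES) | frozenset(EPITHELIA) \
    | frozenset(PREDICATES)

#: Discriminant tissue label -> organ term.
_LABEL_TO_ORGAN = {
    "EA": "ElasticArtery",
    "LV": "LargeVein",
    "MA": "MuscularArtery",
    "HE": "Heart",
}
_ORGAN_TO_LABEL = {v: k for k, v in _LABEL_TO_ORGAN.items()}


class VocabularyError(ValueError):
    """A term outside the controlled vocabulary was used."""


class IntegrityError(ValueError):
    """The fact set violates a uniqueness constraint."""


def _check_organ(term: str) -> str:
    if term not in ORGANS:
        raise VocabularyError(f"{term!r} is not a registered organ {ORGANS}")
    return term


class KnowledgeBase:
    """A finite, duplicate-free set of (subject, predicate, object) facts.

    Subjects are organs; ``hasPresenceOf`` objects are organs and
    ``hasEpithelium`` objects are epithelium types.  Queries over absent
    facts return empty (closed world) — emptiness is meaningful, not an
    error.
    """

    def __init__(self, triples=()) -> None:
        self._triples: set[tuple[str, str, str]] = set()
        for s, p, o in triples:
            self.add(s, p, o)

    @property
    def triples(self) -> frozenset:
        return frozenset(self._triples)

    def __len__(self) -> int:
        return len(self._triples)

    def __eq__(self, other) -> bool:
        return isinstance(other, KnowledgeBase) and self.triples == other.triples

    def add(self, subject: str, predicate: str, obj: str) -> None:
        _check_organ(subject)
        if predicate == HAS_PRESENCE_OF:
            _check_organ(obj)
        elif predicate == HAS_EPITHELIUM:
            if obj not in EPITHELIA:
                raise VocabularyError(
                    f"{obj!r} is not a registered epithelium type {EPITHELIA}"
                )
        else:
            raise VocabularyError(
                f"{predicate!r} is not a registered predicate {PREDICATES}"
            )
        self._triples.add((subject, predicate, obj))

    def ask_presence(self, organ_a: str, organ_b: str) -> bool:
        """Closed-world query: is (A, hasPresenceOf, B) asserted?

        Returns False ("empty") when the fact is absent; raises
        :class:`VocabularyError` for unregistered organs so that a typo
        is never mistaken for an empty answer.
        """
        _check_organ(organ_a)
        _check_organ(organ_b)
        return (organ_a, HAS_PRESENCE_OF, organ_b) in self._triples

    def epithelium_of(self, organ: str) -> str | None:
        """The unique epithelium type lining ``organ``, or None (empty).

        An empty answer means the image most likely contains no
        detectable epithelial tissue for this organ.
        """
        _check_organ(organ)
        hits = sorted(
            o for s, p, o in self._triples
            if s == organ and p == HAS_EPITHELIUM
        )
        if len(hits) > 1:
            raise IntegrityError(
                f"{organ} has {len(hits)} conflicting hasEpithelium facts: {hits}"
            )
        return hits[0] if hits else None


def default_kb() -> KnowledgeBase:
    """The default cardiovascular fact set.

    No cross-organ ``hasPresenceOf`` facts are asserted — a sample of one
    organ does not contain the muscle of another, so every cross-organ
    presence query answers empty and triggers reclassification.  Each of
    the four organs is lined by flat simple epithelium (the endothelium
    of vessels, the endocardium of the heart).
    """
    kb = KnowledgeBase()
    for organ in ORGANS:
        kb.add(organ, HAS_EPITHELIUM, "FlatSimpleEpithelium")
    return kb


def save_kb(kb: KnowledgeBase, path) -> None:
    """Serialise the fact set as Turtle with the ``histo:`` prefix."""
    g = Graph()
    g.bind("histo", NS)
    for s, p, o in sorted(kb.triples):
        g.add((NS[s], NS[p], NS[o]))
    Path(path).write_text(g.serialize(format="turtle"))


def _local_name(ref: URIRef, path) -> str:
    text = str(ref)
    if not text.startswith(str(NS)):
        raise VocabularyError(
            f"{path}: term {text!r} is outside the histoblocks namespace"
        )
    name = text[len(str(NS)):]
    if name not in _VOCABULARY:
        raise VocabularyError(f"{path}: unknown term {name!r}")
    return name


def load_kb(path) -> KnowledgeBase:
    """Parse a Turtle file into a KnowledgeBase, enforcing the vocabulary.

    Malformed Turtle raises rdflib's parse error (with source location);
    well-formed files using unknown terms raise :class:`VocabularyError`
    naming the term and file.
    """
    g = Graph()
    g.parse(str(path), format="turtle")
    kb = KnowledgeBase()
    for s, p, o in g:
        kb.add(_local_name(s, path), _local_name(p, path), _local_name(o, path))
    return kb


def organ_of(label: str):
    """Organ implicated by a discriminant tissue label, else None.

    EA/LV/MA/HE map to their organ; LC, LR and EP are not tied to any
    single organ.
    """
    return _LABEL_TO_ORGAN.get(label)


def label_of(organ: str) -> str:
    """Discriminant tissue label of an organ (inverse of :func:`organ_of`)."""
    return _ORGAN_TO_LABEL[_check_organ(organ)]
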