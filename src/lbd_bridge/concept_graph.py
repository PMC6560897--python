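"""Document-level concept co-occurrence and closed ABC discovery.

Closed literature-based discovery starts from a fixed start concept X
(a disease) and fixed end concepts Z (another disease) and enumerates
intermediate concepts Y — here restricted to a semantic type such as
``"Gene or Gene Product"`` — that co-occur with X in some documents and
with a Z in others.  The co-occurrence substrate is document-level and
binary: a concept pair is counted once per document in which both are
annotated, regardless of within-document multiplicity, mirroring
per-record MeSH-style indexing.

Each emitted intermediate carries FreqXY (documents linking it to X),
FreqYZ (documents linking it to the end concepts, summed over them) and
the product FreqXY x FreqYZ used to rank candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "AnnotatedDocument",
    "CooccurrenceIndex",
    "IntermediateRecord",
    "AnnotationError",
    "VocabularyError",
    "build_index",
    "pair_freq",
    "related_concepts",
    "closed_discovery",
    "score_intermediate",
]


class VocabularyError(KeyError):
    """A concept id was looked up that the vocabulary does not define."""


class AnnotationError(ValueError):
    """A document carries an annotation absent from the vocabulary."""


@dataclass(frozen=True)
class Concept:
    """A vocabulary entry: opaque id, display name, semantic type."""

    concept_id: str
    name: str
    semantic_type: str

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if not self.semantic_type:
            raise ValueError(f"semantic_type must be non-empty for {self.concept_id!r}")


@dataclass(frozen=True)
class AnnotatedDocument:
    """A document reduced to its set of annotated concept ids."""

    doc_id: str
    concepts: frozenset[str]

    def __init__(self, doc_id: str, concepts: Iterable[str]):
        object.__setattr__(self, "doc_id", doc_id)
        object.__setattr__(self, "concepts", frozenset(concepts))


@dataclass
class CooccurrenceIndex:
    """Document-level single and pairwise concept counts over a corpus.

    Invariants (enforced by :func:`build_index`):

    * ``pair_freq`` keys are unordered (frozenset) pairs, so symmetry is
      structural;
    * ``pair_freq[{a,b}] <= min(single_freq[a], single_freq[b])``;
    * ``single_freq[c] <= n_docs``.
    """

    n_docs: int
    single_freq: dict[str, int]
    pair_freq: dict[frozenset[str], int]
    vocabulary: dict[str, Concept]

    def require(self, concept_id: str) -> Concept:
        try:
            return self.vocabulary[concept_id]
        except KeyError:
            raise VocabularyError(f"unknown concept id {concept_id!r}") from None


def build_index(
    corpus: Iterable[AnnotatedDocument],
    vocabulary: Mapping[str, Concept],
) -> CooccurrenceIndex:
    """Count document-level concept singles and unordered pairs.

    Every concept id appearing in a document must exist in *vocabulary*;
    an empty corpus yields a valid index with ``n_docs == 0``.
    """
    single: dict[str, int] = {}
    pairs: dict[frozenset[str], int] = {}
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        for cid in doc.concepts:
            if cid not in vocabulary:
                raise AnnotationError(
                    f"document {doc.doc_id!r} annotated with unknown concept {cid!r}"
                )
            single[cid] = single.get(cid, 0) + 1
        for a, b in itertools.combinations(sorted(doc.concepts), 2):
            key = frozenset((a, b))
            pairs[key] = pairs.get(key, 0) + 1
    return CooccurrenceIndex(
        n_docs=n_docs,
        single_freq=single,
        pair_freq=pairs,
        vocabulary=dict(vocabulary),
    )


def pair_freq(index: CooccurrenceIndex, a: str, b: str) -> int:
    """Number of documents in which concepts *a* and *b* are co-annotated.

    Symmetric in its arguments; 0 when the pair never co-occurs.
    """
    if a == b:
        raise ValueError("pair_freq requires two distinct concepts")
    index.require(a)
    index.require(b)
    return index.pair_freq.get(frozenset((a, b)), 0)


def related_concepts(
    index: CooccurrenceIndex,
    c: str,
    semantic_type_filter: str,
    min_freq: int = 1,
) -> list[tuple[str, int]]:
    """Concepts of a given semantic type co-occurring with *c* at least *min_freq* times.

    Sorted by frequency descending, then concept id ascending.  An unknown
    semantic type simply matches nothing.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    index.require(c)
    hits: list[tuple[str, int]] = []
    for key, freq in index.pair_freq.items():
        if c not in key or freq < min_freq:
            continue
        (other,) = key - {c}
        if index.vocabulary[other].semantic_type == semantic_type_filter:
            hits.append((other, freq))
    hits.sort(key=lambda item: (-item[1], item[0]))
    return hits


@dataclass(frozen=True)
class IntermediateRecord:
    """A candidate intermediate Y linking X to the end concepts Z.

    ``freq_yz_per_z`` retains the per-end-concept counts; the combined
    FreqYZ is their sum over end concepts the gene actually co-occurs
    with, and ``product_score = freq_xy * freq_yz_combined``.
    """

    gene_symbol: str
    concept_id: str
    freq_xy: int
    freq_yz_per_z: Mapping[str, int]
    freq_yz_combined: int
    product_score: int


def score_intermediate(freq_xy: int, freq_yz: int) -> int:
    """Rank score of an intermediate: the product FreqXY x FreqYZ."""
    if freq_xy < 0 or freq_yz < 0:
        raise ValueError("co-occurrence frequencies cannot be negative")
    return freq_xy * freq_yz


def closed_discovery(
    index: CooccurrenceIndex,
    x: str,
    z_list: Sequence[str],
    y_semantic_type: str = "Gene or Gene Product",
    combine_mode: str = "union",
    min_freq: int = 1,
) -> list[IntermediateRecord]:
    """Enumerate intermediates Y of a semantic type linking X to the Z concepts.

    For each end concept z the per-z candidate set holds every concept y of
    type *y_semantic_type* with ``pair_freq(x, y) >= min_freq`` and
    ``pair_freq(y, z) >= min_freq``.  ``combine_mode`` pools the per-z sets:

    ``"union"``
        y must reach X and at least one z (default — matches pooling two
        end-concept candidate lists into one);
    ``"intersection"``
        y must reach X and every z.

    Records are sorted by product score descending, then symbol ascending.
    """
    if not z_list:
        raise ValueError("z_list must be non-empty")
    if x in z_list:
        raise ValueError("start concept x must not appear in z_list")
    if combine_mode not in ("union", "intersection"):
        raise ValueError(f"unknown combine_mode {combine_mode!r}")

    per_z_sets: list[set[str]] = []
    for z in z_list:
        neighbours = {
            y
            for y, _ in related_concepts(index, z, y_semantic_type, min_freq)
            if y != x and pair_freq(index, x, y) >= min_freq
        }
        per_z_sets.append(neighbours)

    if combine_mode == "union":
        candidates = set().union(*per_z_sets)
    else:
        candidates = set.intersection(*per_z_sets)

    records = []
    for y in candidates:
        fxy = pair_freq(index, x, y)
        per_z = {z: pair_freq(index, y, z) for z in z_list}
        co_occurring = {z: f for z, f in per_z.items() if f > 0}
        fyz = sum(co_occurring.values())
        if fxy < 1 or fyz < 1:
            continue
        records.append(
            IntermediateRecord(
                gene_symbol=index.vocabulary[y].name,
                concept_id=y,
                freq_xy=fxy,
                freq_yz_per_z=per_z,
                freq_yz_combined=fyz,
                product_score=score_intermediate(fxy, fyz),
            )
        )
    records.sort(key=lambda r: (-r.product_score, r.gene_symbol))
    logger.info(
        "closed discovery: %d candidates (mode=%s, min_freq=%d)",
        len(records),
        combine_mode,
        min_freq,
    )
    return records
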