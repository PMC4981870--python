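"""Gold-standard co-functional gene pairs.

Positives pair genes sharing at least one annotation term; negatives pair
annotated genes sharing none.  Over-broad terms would dominate the pair
counts (a single term with k genes yields C(k,2) positives), so terms
with too many genes are discarded before pairing, and ontology terms
outside a depth window are dropped when depth metadata is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .datamodel import AnnotationSet, DataError, GenePair, gene_pair

logger = logging.getLogger("netforge")


@dataclass
class TermFilter:
    """Term-specificity filter: ontology depth window plus size cap.

    Terms shallower than ``min_level`` are too general, deeper than
    ``max_level`` too specific; terms with more than ``max_term_size``
    genes generate biased pair counts.
    """

    min_level: int = 2
    max_level: int = 10
    max_term_size: int = 300

    def __post_init__(self) -> None:
        if self.min_level > self.max_level:
            raise DataError("min_level must not exceed max_level")
        if self.max_term_size < 2:
            raise DataError("max_term_size must be >= 2")


@dataclass
class GoldStandard:
    """Disjoint positive/negative unordered gene-pair sets."""

    positives: set[GenePair]
    negatives: set[GenePair]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise DataError(f"{len(overlap)} pairs are both positive and negative")
        if not self.universe:
            genes: set[str] = set()
            for a, b in itertools.chain(self.positives, self.negatives):
                genes.add(a)
                genes.add(b)
            self.universe = frozenset(genes)


def filter_terms(ann: AnnotationSet, f: TermFilter) -> AnnotationSet:
    """Apply the depth-window and size filters to an annotation set.

    The depth filter only applies to terms carrying a ``level`` in
    ``term_meta``; annotation sources without depth metadata (pathway
    databases) are filtered on size alone.
    """
    kept: dict[str, frozenset[str]] = {}
    for term, genes in ann.terms.items():
        level = ann.term_meta.get(term, {}).get("level")
        if level is not None and not (f.min_level <= level <= f.max_level):
            continue
        if len(genes) > f.max_term_size:
            continue
        kept[term] = genes
    if not kept:
        logger.warning("term filter removed all %d terms", len(ann.terms))
    meta = {t: m for t, m in ann.term_meta.items() if t in kept}
    return AnnotationSet(terms=kept, term_meta=meta)


def build_positives(ann: AnnotationSet) -> set[GenePair]:
    """All unordered pairs of genes co-annotated by at least one term."""
    positives: set[GenePair] = set()
    for genes in ann.terms.values():
        for a, b in itertools.combinations(sorted(genes), 2):
            positives.add(gene_pair(a, b))
    return positives


def build_negatives(ann: AnnotationSet) -> set[GenePair]:
    """All unordered pairs of annotated genes sharing zero terms."""
    gene_terms = ann.gene_to_terms()
    genes = sorted(gene_terms)
    negatives: set[GenePair] = set()
    for i, a in enumerate(genes):
        ta = gene_terms[a]
        for b in genes[i + 1 :]:
            if ta.isdisjoint(gene_terms[b]):
                negatives.add((a, b))
    return negatives


def build_gold_standard(ann: AnnotationSet, f: TermFilter | None = None) -> GoldStandard:
    """Filter terms then derive positive and negative pairs in one step."""
    if f is not None:
        ann = filter_terms(ann, f)
    return GoldStandard(
        positives=build_positives(ann),
        negatives=build_negatives(ann),
        universe=ann.universe,
    )


def merge_gold(standards: list[GoldStandard]) -> GoldStandard:
    """Merge gold standards from several annotation sources.

    A shared annotation anywhere is positive evidence, so a pair that is
    positive in any source is removed from the merged negatives.
    """
    if not standards:
        raise DataError("merge_gold requires at least one input")
    positives: set[GenePair] = set()
    negatives: set[GenePair] = set()
    universe: set[str] = set()
    for gs in standards:
        positives |= gs.positives
        negatives |= gs.negatives
        universe |= gs.universe
    negatives -= positives
    return GoldStandard(positives=positives, negatives=negatives, universe=frozenset(universe))
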