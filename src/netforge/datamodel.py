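"""Core domain containers for co-functional gene networks.

A gene identifier is a plain string token (no whitespace); a gene pair is
always stored canonically with the lexicographically smaller identifier
first, which makes every edge set an unordered simple graph by
construction.  Networks carry either log-likelihood scores (LLS, one
evidence dataset) or weighted-sum scores (WS, the integrated network) as
edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger("netforge")

GenePair = tuple[str, str]


class DataError(ValueError):
    """Raised for malformed input data (CLI exit code 2)."""


def validate_gene_id(gene: str) -> str:
    """Validate a gene identifier: non-empty, no internal whitespace."""
    if not isinstance(gene, str) or not gene or any(c.isspace() for c in gene):
        raise DataError(f"invalid gene identifier: {gene!r}")
    return gene


def gene_pair(a: str, b: str) -> GenePair:
    """Return the canonical unordered pair (smaller identifier first).

    Self-pairs are rejected: a gene is never co-functional with itself in
    the pairing sense used here.
    """
    if a == b:
        raise DataError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class AnnotationSet:
    """Mapping of annotation terms (GO-BP, pathways, domains...) to gene sets.

    ``term_meta`` optionally carries per-term metadata, notably the
    ontology ``level`` (depth) used for term-specificity filtering and a
    human-readable ``name``.
    """

    terms: dict[str, frozenset[str]]
    term_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(gs) for t, gs in self.terms.items()}
        for term, genes in self.terms.items():
            if not genes:
                raise DataError(f"term {term!r} has an empty gene set")

    @property
    def universe(self) -> frozenset[str]:
        """All genes annotated by at least one term."""
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        """Invert the term map: gene -> set of annotating terms."""
        inv: dict[str, set[str]] = {}
        for term, genes in self.terms.items():
            for g in genes:
                inv.setdefault(g, set()).add(term)
        return {g: frozenset(ts) for g, ts in inv.items()}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class ScoredPairTable:
    """One evidence dataset's continuous scores on unordered gene pairs.

    ``rows`` maps canonical pairs to the dataset-intrinsic score (mutual
    information, correlation coefficient, gene distance statistic, ...),
    before any LLS calibration.
    """

    dataset_id: str
    rows: dict[GenePair, float]

    def __post_init__(self) -> None:
        for pair, score in self.rows.items():
            if pair[0] >= pair[1]:
                raise DataError(f"non-canonical or self pair {pair!r}")
            if not np.isfinite(score):
                raise DataError(f"non-finite score for pair {pair!r}")

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.rows:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.rows)


class _EdgeNetwork:
    """Shared behaviour of weighted undirected simple networks."""

    edges: dict[GenePair, float]

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Gene -> {neighbour -> edge weight}."""
        adj: dict[str, dict[str, float]] = {}
        for (a, b), w in self.edges.items():
            adj.setdefault(a, {})[b] = w
            adj.setdefault(b, {})[a] = w
        return adj

    def ranked_edges(self) -> list[tuple[GenePair, float]]:
        """Edges sorted by descending weight, ties by canonical pair order."""
        return sorted(self.edges.items(), key=lambda kv: (-kv[1], kv[0]))

    def __len__(self) -> int:
        return len(self.edges)

    def _check_edges(self) -> None:
        for pair in self.edges:
            if pair[0] >= pair[1]:
                raise DataError(f"non-canonical or self edge {pair!r}")


@dataclass
class ComponentNetwork(_EdgeNetwork):
    """A single evidence dataset's calibrated network; weights are LLS."""

    dataset_id: str
    edges: dict[GenePair, float]

    def __post_init__(self) -> None:
        self._check_edges()


@dataclass
class IntegratedNetwork(_EdgeNetwork):
    """The comprehensive network after weighted-sum integration.

    ``provenance`` records, per edge, the supporting (dataset_id, lls)
    evidence that passed the integration threshold.
    """

    edges: dict[GenePair, float]
    provenance: dict[GenePair, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_edges()


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (one microarray/RNA-seq dataset)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene rows in expression matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def iter_pairs(genes: Iterable[str]) -> Iterator[GenePair]:
    """All canonical unordered pairs of the given genes."""
    ordered = sorted(set(genes))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            yield (a, b)
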