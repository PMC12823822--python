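"""Metapath label extraction: positives, unlabeled genes, and EFO features.

For a disease anchored at one or more CUIs, two fixed 2-hop metapaths
define the learning problem:

* **positives** — genes reached by Disease-Compound-Gene: a gene counts as
  a known (class-1) disease gene exactly when some compound links it to a
  disease anchor.  Direct Disease-Gene edges do NOT qualify: routing the
  label through compounds keeps the labeled set an (approximately) random
  sample of the positive class, which is the SCAR premise the downstream
  prior estimator relies on.
* **unlabeled** — genes reached by PositiveGene-EFO-Gene that are not
  themselves positive: class 0, a mix of hidden positives and negatives.

The Experimental Factor Ontology (EFO) nodes realizing the second metapath
become the binary feature vocabulary; the compounds realizing the first
are recorded and barred from the feature space.  Relationship types along
either metapath are deliberately unconstrained — any edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import PropertyGraph, neighbors

__all__ = [
    "DiseaseQuery",
    "LabelSet",
    "LabelingError",
    "extract_labels",
    "label_vector",
]


class LabelingError(ValueError):
    """Raised when label extraction cannot proceed on the given graph."""


@dataclass(frozen=True)
class DiseaseQuery:
    """One disease, possibly split over several CUIs (anchors are unioned)."""

    disease_cuis: tuple[str, ...]
    disease_name: str = ""

    def __post_init__(self) -> None:
        if not self.disease_cuis:
            raise ValueError("disease query needs at least one CUI")
        if len(set(self.disease_cuis)) != len(self.disease_cuis):
            raise ValueError("disease CUIs must be distinct")

    @classmethod
    def from_cuis(cls, cuis, name: str = "") -> "DiseaseQuery":
        return cls(tuple(cuis), name)


@dataclass
class LabelSet:
    """Result of the metapath queries for one disease.

    Invariants: positives and unlabeled are disjoint; every feature EFO is
    adjacent to at least one positive gene; every unlabeled gene is
    adjacent to at least one feature EFO.
    """

    positive_cuis: set[str] = field(default_factory=set)
    unlabeled_cuis: set[str] = field(default_factory=set)
    feature_efo_cuis: set[str] = field(default_factory=set)
    removed_compound_cuis: set[str] = field(default_factory=set)

    def validate(self) -> None:
        overlap = self.positive_cuis & self.unlabeled_cuis
        if overlap:
            raise LabelingError(f"positive/unlabeled overlap: {sorted(overlap)[:5]}")


def extract_labels(graph: PropertyGraph, query: DiseaseQuery) -> LabelSet:
    """Run the two metapath queries and return the resulting label sets.

    Set-valued (DISTINCT) semantics: the result is independent of edge
    order and of how many parallel relations realize a hop.  A gene
    reachable both as a positive and via an EFO path is positive only.

    Raises :class:`LabelingError` if no disease anchor is present in the
    graph, or if the positive set comes out empty (nothing downstream can
    learn from zero positives).
    """
    anchors = [c for c in query.disease_cuis if c in graph]
    if not anchors:
        raise LabelingError(
            f"no disease node found for CUIs {sorted(query.disease_cuis)}"
        )

    positives: set[str] = set()
    removed_compounds: set[str] = set()
    for d in anchors:
        for c in neighbors(graph, d, type_filter="Compound"):
            genes = neighbors(graph, c, type_filter="Gene")
            if genes:
                positives |= genes
                removed_compounds.add(c)
    if not positives:
        raise LabelingError(
            f"no positive genes: no Disease-Compound-Gene path from anchors {anchors}"
        )

    feature_efos: set[str] = set()
    unlabeled: set[str] = set()
    for g1 in positives:
        for e in neighbors(graph, g1, type_filter="EFO"):
            g2s = neighbors(graph, e, type_filter="Gene") - positives
            if g2s:
                feature_efos.add(e)
                unlabeled |= g2s

    labels = LabelSet(
        positive_cuis=positives,
        unlabeled_cuis=unlabeled,
        feature_efo_cuis=feature_efos,
        removed_compound_cuis=removed_compounds,
    )
    labels.validate()
    return labels


def label_vector(labels: LabelSet) -> list[tuple[str, int]]:
    """Deterministic (gene_cui, class) ordering: positives first, each block
    sorted lexicographically by CUI."""
    labels.validate()
    return [(c, 1) for c in sorted(labels.positive_cuis)] + [
        (c, 0) for c in sorted(labels.unlabeled_cuis)
    ]
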