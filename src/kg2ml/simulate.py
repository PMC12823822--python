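"""Synthetic knowledge graphs and PU matrices with planted hidden positives.

Real disease-gene knowledge graphs have no ground truth for the unlabeled
set, so every quantitative claim about the estimator is checked here
instead: the generator plants a known fraction of hidden positives and the
pipeline must recover it.

Two generators share one generative model:

* a **positive profile**: Bernoulli(p_signal) links to a small set of
  signal EFO terms plus Bernoulli(p_background) links to background terms;
* a **negative profile**: Bernoulli(p_background) links everywhere;
* genes carrying the positive profile split into *labeled* positives — a
  uniform random subset, so labeling is independent of the realized
  features (SCAR holds by construction) — and *hidden* positives, which
  keep the positive link profile but get no compound path to the disease;
* every entry is then flipped with probability ``flip_noise``.

``simulate_kg`` materializes this as a typed property graph (one Disease
node, compounds wiring only the labeled positives to it, Gene-EFO edges
from the profiles), so the whole metapath pipeline can run end to end;
``simulate_pu_matrix`` skips the graph and emits the feature matrix
directly for estimator-level tests.  Both are deterministic given
``spec.seed``.

Default sizes (6,000 genes, 1,200 labeled positives, 300 EFO features of
which 40 carry signal) mirror the per-disease scale of real condensed
biomedical KGs — a couple of thousand labeled genes against several
thousand unlabeled ones with a few hundred path features — at a cost that
keeps repeated-CV experiments cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .features import FeatureMatrix
from .graph import EdgeRecord, NodeRecord, PropertyGraph

__all__ = ["KGSimSpec", "GroundTruth", "simulate_kg", "simulate_pu_matrix",
           "write_truth", "read_truth"]


@dataclass(frozen=True)
class KGSimSpec:
    """Generator settings; ``true_alpha`` is the planted fraction of hidden
    positives among the nominal unlabeled genes."""

    n_genes: int = 6000
    n_compounds: int = 200
    n_labeled_positive: int = 1200
    true_alpha: float = 0.3
    n_signal_efo: int = 40
    n_background_efo: int = 260
    p_signal: float = 0.35
    p_background: float = 0.05
    flip_noise: float = 0.05
    seed: int = 0

    @property
    def n_efo(self) -> int:
        return self.n_signal_efo + self.n_background_efo

    @property
    def n_unlabeled(self) -> int:
        return self.n_genes - self.n_labeled_positive

    @property
    def n_hidden_positive(self) -> int:
        return int(round(self.true_alpha * self.n_unlabeled))

    def validate(self) -> None:
        if not 0 <= self.true_alpha < 1:
            raise ValueError("true_alpha must lie in [0, 1)")
        if not self.p_signal > self.p_background:
            raise ValueError("p_signal must exceed p_background (separability)")
        if self.n_labeled_positive >= self.n_genes:
            raise ValueError("n_labeled_positive must be < n_genes")
        if self.n_labeled_positive < 1 or self.n_signal_efo < 1:
            raise ValueError("need at least one labeled positive and one signal EFO")
        for p in (self.p_signal, self.p_background, self.flip_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted gene roles; the three sets partition all genes."""

    labeled_positive_cuis: set[str]
    hidden_positive_cuis: set[str]
    negative_cuis: set[str]

    @property
    def all_genes(self) -> set[str]:
        return (self.labeled_positive_cuis | self.hidden_positive_cuis
                | self.negative_cuis)


def _gene_roles(spec: KGSimSpec, rng: np.random.Generator):
    genes = [f"G{i:06d}" for i in range(spec.n_genes)]
    perm = rng.permutation(spec.n_genes)
    n_pos_profile = spec.n_labeled_positive + spec.n_hidden_positive
    labeled = {genes[i] for i in perm[: spec.n_labeled_positive]}
    hidden = {genes[i] for i in perm[spec.n_labeled_positive:n_pos_profile]}
    negative = {genes[i] for i in perm[n_pos_profile:]}
    return genes, GroundTruth(labeled, hidden, negative)


def _link_profile(
    spec: KGSimSpec, genes: list[str], truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Dense 0/1 gene x EFO link matrix drawn from the two profiles."""
    pos_profile = np.array(
        [g in truth.labeled_positive_cuis or g in truth.hidden_positive_cuis
         for g in genes]
    )
    p = np.full((spec.n_genes, spec.n_efo), spec.p_background)
    p[np.ix_(pos_profile, np.arange(spec.n_signal_efo))] = spec.p_signal
    links = (rng.random((spec.n_genes, spec.n_efo)) < p).astype(np.int8)
    if spec.flip_noise > 0:
        flips = rng.random((spec.n_genes, spec.n_efo)) < spec.flip_noise
        links ^= flips.astype(np.int8)
    return links


def simulate_kg(spec: KGSimSpec) -> tuple[PropertyGraph, GroundTruth]:
    """Typed property graph with planted roles.

    Labeled positives are wired Disease-Compound-Gene (one to three
    compounds each); hidden positives and negatives get no compound path,
    so metapath label extraction recovers the labeled positives exactly
    and files everything EFO-reachable as unlabeled.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes, truth = _gene_roles(spec, rng)
    efos = [f"E{j:04d}" for j in range(spec.n_efo)]
    compounds = [f"C{k:04d}" for k in range(spec.n_compounds)]
    disease = "D0001"

    nodes = [NodeRecord(disease, "Disease", "synthetic disease")]
    nodes += [NodeRecord(c, "Compound", f"compound {c}") for c in compounds]
    nodes += [NodeRecord(g, "Gene", f"gene {g}") for g in genes]
    nodes += [NodeRecord(e, "EFO", f"EFO term {e}") for e in efos]

    edges: list[EdgeRecord] = []
    used_compounds: set[str] = set()
    for g in sorted(truth.labeled_positive_cuis):
        k = int(rng.integers(1, 4))
        for c_idx in rng.choice(spec.n_compounds, size=k, replace=False):
            c = compounds[c_idx]
            used_compounds.add(c)
            edges.append(EdgeRecord(c, g, "compound_gene", "SIM"))
    for c in sorted(used_compounds):
        edges.append(EdgeRecord(disease, c, "disease_compound", "SIM"))

    links = _link_profile(spec, genes, truth, rng)
    gi, ej = np.nonzero(links)
    for i, j in zip(gi, ej):
        edges.append(EdgeRecord(genes[i], efos[j], "gene_efo", "SIM"))

    return PropertyGraph.from_records(nodes, edges), truth


def simulate_pu_matrix(spec: KGSimSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Feature matrix drawn directly from the two Bernoulli profiles.

    Rows follow the pipeline convention (labeled positives first, then
    unlabeled, each block CUI-sorted); y is 1 for labeled positives only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes, truth = _gene_roles(spec, rng)
    links = _link_profile(spec, genes, truth, rng)

    order = sorted(truth.labeled_positive_cuis) + sorted(
        truth.hidden_positive_cuis | truth.negative_cuis
    )
    idx = {g: i for i, g in enumerate(genes)}
    values = sp.csr_matrix(links[[idx[g] for g in order]])
    y = np.array([1] * spec.n_labeled_positive + [0] * spec.n_unlabeled,
                 dtype=np.int8)
    cols = [f"E{j:04d}" for j in range(spec.n_efo)]
    return FeatureMatrix(order, cols, values, y), truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_cui\trole\n")
        for role, cuis in (
            ("labeled_positive", truth.labeled_positive_cuis),
            ("hidden_positive", truth.hidden_positive_cuis),
            ("negative", truth.negative_cuis),
        ):
            for c in sorted(cuis):
                fh.write(f"{c}\t{role}\n")


def read_truth(path: str | Path) -> GroundTruth:
    roles: dict[str, set[str]] = {
        "labeled_positive": set(), "hidden_positive": set(), "negative": set()
    }
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_cui", "role"]:
            raise ValueError(f"unexpected truth header {header}")
        for line in fh:
            cui, role = line.rstrip("\n").split("\t")
            roles[role].add(cui)
    return GroundTruth(roles["labeled_positive"], roles["hidden_positive"],
                       roles["negative"])
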