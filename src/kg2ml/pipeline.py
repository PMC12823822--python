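"""Pipeline orchestration: run every stage in order and persist artifacts.

Stages: (optional) simulate -> load -> condense -> label -> featurize ->
pulscar -> evaluate -> rank.  Every intermediate artifact is written to
the output directory in a plain-text format, and a manifest records the
package version, all parameters, per-stage artifact checksums and the base
seed, so a re-run with an identical config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .evaluation import EvalConfig, compare, run_model1, run_model2
from .features import build_feature_matrix, prune_columns, read_matrix, write_matrix
from .graph import condense, load_graph, write_graph
from .labeling import DiseaseQuery, LabelSet, extract_labels
from .pulscar import (
    AlphaEstimate,
    CalibratedScores,
    ImputedSet,
    PulscarConfig,
    impute_positives,
    rank_genes,
    run_pulscar,
)
from .simulate import KGSimSpec, simulate_kg, write_truth

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "write_labels",
    "read_labels",
    "write_alpha_json",
    "write_scores",
    "read_imputed",
]

DEFAULT_KEEP_TYPES = ("Disease", "Compound", "Gene", "EFO")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``simulate`` is true (a synthetic graph is generated into the
    output directory) or ``nodes_table``/``edges_table`` must point at an
    existing graph.  All randomness derives from ``base_seed``.
    """

    out_dir: str = "kg2ml_run"
    simulate: bool = False
    nodes_table: str | None = None
    edges_table: str | None = None
    disease_cuis: tuple[str, ...] = ()
    disease_name: str = ""
    keep_types: tuple[str, ...] = DEFAULT_KEEP_TYPES
    min_feature_count: int = 1
    top_k: int = 15
    base_seed: int = 42
    sim_spec: KGSimSpec = field(default_factory=KGSimSpec)
    pulscar: PulscarConfig = field(default_factory=PulscarConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "sim_spec":
                kwargs[key] = KGSimSpec(**value)
            elif key == "pulscar":
                kwargs[key] = PulscarConfig(**value)
            elif key == "evaluation":
                kwargs[key] = EvalConfig(**{
                    k: tuple(v) if k == "metrics" else v for k, v in value.items()
                })
            elif key in ("disease_cuis", "keep_types"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# artifact writers/readers (plain text, byte-deterministic)

def write_labels(labels: LabelSet, labels_path: str | Path,
                 features_path: str | Path,
                 removed_path: str | Path | None = None) -> None:
    with Path(labels_path).open("w") as fh:
        fh.write("gene_cui\tclass\trole\n")
        for c in sorted(labels.positive_cuis):
            fh.write(f"{c}\t1\tpositive\n")
        for c in sorted(labels.unlabeled_cuis):
            fh.write(f"{c}\t0\tunlabeled\n")
    with Path(features_path).open("w") as fh:
        fh.write("efo_cui\n")
        for c in sorted(labels.feature_efo_cuis):
            fh.write(f"{c}\n")
    if removed_path is not None:
        with Path(removed_path).open("w") as fh:
            fh.write("compound_cui\n")
            for c in sorted(labels.removed_compound_cuis):
                fh.write(f"{c}\n")


def read_labels(labels_path: str | Path, features_path: str | Path,
                removed_path: str | Path | None = None) -> LabelSet:
    labels = LabelSet()
    with Path(labels_path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_cui", "class", "role"]:
            raise ValueError(f"unexpected labels header {header}")
        for line in fh:
            cui, cls, _role = line.rstrip("\n").split("\t")
            (labels.positive_cuis if cls == "1" else labels.unlabeled_cuis).add(cui)
    with Path(features_path).open() as fh:
        fh.readline()
        labels.feature_efo_cuis = {line.strip() for line in fh if line.strip()}
    if removed_path is not None and Path(removed_path).exists():
        with Path(removed_path).open() as fh:
            fh.readline()
            labels.removed_compound_cuis = {
                line.strip() for line in fh if line.strip()
            }
    return labels


def write_alpha_json(ae: AlphaEstimate, path: str | Path) -> None:
    payload = {
        "mean_alpha": ae.mean_alpha,
        "ci_lower": ae.ci_lower,
        "ci_upper": ae.ci_upper,
        "per_iteration_alphas": [float(a) for a in ae.per_iteration_alphas],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_scores(cs: CalibratedScores, imputed: ImputedSet,
                 path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_cui\tmean_prob\timputed_flag\n")
        order = sorted(zip(cs.gene_cuis, cs.mean_probs),
                       key=lambda t: (-t[1], t[0]))
        for cui, p in order:
            flag = int(cui in imputed.probable_positive_cuis)
            fh.write(f"{cui}\t{float(p)!r}\t{flag}\n")


def read_imputed(path: str | Path) -> ImputedSet:
    cuis = set()
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_cui", "mean_prob", "imputed_flag"]:
            raise ValueError(f"unexpected scores header {header}")
        for line in fh:
            cui, _p, flag = line.rstrip("\n").split("\t")
            if flag == "1":
                cuis.add(cui)
    return ImputedSet(probable_positive_cuis=cuis,
                      rule="read from scores table (imputed_flag == 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "kg2ml_version": __version__,
        "base_seed": config.base_seed,
        "parameters": {
            "keep_types": list(config.keep_types),
            "min_feature_count": config.min_feature_count,
            "top_k": config.top_k,
            "sim_spec": asdict(config.sim_spec) if config.simulate else None,
            "pulscar": {k: v for k, v in asdict(config.pulscar).items()},
            "evaluation": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in asdict(config.evaluation).items()},
        },
        "stages": {},
    }

    def record(stage: str, artifacts: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in artifacts.items()
        }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    nodes_path, edges_path = config.nodes_table, config.edges_table
    disease_cuis = config.disease_cuis
    truth = None
    if config.simulate:
        with stage("simulate"):
            import dataclasses

            spec = dataclasses.replace(config.sim_spec, seed=config.base_seed)
            graph, truth = simulate_kg(spec)
            nodes_path = str(out / "nodes.tsv")
            edges_path = str(out / "edges.tsv")
            write_graph(graph, nodes_path, edges_path)
            write_truth(truth, out / "truth.tsv")
            record("simulate", {"nodes": Path(nodes_path),
                                "edges": Path(edges_path),
                                "truth": out / "truth.tsv"})
            if not disease_cuis:
                disease_cuis = ("D0001",)

    with stage("load"):
        if not nodes_path or not edges_path:
            raise FileNotFoundError("no graph tables configured")
        graph = load_graph(nodes_path, edges_path)

    with stage("condense"):
        graph = condense(graph, set(config.keep_types))
        cn, ce = out / "condensed_nodes.tsv", out / "condensed_edges.tsv"
        write_graph(graph, cn, ce)
        record("condense", {"nodes": cn, "edges": ce})

    with stage("label"):
        query = DiseaseQuery.from_cuis(disease_cuis, config.disease_name)
        labels = extract_labels(graph, query)
        lp, fp, rp = (out / "labels.tsv", out / "features.tsv",
                      out / "removed_compounds.tsv")
        write_labels(labels, lp, fp, rp)
        record("label", {"labels": lp, "features": fp, "removed_compounds": rp})

    with stage("featurize"):
        fm = build_feature_matrix(graph, labels)
        fm = prune_columns(fm, config.min_feature_count)
        matrix_dir = out / "matrix"
        artifacts = write_matrix(fm, matrix_dir)
        record("featurize", artifacts)

    with stage("pulscar"):
        import dataclasses

        pcfg = dataclasses.replace(config.pulscar, base_seed=config.base_seed)
        ae, cs = run_pulscar(fm, pcfg)
        imputed = impute_positives(cs, ae)
        ap, sp_ = out / "alpha.json", out / "scores.tsv"
        write_alpha_json(ae, ap)
        write_scores(cs, imputed, sp_)
        record("pulscar", {"alpha": ap, "scores": sp_})

    with stage("evaluate"):
        import dataclasses

        ecfg = dataclasses.replace(config.evaluation, base_seed=config.base_seed)
        m1 = run_model1(fm, ecfg)
        m2 = run_model2(fm, imputed, ecfg)
        cp, pp = out / "comparison.json", out / "comparison.png"
        comparison = compare(m1, m2, ecfg, plot_path=pp)
        payload = {
            "convention": "metrics computed against working labels "
                          "(unlabeled = negative), except "
                          "recall_on_labeled_positives which uses only the "
                          "original labeled positives",
            "model1": {m: {"mean": v[0], "ci_lower": v[1], "ci_upper": v[2]}
                       for m, v in comparison.model1_metrics.items()},
            "model2": {m: {"mean": v[0], "ci_lower": v[1], "ci_upper": v[2]}
                       for m, v in comparison.model2_metrics.items()},
        }
        cp.write_text(json.dumps(payload, indent=2) + "\n")
        record("evaluate", {"comparison": cp, "plot": pp})

    with stage("rank"):
        top = rank_genes(cs, k=min(config.top_k, len(cs.gene_cuis)))
        tp = out / "top_genes.tsv"
        with tp.open("w") as fh:
            fh.write("rank\tgene_cui\tmean_prob\n")
            for r, (cui, p) in enumerate(top, start=1):
                fh.write(f"{r}\t{cui}\t{p!r}\n")
        record("rank", {"top_genes": tp})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
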