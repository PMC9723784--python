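"""End-to-end pipeline: load -> fingerprint -> matrix -> threshold -> graph.

Composes the per-module operations into one deterministic run that writes
six artifacts (similarity matrix, edge list, GraphML graph, case report,
ranked predictions, run manifest) to an output directory.  Identical
config and inputs produce byte-identical artifacts; only the manifest
carries a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chem_core import parse_smiles
from .fingerprints import FingerprintConfig
from .knowledge import (
    builtin_fixture,
    load_compound_catalog,
    load_enzyme_map,
    load_genome_annotation,
)
from .network import (
    build_tripartite,
    classify_cases,
    export_graph,
    predict_enzymes,
    summarize_graph,
)
from .similarity import (
    SimilarityEdge,
    similarity_matrix,
    threshold_edges,
    write_matrix_tsv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("load", "fingerprint", "matrix", "threshold", "build", "classify_predict_export")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML, overridable by flags."""

    compounds: str | None = None
    enzymes: str | None = None
    annotation: str | None = None
    outdir: str = "lignolink_out"
    theta: float = 0.65
    inclusive_threshold: bool = True
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    top_k: int | None = None
    seed: int = 0
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if isinstance(self.fingerprint, dict):
            self.fingerprint = FingerprintConfig(**self.fingerprint)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _apply_top_k(edges: list[SimilarityEdge], k: int) -> list[SimilarityEdge]:
    """Keep each PDCC's k most similar LDCC (ties by LDCC id)."""
    by_pdcc: dict[str, list[SimilarityEdge]] = {}
    for e in edges:
        by_pdcc.setdefault(e.pdcc_id, []).append(e)
    kept: list[SimilarityEdge] = []
    for pid in sorted(by_pdcc):
        ranked = sorted(by_pdcc[pid], key=lambda e: (-e.similarity, e.ldcc_id))
        kept.extend(ranked[:k])
    return kept


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write the six run artifacts.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {**asdict(cfg), "fingerprint": asdict(cfg.fingerprint)},
        "stages": {},
        "inputs": {},
    }

    # load
    try:
        if cfg.compounds is None:
            compounds, enzymes, annotation = builtin_fixture()
            manifest["inputs"]["source"] = "builtin_fixture"
        else:
            for key in ("compounds", "enzymes", "annotation"):
                p = getattr(cfg, key)
                if p is None or not Path(p).exists():
                    raise PipelineError("load", f"{key} file not found: {p}")
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
            compounds = load_compound_catalog(cfg.compounds, strict=cfg.strict)
            enzymes = load_enzyme_map(cfg.enzymes, compounds, strict=cfg.strict)
            annotation = load_genome_annotation(cfg.annotation)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    manifest["stages"]["load"] = {
        "compounds": len(compounds),
        "enzymes": len(enzymes),
        "genomes": len(annotation.genome_ids),
    }

    # fingerprint + matrix
    try:
        pdcc = [(c.id, parse_smiles(c.smiles, c.id)) for c in compounds if c.partition == "PDCC"]
        ldcc = [(c.id, parse_smiles(c.smiles, c.id)) for c in compounds if c.partition == "LDCC"]
        matrix = similarity_matrix(pdcc, ldcc, cfg.fingerprint)
    except Exception as exc:
        raise PipelineError("matrix", str(exc)) from exc
    write_matrix_tsv(matrix, outdir / "similarity_matrix.tsv")
    manifest["stages"]["fingerprint"] = {"molecules": len(pdcc) + len(ldcc)}
    manifest["stages"]["matrix"] = {"shape": list(matrix.values.shape)}

    # threshold
    edges = threshold_edges(matrix, cfg.theta, cfg.inclusive_threshold)
    if cfg.top_k is not None:
        edges = _apply_top_k(edges, cfg.top_k)
    with open(outdir / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("pdcc_id\tldcc_id\tsimilarity\n")
        for e in edges:
            fh.write(f"{e.pdcc_id}\t{e.ldcc_id}\t{e.similarity:.4f}\n")
    manifest["stages"]["threshold"] = {"edges": len(edges), "theta": cfg.theta}

    # build
    try:
        names = {c.id: c.name for c in compounds}
        smiles = {c.id: c.smiles for c in compounds}
        graph = build_tripartite(
            edges, enzymes, annotation, compound_names=names, compound_smiles=smiles
        )
    except Exception as exc:
        raise PipelineError("build", str(exc)) from exc
    export_graph(graph, outdir / "graph.graphml", format="graphml")
    isolated = sorted(
        {c.id for c in compounds if c.partition == "PDCC"} - {e.pdcc_id for e in edges}
    )
    manifest["stages"]["build"] = {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "isolated_pdcc": isolated,
    }

    # classify + predict + export
    try:
        report = classify_cases(graph)
        with open(outdir / "case_report.tsv", "w", encoding="utf-8") as fh:
            fh.write("pdcc_id\tlabels\n")
            for pid in sorted(report.labels):
                fh.write(f"{pid}\t{','.join(sorted(report.labels[pid]))}\n")
        with open(outdir / "predictions.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "pdcc_id\trank\tenzyme_id\tec\tsupporting_ldcc\tsimilarity\tgene_counts\n"
            )
            for pid in sorted({e.pdcc_id for e in edges}):
                for rank, pred in enumerate(predict_enzymes(graph, pid), 1):
                    gc = ";".join(f"{g}:{n}" for g, n in pred.gene_counts)
                    ec = graph.nodes[pred.enzyme_id].get("ec", "")
                    fh.write(
                        f"{pid}\t{rank}\t{pred.enzyme_id}\t{ec}\t"
                        f"{pred.supporting_ldcc_id}\t{pred.similarity:.4f}\t{gc}\n"
                    )
    except Exception as exc:
        raise PipelineError("classify_predict_export", str(exc)) from exc
    manifest["stages"]["classify_predict_export"] = {
        "case_counts": dict(report.counts),
        "summary": summarize_graph(graph, report),
    }

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
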