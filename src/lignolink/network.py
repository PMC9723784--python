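"""Tripartite compound-compound-enzyme graph, case labels, predictions.

The graph has three node partitions — plastic-derived compounds (PDCC),
lignin-derived compounds (LDCC), and lignin-catabolizing enzymes (ENZ) —
and two edge types: *similarity* edges (PDCC-LDCC pairs at or above the
Tanimoto threshold) and *catalysis* edges (an enzyme uses an LDCC as
substrate).  No other edge is legal.  Graph semantics are unweighted; the
similarity fraction is retained as an edge attribute so predictions can be
ranked and exports stay informative.

A PDCC's predicted enzymes are those reachable through one similarity edge
and one catalysis edge: activity on the LDCC is transferred to the
structurally similar PDCC.  Each PDCC is also labelled with the observed
connection motif:

case_i
    similar to exactly one LDCC, which a single enzyme catabolizes;
case_ii
    similar to two or more LDCC whose enzymes differ;
case_iii_member
    shares some LDCC (itself served by a single enzyme) with at least one
    other PDCC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .knowledge import EnzymeRecord, GenomeAnnotation
from .similarity import SimilarityEdge

__all__ = [
    "TripartiteError",
    "CaseReport",
    "Prediction",
    "build_tripartite",
    "check_tripartite",
    "classify_cases",
    "predict_enzymes",
    "export_graph",
    "import_graphml",
    "summarize_graph",
]

PARTITION_KEY = "partition"
CASE_LABELS = ("case_i", "case_ii", "case_iii_member", "unclassified")


class TripartiteError(ValueError):
    """Raised when a graph violates the tripartite contract."""


@dataclass
class CaseReport:
    """Connection-motif labels per PDCC plus summary tallies."""

    labels: dict[str, set[str]]  # pdcc_id -> subset of CASE_LABELS
    hub_ldcc: set[str]  # LDCC with >=2 PDCC neighbors and exactly 1 enzyme
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = Counter(
                label for labels in self.labels.values() for label in labels
            )


@dataclass(frozen=True)
class Prediction:
    """One enzyme predicted active on a PDCC, with its best evidence path."""

    pdcc_id: str
    enzyme_id: str
    supporting_ldcc_id: str
    similarity: float
    gene_counts: tuple[tuple[str, int], ...] = ()

    def gene_counts_dict(self) -> dict[str, int]:
        return dict(self.gene_counts)


def build_tripartite(
    edges: list[SimilarityEdge],
    enzymes: list[EnzymeRecord],
    annotation: GenomeAnnotation | None = None,
    compound_names: dict[str, str] | None = None,
    compound_smiles: dict[str, str] | None = None,
    all_pdcc_ids: list[str] | None = None,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Assemble the tripartite graph from thresholded edges and the enzyme map.

    PDCC nodes are those with at least one surviving similarity edge (all
    catalog PDCC when ``drop_isolated`` is false, which requires
    ``all_pdcc_ids``).  Every enzyme with at least one substrate becomes an
    ENZ node connected to its LDCC substrates; enzyme nodes carry the gene
    count of every annotated genome.  Node insertion is lexicographic so
    identical inputs build identical graphs.
    """
    names = compound_names or {}
    smiles = compound_smiles or {}
    annotation = annotation or GenomeAnnotation()

    g = nx.Graph()
    pdcc_ids = sorted({e.pdcc_id for e in edges})
    if not drop_isolated:
        if all_pdcc_ids is None:
            raise TripartiteError("drop_isolated=False requires all_pdcc_ids")
        pdcc_ids = sorted(set(pdcc_ids) | set(all_pdcc_ids))
    ldcc_ids = sorted(
        {e.ldcc_id for e in edges}
        | {s for enz in enzymes for s in enz.substrates}
    )
    for pid in pdcc_ids:
        g.add_node(
            pid,
            partition="PDCC",
            name=names.get(pid, pid),
            smiles=smiles.get(pid, ""),
        )
    for lid in ldcc_ids:
        g.add_node(
            lid,
            partition="LDCC",
            name=names.get(lid, lid),
            smiles=smiles.get(lid, ""),
        )
    for enz in sorted(enzymes, key=lambda e: e.id):
        g.add_node(
            enz.id,
            partition="ENZ",
            name=enz.name,
            ec=enz.ec or "",
            ko=",".join(enz.ko),
            gene_counts=dict(annotation.for_enzyme(enz.id)),
        )
        for sub in enz.substrates:
            if sub not in g or g.nodes[sub][PARTITION_KEY] != "LDCC":
                raise TripartiteError(
                    f"enzyme {enz.id!r} substrate {sub!r} is not an LDCC node"
                )
            g.add_edge(enz.id, sub, type="catalysis")
    for e in edges:
        if e.pdcc_id not in g:
            raise TripartiteError(f"similarity edge references unknown PDCC {e.pdcc_id!r}")
        g.add_edge(e.pdcc_id, e.ldcc_id, type="similarity", weight=float(e.similarity))

    unknown = set().union(*annotation.counts.values()) - {e.id for e in enzymes} if annotation.counts else set()
    if unknown:
        import logging

        logging.getLogger(__name__).warning(
            "annotation references enzyme id(s) absent from the enzyme map: %s",
            sorted(unknown),
        )
    check_tripartite(g)
    return g


_ALLOWED_EDGE = {
    ("PDCC", "LDCC"): "similarity",
    ("LDCC", "PDCC"): "similarity",
    ("LDCC", "ENZ"): "catalysis",
    ("ENZ", "LDCC"): "catalysis",
}


def check_tripartite(g: nx.Graph) -> None:
    """Raise :class:`TripartiteError` on any forbidden edge or self-loop."""
    for u, v, data in g.edges(data=True):
        if u == v:
            raise TripartiteError(f"self-loop on {u!r}")
        pu = g.nodes[u].get(PARTITION_KEY)
        pv = g.nodes[v].get(PARTITION_KEY)
        expected = _ALLOWED_EDGE.get((pu, pv))
        if expected is None:
            raise TripartiteError(f"forbidden edge {u!r}({pu}) - {v!r}({pv})")
        if data.get("type") != expected:
            raise TripartiteError(
                f"edge {u!r}-{v!r} has type {data.get('type')!r}, expected {expected!r}"
            )
        if expected == "similarity" and "weight" in data and not 0 <= data["weight"] <= 1:
            raise TripartiteError(f"similarity weight out of range on {u!r}-{v!r}")


def _nodes_of(g: nx.Graph, partition: str) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get(PARTITION_KEY) == partition)


def _enzymes_of_ldcc(g: nx.Graph, lid: str) -> set[str]:
    return {
        n for n in g.neighbors(lid) if g.nodes[n][PARTITION_KEY] == "ENZ"
    }


def classify_cases(g: nx.Graph) -> CaseReport:
    """Label every PDCC with its connection motif(s).

    A pure function of graph topology: for PDCC ``p`` with LDCC
    neighborhood ``L(p)`` and per-LDCC enzyme sets ``E(l)`` —
    case_i iff ``|L(p)| == 1`` and that LDCC has exactly one enzyme;
    case_ii iff ``|L(p)| >= 2`` and the union of enzymes is >= 2;
    case_iii_member iff some neighbor LDCC has >= 2 PDCC neighbors and
    exactly one enzyme.  A PDCC matching nothing is ``unclassified``.
    """
    check_tripartite(g)
    labels: dict[str, set[str]] = {}
    hubs: set[str] = set()
    for lid in _nodes_of(g, "LDCC"):
        pdcc_nb = [n for n in g.neighbors(lid) if g.nodes[n][PARTITION_KEY] == "PDCC"]
        if len(pdcc_nb) >= 2 and len(_enzymes_of_ldcc(g, lid)) == 1:
            hubs.add(lid)
    for pid in _nodes_of(g, "PDCC"):
        lp = [n for n in g.neighbors(pid) if g.nodes[n][PARTITION_KEY] == "LDCC"]
        tags: set[str] = set()
        if len(lp) == 1 and len(_enzymes_of_ldcc(g, lp[0])) == 1:
            tags.add("case_i")
        if len(lp) >= 2:
            union = set().union(*(_enzymes_of_ldcc(g, l) for l in lp))
            if len(union) >= 2:
                tags.add("case_ii")
        if any(l in hubs for l in lp):
            tags.add("case_iii_member")
        if not tags:
            tags.add("unclassified")
        labels[pid] = tags
    return CaseReport(labels=labels, hub_ldcc=hubs)


def predict_enzymes(g: nx.Graph, pdcc_id: str) -> list[Prediction]:
    """Rank the enzymes reachable from one PDCC through similarity edges.

    One prediction per enzyme, supported by its highest-similarity LDCC;
    ranked by similarity descending with enzyme-id lexicographic
    tie-breaks.  Gene counts come from the enzyme node attributes.
    """
    if pdcc_id not in g:
        raise KeyError(f"unknown node {pdcc_id!r}")
    if g.nodes[pdcc_id][PARTITION_KEY] != "PDCC":
        raise ValueError(f"node {pdcc_id!r} is not a PDCC")
    best: dict[str, tuple[float, str]] = {}
    for lid in g.neighbors(pdcc_id):
        if g.nodes[lid][PARTITION_KEY] != "LDCC":
            continue
        sim = float(g.edges[pdcc_id, lid].get("weight", 1.0))
        for eid in _enzymes_of_ldcc(g, lid):
            # keep the best supporting LDCC per enzyme; ties keep the
            # lexicographically smaller LDCC id for determinism
            cur = best.get(eid)
            if cur is None or sim > cur[0] or (sim == cur[0] and lid < cur[1]):
                best[eid] = (sim, lid)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [
        Prediction(
            pdcc_id=pdcc_id,
            enzyme_id=eid,
            supporting_ldcc_id=lid,
            similarity=sim,
            gene_counts=tuple(sorted(g.nodes[eid].get("gene_counts", {}).items())),
        )
        for eid, (sim, lid) in ranked
    ]


# --------------------------------------------------------------------------
# export / import


def export_graph(g: nx.Graph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML or as a nodes+edges TSV pair.

    GraphML serializes per-genome gene counts as ``genome:count;...`` (a
    flat string, since GraphML attributes are scalar); re-import restores
    the dictionary.  ``edge_tsv`` writes ``<path>.nodes.tsv`` and
    ``<path>.edges.tsv``.
    """
    if format == "graphml":
        h = g.copy()
        for n, d in h.nodes(data=True):
            gc = d.pop("gene_counts", None)
            if gc is not None:
                d["gene_counts"] = ";".join(f"{k}:{v}" for k, v in sorted(gc.items()))
        nx.write_graphml(h, path)
    elif format == "edge_tsv":
        base = str(path)
        with open(base + ".nodes.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\tpartition\tname\tsmiles\tec\tko\tgene_counts\n")
            for n in sorted(g.nodes):
                d = g.nodes[n]
                gc = ";".join(f"{k}:{v}" for k, v in sorted(d.get("gene_counts", {}).items()))
                fh.write(
                    f"{n}\t{d.get('partition','')}\t{d.get('name','')}\t"
                    f"{d.get('smiles','')}\t{d.get('ec','')}\t{d.get('ko','')}\t{gc}\n"
                )
        with open(base + ".edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("u\tv\ttype\tweight\n")
            for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
                d = g.edges[u, v]
                w = f"{d['weight']:.4f}" if "weight" in d else ""
                fh.write(f"{u}\t{v}\t{d.get('type','')}\t{w}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graphml(path) -> nx.Graph:
    """Read a GraphML export back into an attributed tripartite graph."""
    g = nx.read_graphml(path)
    h = nx.Graph()
    for n, d in g.nodes(data=True):
        d = dict(d)
        gc = d.pop("gene_counts", "")
        if gc:
            d["gene_counts"] = {
                k: int(v) for k, v in (item.split(":") for item in gc.split(";"))
            }
        elif "gene_counts" in g.nodes[n]:
            d["gene_counts"] = {}
        h.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, **d)
    check_tripartite(h)
    return h


def summarize_graph(g: nx.Graph, report: CaseReport | None = None) -> str:
    """Plain-text summary: node/edge counts per partition and case tallies."""
    lines = []
    for part in ("PDCC", "LDCC", "ENZ"):
        lines.append(f"{part} nodes: {len(_nodes_of(g, part))}")
    sim = sum(1 for *_, d in g.edges(data=True) if d.get("type") == "similarity")
    cat = g.number_of_edges() - sim
    lines.append(f"similarity edges: {sim}")
    lines.append(f"catalysis edges: {cat}")
    if report is not None:
        for label in CASE_LABELS:
            lines.append(f"{label}: {report.counts.get(label, 0)}")
    return "\n".join(lines)
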