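"""Interaction network construction and hub-pair shortlisting.

The combined network mixes STRING-style scored protein-protein edges
(kept above a combined-score threshold, 0.4 "medium confidence" by
default) with unweighted mRNA-lncRNA proximity edges.  Hub ranking uses
degree centrality, degree / (n - 1).

Shortlisting applies the screening funnel to pair-bearing mRNAs:
membership in a target pathway (insulin resistance in the motivating
study), functional annotation in both carbohydrate- and lipid-metabolism
categories (or, as the alternative reading, involvement in more than two
pathways), and a database-annotated paired lncRNA.  Each filter only
shrinks the candidate set and is logged with before/after counts;
survivors are ranked by degree centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

from .proximity import HMLPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredEdge:
    """A scored interaction edge; scores live on the [0, 1] scale."""

    node_a: str
    node_b: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"edge ({self.node_a}, {self.node_b}): score {self.score} "
                f"not in [0, 1]"
            )


@dataclass(frozen=True)
class HubCandidate:
    """A pair-bearing mRNA with its centrality and annotation evidence."""

    mrna_id: str
    lncrna_ids: tuple[str, ...]
    degree: int
    degree_centrality: float
    categories: frozenset[str] = frozenset()
    in_target_pathway: bool = False
    n_pathways: int = 0
    annotated_lncrna: bool = False


class FunnelStage(NamedTuple):
    """One filtering stage's audit record."""

    stage: str
    count_in: int
    count_out: int
    parameters: dict


def read_string_edges(path: str | Path) -> list[ScoredEdge]:
    """Read a STRING-style TSV (protein1, protein2, combined_score).

    Native STRING combined scores run 0-1000 and are rescaled to [0, 1];
    inputs already on [0, 1] are passed through.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns[:3])
    scores = df[cols[2]].astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    return [
        ScoredEdge(node_a=str(a), node_b=str(b), score=float(s))
        for a, b, s in zip(df[cols[0]], df[cols[1]], scores)
    ]


def build_network(
    ppi_edges: Iterable[ScoredEdge],
    pairs: Iterable[HMLPair],
    score_threshold: float = 0.4,
) -> nx.Graph:
    """Simple undirected graph of thresholded PPI edges plus HML pair edges.

    Edge attribute ``kind`` is 'ppi' or 'hml'; an edge present as both keeps
    'ppi' with ``also_hml=True``.  Self-loops are dropped with a warning.
    """
    if not (0.0 <= score_threshold <= 1.0):
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    g = nx.Graph()
    n_loops = 0
    for e in ppi_edges:
        if e.node_a == e.node_b:
            n_loops += 1
            continue
        if e.score < score_threshold:
            continue
        if g.has_edge(e.node_a, e.node_b):
            # keep the best score when duplicates appear
            g[e.node_a][e.node_b]["score"] = max(g[e.node_a][e.node_b]["score"], e.score)
        else:
            g.add_edge(e.node_a, e.node_b, kind="ppi", score=e.score)
    for p in pairs:
        if p.mrna_id == p.lncrna_id:
            n_loops += 1
            continue
        if g.has_edge(p.mrna_id, p.lncrna_id):
            g[p.mrna_id][p.lncrna_id]["also_hml"] = True
        else:
            g.add_edge(p.mrna_id, p.lncrna_id, kind="hml")
    if n_loops:
        logger.warning("build_network: dropped %d self-loop edges", n_loops)
    return g


def degree_centrality(graph: nx.Graph) -> dict[str, float]:
    """Degree centrality, degree / (n - 1), for every node."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"degree centrality needs >= 2 nodes, got {n}")
    return {node: deg / (n - 1) for node, deg in graph.degree()}


def select_hub_pairs(
    graph: nx.Graph,
    enrichment_tags: Mapping[str, frozenset[str]],
    pairs: Iterable[HMLPair],
    annotations: Mapping[str, bool],
    target_pathway: Iterable[str],
    top_k: int = 10,
    pathway_counts: Mapping[str, int] | None = None,
    dual_category_rule: str = "categories",
) -> tuple[list[HubCandidate], list[FunnelStage]]:
    """Apply the hub-pair shortlist funnel and rank survivors.

    Candidates are mRNAs with at least one HML pair.  Sequential filters:

    1. membership in ``target_pathway``;
    2. dual metabolic annotation — by default both carbohydrate- and
       lipid-metabolism category flags (``dual_category_rule='categories'``),
       or involvement in more than two pathways
       (``dual_category_rule='n_pathways'``);
    3. at least one paired lncRNA carrying a database annotation flag.

    Survivors are ranked by degree centrality descending, ties by
    n_pathways descending then mrna_id ascending, truncated to ``top_k``.
    Returns the shortlist and the funnel audit trail; an empty shortlist is
    a valid outcome.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if dual_category_rule not in ("categories", "n_pathways"):
        raise ValueError(f"unknown dual_category_rule {dual_category_rule!r}")
    pairs = list(pairs)
    target_pathway = set(target_pathway)
    pathway_counts = dict(pathway_counts or {})
    lnc_by_mrna: dict[str, list[str]] = {}
    for p in pairs:
        lnc_by_mrna.setdefault(p.mrna_id, []).append(p.lncrna_id)

    centrality = degree_centrality(graph) if graph.number_of_nodes() >= 2 else {}
    degrees = dict(graph.degree())

    def make(mrna_id: str) -> HubCandidate:
        return HubCandidate(
            mrna_id=mrna_id,
            lncrna_ids=tuple(sorted(set(lnc_by_mrna[mrna_id]))),
            degree=int(degrees.get(mrna_id, 0)),
            degree_centrality=float(centrality.get(mrna_id, 0.0)),
            categories=frozenset(enrichment_tags.get(mrna_id, frozenset())),
            in_target_pathway=mrna_id in target_pathway,
            n_pathways=int(pathway_counts.get(mrna_id, 0)),
            annotated_lncrna=any(
                annotations.get(l, False) for l in lnc_by_mrna[mrna_id]
            ),
        )

    candidates = [make(m) for m in sorted(lnc_by_mrna)]
    funnel: list[FunnelStage] = []

    def apply(stage: str, predicate, params: dict) -> None:
        nonlocal candidates
        before = len(candidates)
        candidates = [c for c in candidates if predicate(c)]
        funnel.append(FunnelStage(stage, before, len(candidates), params))
        logger.info("select_hub_pairs: %s %d -> %d", stage, before, len(candidates))

    apply(
        "target_pathway",
        lambda c: c.in_target_pathway,
        {"pathway_size": len(target_pathway)},
    )
    if dual_category_rule == "categories":
        required = {"carbohydrate_metabolism", "lipid_metabolism"}
        apply(
            "dual_category",
            lambda c: required <= c.categories,
            {"rule": "categories"},
        )
    else:
        apply(
            "dual_category",
            lambda c: c.n_pathways > 2,
            {"rule": "n_pathways > 2"},
        )
    apply("annotated_lncrna", lambda c: c.annotated_lncrna, {})

    candidates.sort(
        key=lambda c: (-c.degree_centrality, -c.n_pathways, c.mrna_id)
    )
    before = len(candidates)
    candidates = candidates[:top_k]
    funnel.append(FunnelStage("top_k", before, len(candidates), {"top_k": top_k}))
    return candidates, funnel


def write_graph_tsv(graph: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Edge-list and node-attribute TSVs for visualization tools."""
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tkind\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            score = data.get("score", "")
            fh.write(f"{a}\t{b}\t{data.get('kind', '')}\t{score}\n")
    centrality = (
        degree_centrality(graph) if graph.number_of_nodes() >= 2 else {}
    )
    with open(nodes_path, "w") as fh:
        fh.write("node\tdegree\tdegree_centrality\n")
        for node in sorted(graph.nodes):
            fh.write(
                f"{node}\t{graph.degree(node)}\t{centrality.get(node, 0.0):.6g}\n"
            )
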