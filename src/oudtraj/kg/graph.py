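"""Therapy-graph assembly: disease → genes (direct + pathway-bridged) → drugs.

The graph is a typed, weighted :class:`networkx.DiGraph` with one disease
node (``OUD``), gene nodes, pathway nodes (bridging support only) and drug
nodes.  Edge types:

``HAS_GENE``          OUD → seed gene, weight from the evidence score (capped);
``HAS_GENE_BRIDGED``  OUD → pathway co-member, weight from the γ-penalized
                      pathway bonus (max over bridging pathways, all of which
                      are recorded as provenance);
``IN_PATHWAY``        gene → pathway (support/provenance only);
``TARGETED_BY``       gene → drug, weight from potency + indicator score.

For ranking, the graph is projected onto {OUD} ∪ genes ∪ drugs and each
node's outgoing weights are normalized to a row-stochastic transition
structure; out-degree-zero nodes are flagged dangling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from .weights import (
    DrugTargetEvidence,
    GeneEvidence,
    KGParams,
    compute_direct_gene_weight,
    compute_gene_drug_weight,
)

logger = logging.getLogger(__name__)

OUD_NODE = "OUD"


def build_graph(
    gene_evidence: Sequence[GeneEvidence],
    pathways: Sequence[tuple[str, str, Sequence[str]]],
    drug_targets: Sequence[DrugTargetEvidence],
    params: KGParams | None = None,
) -> nx.DiGraph:
    """Assemble the full therapy graph from the three evidence tables."""
    params = params or KGParams()
    g = nx.DiGraph()
    g.add_node(OUD_NODE, type="OUD")

    direct_weights: dict[str, float] = {}
    for ev in gene_evidence:
        a, w = compute_direct_gene_weight(ev, params)
        g.add_node(ev.gene, type="gene", seed=True)
        g.add_edge(
            OUD_NODE,
            ev.gene,
            type="HAS_GENE",
            weight=w,
            a_score=a,
            branch=_branch_name(ev),
        )
        direct_weights[ev.gene] = w

    for name, _desc, members in pathways:
        g.add_node(f"pathway:{name}", type="pathway", name=name)
        for m in members:
            if m not in g:
                g.add_node(m, type="gene", seed=False)
            g.add_edge(m, f"pathway:{name}", type="IN_PATHWAY", weight=1.0)

    bridge_pathway_genes(g, pathways, direct_weights, params)

    for ev in drug_targets:
        w = compute_gene_drug_weight(ev, params)
        if ev.gene not in g:
            g.add_node(ev.gene, type="gene", seed=False)
        if ev.drug_id not in g:
            g.add_node(
                ev.drug_id, type="drug", name=ev.drug_name, approved=0, bbb=0
            )
        node = g.nodes[ev.drug_id]
        node["approved"] = max(node["approved"], ev.app)
        node["bbb"] = max(node["bbb"], ev.bbb)
        prev = g.get_edge_data(ev.gene, ev.drug_id)
        if prev is None or prev["weight"] < w:
            g.add_edge(ev.gene, ev.drug_id, type="TARGETED_BY", weight=w)
    return g


def _branch_name(ev: GeneEvidence) -> str:
    if ev.r_rep is not None:
        return "replication"
    if ev.flag_mvp:
        return "mvp"
    if ev.flag_oud_only:
        return "oud_only"
    if ev.flag_mtag:
        return "mtag"
    if ev.posterior is not None:
        return "posterior"
    if ev.p_rank is not None:
        return "p_rank"
    return "none"


def bridge_pathway_genes(
    graph: nx.DiGraph,
    pathways: Sequence[tuple[str, str, Sequence[str]]],
    direct_weights: dict[str, float],
    params: KGParams,
) -> nx.DiGraph:
    """Grant γ-penalized disease edges to pathway co-members of seed genes.

    A pathway with at least ``m_min`` seed members gives each non-seed member
    the bonus ``gamma * (sum of the seed members' direct weights) / |M_p|``.
    A gene bridged by several pathways keeps the maximum bonus, with every
    supporting pathway recorded; at most ``b_max`` genes (highest bonus
    first, ties by gene id) receive edges.
    """
    seed = set(direct_weights)
    best: dict[str, float] = {}
    support: dict[str, list[str]] = {}
    for name, _desc, members in pathways:
        members = list(dict.fromkeys(members))
        if not members:
            logger.warning("pathway %s has no members; skipped", name)
            continue
        in_p = [m for m in members if m in seed]
        if len(in_p) < params.m_min:
            continue
        bonus = params.gamma * sum(direct_weights[m] for m in in_p) / len(members)
        for h in members:
            if h in seed:
                continue
            support.setdefault(h, []).append(name)
            if bonus > best.get(h, -np.inf):
                best[h] = bonus
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[: params.b_max]
    for gene, bonus in ranked:
        if gene not in graph:
            graph.add_node(gene, type="gene", seed=False)
        graph.add_edge(
            OUD_NODE,
            gene,
            type="HAS_GENE_BRIDGED",
            weight=max(params.eps, bonus),
            pathways=sorted(support[gene]),
        )
    return graph


@dataclass
class Projection:
    """Row-stochastic transition structure over {OUD} ∪ genes ∪ drugs."""

    nodes: list[str]
    index: dict[str, int]
    P: sparse.csr_matrix
    dangling: np.ndarray  # True where the node has no outgoing edges
    drugs: list[str]


def project_and_normalize(graph: nx.DiGraph) -> Projection:
    """Drop pathway nodes and row-normalize the remaining outgoing weights.

    Pathway nodes only exist to justify bridged edges (their effect is folded
    into ``HAS_GENE_BRIDGED`` weights), so the walk runs on OUD, gene and
    drug nodes only.  Every node with outgoing edges gets weights summing to
    one; out-degree-zero nodes (typically drugs) are flagged dangling.
    """
    genes = sorted(n for n, a in graph.nodes(data=True) if a["type"] == "gene")
    drugs = sorted(n for n, a in graph.nodes(data=True) if a["type"] == "drug")
    nodes = [OUD_NODE] + genes + drugs
    index = {n: i for i, n in enumerate(nodes)}
    keep = set(nodes)

    rows, cols, vals = [], [], []
    out_sum = np.zeros(len(nodes))
    for u, v, attrs in graph.edges(data=True):
        if u not in keep or v not in keep:
            continue
        w = float(attrs["weight"])
        if w <= 0:
            raise ValueError(f"non-positive edge weight on {u}->{v}")
        rows.append(index[u])
        cols.append(index[v])
        vals.append(w)
        out_sum[index[u]] += w
    dangling = out_sum == 0
    norm = np.where(dangling, 1.0, out_sum)
    vals = [w / norm[i] for i, w in zip(rows, vals)]
    P = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes))
    )
    return Projection(nodes=nodes, index=index, P=P, dangling=dangling, drugs=drugs)
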