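"""Drug ranking, salt-form alias merging and the ranked-table writer."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import OUD_NODE, Projection

#: salt / ester suffix tokens stripped during alias normalization
SALT_SUFFIXES = {
    "hydrochloride",
    "dihydrochloride",
    "hydrobromide",
    "sulfate",
    "sulphate",
    "tartrate",
    "bitartrate",
    "maleate",
    "mesylate",
    "besylate",
    "tosylate",
    "citrate",
    "phosphate",
    "acetate",
    "fumarate",
    "succinate",
    "lactate",
    "nitrate",
    "bromide",
    "chloride",
    "sodium",
    "potassium",
    "calcium",
    "decanoate",
    "palmitate",
    "hcl",
}


def normalize_alias(name: str) -> str:
    """Lowercase and strip trailing salt/ester tokens from a drug name."""
    tokens = name.strip().lower().split()
    while len(tokens) > 1 and tokens[-1] in SALT_SUFFIXES:
        tokens.pop()
    return " ".join(tokens)


@dataclass
class RankedDrugRow:
    """One line of the ranked-drug output."""

    rank: int
    drug_id: str
    drug_name: str
    score: float
    supporting_genes: list[str] = field(default_factory=list)
    gene_labels: list[str] = field(default_factory=list)
    supporting_pathways: list[str] = field(default_factory=list)
    approved: int = 0
    bbb: int = 0


def _gene_label(graph: nx.DiGraph, gene: str) -> str:
    edge = graph.get_edge_data(OUD_NODE, gene)
    if edge is None:
        return "non-seed"
    return "direct" if edge["type"] == "HAS_GENE" else "bridged"


def rank_drugs(
    graph: nx.DiGraph,
    proj: Projection,
    r: np.ndarray,
    alias_mode: str = "keep",
    why_top: int = 3,
    score_offsets: dict[str, float] | None = None,
) -> list[RankedDrugRow]:
    """Sort drugs by score with provenance (the "why" columns).

    Scores are ``r(d)`` plus an optional additive per-drug offset.  Each row
    carries up to ``why_top`` supporting genes ordered by their walk
    contribution ``r(g) * P(g->d)``, labelled direct / bridged / non-seed,
    with the bridging pathways of bridged genes.  ``alias_mode="merge"``
    collapses salt forms of one ingredient onto the highest-scoring entry,
    taking the union of supporting genes.
    """
    if alias_mode not in ("keep", "merge"):
        raise ValueError("alias_mode must be 'keep' or 'merge'")
    offsets = score_offsets or {}

    entries = []
    for d in proj.drugs:
        score = float(r[proj.index[d]]) + float(offsets.get(d, 0.0))
        support = []
        for g in graph.predecessors(d):
            edge = graph.get_edge_data(g, d)
            if edge["type"] != "TARGETED_BY":
                continue
            contrib = float(r[proj.index[g]]) * proj.P[proj.index[g], proj.index[d]]
            support.append((contrib, g))
        support.sort(key=lambda t: (-t[0], t[1]))
        genes = [g for _, g in support]
        labels = [_gene_label(graph, g) for g in genes]
        pathways: list[str] = []
        for g, lab in zip(genes, labels):
            if lab == "bridged":
                for p in graph.get_edge_data(OUD_NODE, g).get("pathways", []):
                    if p not in pathways:
                        pathways.append(p)
        entries.append(
            {
                "drug_id": d,
                "drug_name": graph.nodes[d].get("name", d),
                "score": score,
                "genes": genes,
                "labels": labels,
                "pathways": pathways,
                "approved": int(graph.nodes[d].get("approved", 0)),
                "bbb": int(graph.nodes[d].get("bbb", 0)),
            }
        )

    if alias_mode == "merge":
        merged: dict[str, dict] = {}
        for e in sorted(entries, key=lambda e: (-e["score"], e["drug_id"])):
            key = normalize_alias(e["drug_name"])
            if key not in merged:
                merged[key] = e
            else:
                keeper = merged[key]
                for g, lab in zip(e["genes"], e["labels"]):
                    if g not in keeper["genes"]:
                        keeper["genes"].append(g)
                        keeper["labels"].append(lab)
                for p in e["pathways"]:
                    if p not in keeper["pathways"]:
                        keeper["pathways"].append(p)
                keeper["approved"] = max(keeper["approved"], e["approved"])
                keeper["bbb"] = max(keeper["bbb"], e["bbb"])
        entries = list(merged.values())

    entries.sort(key=lambda e: (-e["score"], e["drug_id"]))
    return [
        RankedDrugRow(
            rank=i + 1,
            drug_id=e["drug_id"],
            drug_name=e["drug_name"],
            score=e["score"],
            supporting_genes=e["genes"][:why_top],
            gene_labels=e["labels"][:why_top],
            supporting_pathways=e["pathways"],
            approved=e["approved"],
            bbb=e["bbb"],
        )
        for i, e in enumerate(entries)
    ]


RANKED_HEADER = [
    "rank",
    "drug_id",
    "drug_name",
    "score",
    "supporting_genes",
    "gene_labels",
    "supporting_pathways",
    "approved",
    "bbb",
]


def write_ranked_tsv(rows: list[RankedDrugRow], out_path) -> None:
    """Write the ranked table; scores carry 6 significant digits."""
    with open(out_path, "w", newline="\n") as fh:
        fh.write("\t".join(RANKED_HEADER) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        str(row.rank),
                        row.drug_id,
                        row.drug_name,
                        format(row.score, ".6g"),
                        ",".join(row.supporting_genes),
                        ",".join(row.gene_labels),
                        ",".join(row.supporting_pathways),
                        str(row.approved),
                        str(row.bbb),
                    ]
                )
                + "\n"
            )
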