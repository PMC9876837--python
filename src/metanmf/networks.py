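"""Interaction subnetworks, centralities, hub ranking and bipartite reports.

Given a STRING-like confidence-scored edge list and a list of seed genes
(typically DEGs or metagene members), a first-order subnetwork is the seeds
plus all their direct interactors with every edge among included nodes;
the zero-order variant is the induced subgraph on seeds only.  Hubs are
ranked by degree (ties by betweenness, then symbol).  Betweenness is
Brandes' algorithm on the unweighted graph, unnormalized pair counts with
endpoints excluded, so magnitudes are comparable to published hub tables.
Edge scores act as a confidence filter only, never as distances.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

HUB_COLUMNS = ["gene", "degree", "betweenness"]


def build_subnetwork(seeds, edges: pd.DataFrame, min_score: float = 0.9,
                     order: str = "first") -> nx.Graph:
    """Construct a seed-gene subnetwork from a scored edge list.

    ``order='first'``: seeds plus direct interactors, with all edges among
    included nodes (non-seed interactors carry ``is_seed=False``);
    ``order='zero'``: induced subgraph on seeds only.  Edges with score
    below ``min_score`` are dropped first.  Seeds present in the (filtered)
    interactome but left without edges are retained as isolated nodes,
    flagged ``isolated=True``.
    """
    if order not in ("first", "zero"):
        raise ValueError(f"unknown order {order!r}")
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("empty seed list")
    all_nodes = set(edges["node_a"]) | set(edges["node_b"])
    seed_set = set(seeds)
    known = seed_set & all_nodes
    if not known:
        raise ValueError("no seed gene present in the interactome")
    kept = edges[edges["score"] >= min_score]
    interactome = nx.Graph()
    interactome.add_weighted_edges_from(
        kept[["node_a", "node_b", "score"]].itertuples(index=False),
        weight="score")
    # seeds known to the interactome but stripped of edges by the score
    # filter stay in play as isolated, flagged nodes
    nodes = set(known)
    if order == "first":
        for s in known:
            if s in interactome:
                nodes.update(interactome.neighbors(s))
    g = interactome.subgraph(nodes).copy()
    for s in known - set(g.nodes):
        g.add_node(s)
    nx.set_node_attributes(g, {v: v in seed_set for v in g.nodes}, "is_seed")
    nx.set_node_attributes(g, {v: g.degree(v) == 0 for v in g.nodes},
                           "isolated")
    absent = seed_set - all_nodes
    if absent:
        log.info("%d seeds absent from the interactome", len(absent))
    log.info("subnetwork (%s-order): %d nodes, %d edges", order,
             g.number_of_nodes(), g.number_of_edges())
    return g


def centralities(g: nx.Graph) -> nx.Graph:
    """Annotate every node with ``degree`` and unnormalized ``betweenness``
    (Brandes, unweighted shortest paths, endpoints excluded)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    bc = nx.betweenness_centrality(g, normalized=False, endpoints=False)
    nx.set_node_attributes(g, bc, "betweenness")
    return g


def rank_hubs(g: nx.Graph, k: int = 10,
              deg_table: pd.DataFrame | None = None,
              metagene_of: dict | None = None) -> pd.DataFrame:
    """Top-k nodes by degree, ties by betweenness then symbol.

    When a DEG table is supplied its ``mean_expr`` and ``logFC`` columns
    are joined in (as ``expression`` / ``logFC``); ``metagene_of`` adds an
    optional gene→metagene column.
    """
    centralities(g)  # idempotent; guarantees attributes exist
    if k > g.number_of_nodes():
        log.warning("k=%d exceeds node count %d: returning all nodes", k,
                    g.number_of_nodes())
        k = g.number_of_nodes()
    ranked = sorted(
        g.nodes,
        key=lambda v: (-g.nodes[v]["degree"], -g.nodes[v]["betweenness"], v),
    )[:k]
    table = pd.DataFrame({
        "gene": ranked,
        "degree": [g.nodes[v]["degree"] for v in ranked],
        "betweenness": [g.nodes[v]["betweenness"] for v in ranked],
    })
    if deg_table is not None:
        extra = deg_table.set_index("gene")[["mean_expr", "logFC"]].rename(
            columns={"mean_expr": "expression"})
        table = table.join(extra, on="gene")
    if metagene_of is not None:
        table["metagene"] = table["gene"].map(metagene_of)
    return table


def bipartite_report(genes, assoc: pd.DataFrame, min_score: float = 0.0,
                     min_shared: int = 2,
                     rank_entities: bool = False) -> pd.DataFrame:
    """Report entities (diseases, TFs, ...) associated with ≥ ``min_shared``
    query genes at association score ≥ ``min_score``.

    With ``rank_entities=True`` the entities are additionally ranked by
    their degree then betweenness on the gene-entity bipartite graph
    (the TF-interaction convention); otherwise rows are ordered by the
    number of shared genes descending.
    """
    genes = set(genes)
    sub = assoc[(assoc["score"] >= min_score) & assoc["gene"].isin(genes)]
    rows = []
    for entity, grp in sub.groupby("entity"):
        shared = sorted(grp["gene"].unique())
        if len(shared) >= min_shared:
            rows.append({"entity": entity, "n_shared": len(shared),
                         "genes": ",".join(shared)})
    if not rows:
        return pd.DataFrame(columns=["entity", "n_shared", "genes"])
    df = pd.DataFrame(rows)

    if rank_entities:
        b = nx.Graph()
        for _, row in sub.iterrows():
            b.add_edge(("gene", row["gene"]), ("entity", row["entity"]))
        bc = nx.betweenness_centrality(b, normalized=False, endpoints=False)
        df["degree"] = [b.degree(("entity", e)) for e in df["entity"]]
        df["betweenness"] = [bc[("entity", e)] for e in df["entity"]]
        df = df.sort_values(["degree", "betweenness", "entity"],
                            ascending=[False, False, True], kind="mergesort")
    else:
        df = df.sort_values(["n_shared", "entity"], ascending=[False, True],
                            kind="mergesort")
    return df.reset_index(drop=True)
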