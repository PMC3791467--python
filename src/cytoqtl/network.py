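"""Epistatic interaction network from term prevalence.

Nodes are the model loci (hotspot markers plus the cytoplasm), sized by
the fraction of metabolites their main effect touches; edges join locus
pairs whose interaction is FDR-significant for at least a minimum
fraction of the metabolites (default 10%, a conservative prevalence
filter on top of the FDR).  Triangles through the cytoplasm node — two
nuclear loci that interact with each other and each with the cytoplasm —
define the three-way interaction terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .data import CYTOPLASM


def interaction_prevalence(
    term_table: pd.DataFrame, n_metabolites: int | None = None
) -> pd.Series:
    """Fraction of metabolites with a significant (q < FDR) flag per term.

    Requires the ``significant`` column from :func:`cytoqtl.models.apply_fdr`.
    """
    if "significant" not in term_table.columns:
        raise ValueError("term table has no FDR flags; run apply_fdr first")
    if n_metabolites is None:
        n_metabolites = term_table["metabolite"].nunique()
    counts = (
        term_table[term_table["significant"].fillna(False)]
        .groupby("term", sort=False)["metabolite"]
        .nunique()
    )
    all_terms = term_table["term"].unique()
    return counts.reindex(all_terms, fill_value=0) / n_metabolites


def build_network(
    prevalences: pd.Series,
    min_fraction: float = 0.10,
    node_order: list[str] | None = None,
) -> tuple[nx.Graph, dict]:
    """Graph of interacting loci plus degree statistics.

    ``prevalences`` is indexed by term name: plain locus names become
    node attributes, ``a:b`` pair terms become candidate edges retained
    when prevalence >= ``min_fraction``.  Degree statistics (mean ± SE)
    are computed over connected nodes (degree >= 1).
    """
    graph = nx.Graph()
    mains = {t: v for t, v in prevalences.items() if ":" not in t}
    pairs = {t: v for t, v in prevalences.items() if t.count(":") == 1}
    order = node_order
    if order is None:
        # cytoplasm first, then declaration order
        order = sorted(mains, key=lambda t: (t != CYTOPLASM, list(mains).index(t)))
    for node in order:
        graph.add_node(node, fraction=float(mains.get(node, 0.0)))
    for term, v in pairs.items():
        a, b = term.split(":")
        for node in (a, b):
            if node not in graph:
                graph.add_node(node, fraction=float(mains.get(node, 0.0)))
        if v >= min_fraction:
            graph.add_edge(a, b, fraction=float(v))
    degrees = np.array([d for _, d in graph.degree() if d >= 1], dtype=float)
    if degrees.size:
        mean = float(degrees.mean())
        se = (
            float(degrees.std(ddof=1) / np.sqrt(degrees.size))
            if degrees.size > 1
            else np.nan
        )
    else:
        mean = se = np.nan
    stats = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_connected_nodes": int(degrees.size),
        "mean_degree": mean,
        "se_degree": se,
    }
    return graph, stats


def find_cytonuclear_triangles(
    graph: nx.Graph, cyto: str = CYTOPLASM
) -> list[tuple[str, str, str]]:
    """Nuclear pairs interacting with each other and with the cytoplasm.

    Returns deterministic, sorted (cytoplasm, locusA, locusB) triples;
    these are the candidate three-way model terms.
    """
    if cyto not in graph:
        return []
    neighbors = sorted(graph.neighbors(cyto))
    triples = []
    for i, a in enumerate(neighbors):
        for b in neighbors[i + 1 :]:
            if graph.has_edge(a, b):
                triples.append((cyto, a, b))
    return triples


def export_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"source": a, "target": b, "fraction": d.get("fraction", np.nan)}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "fraction"]).to_csv(
        path, index=False
    )


def export_sif(graph: nx.Graph, path) -> None:
    """Simple interaction format (node, relation, node) for graph viewers."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in graph.edges():
            fh.write(f"{a}\tepistasis\t{b}\n")
        for node in nx.isolates(graph):
            fh.write(f"{node}\n")
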