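"""Pathway association network: Jaccard-overlap edges, annotated nodes.

Pathways sharing proteins are connected by edges weighted with the Jaccard
similarity |Pi ∩ Pj| / |Pi ∪ Pj| of their (deduplicated) protein sets.
Nodes carry the pathway size and, per subtype, the number of changed
proteins (nonzero entries of that subtype's merged pathway-protein matrix
row).  The displayed subset is chosen by a mean-changed-count rule: keep
pathways whose average changed-protein count across subtypes strictly
exceeds a threshold.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .pathways import PathwayDB, PathwayProteinMatrix

__all__ = ["jaccard", "select_top_pathways", "build_network", "write_graphml"]


def jaccard(p_i: Iterable[str], p_j: Iterable[str]) -> float:
    """Jaccard similarity of two protein sets (duplicates eliminated)."""
    a, b = set(p_i), set(p_j)
    if not a or not b:
        raise ValueError("Jaccard similarity undefined for an empty set")
    return len(a & b) / len(a | b)


def select_top_pathways(
    matrices: Sequence[PathwayProteinMatrix] | pd.DataFrame,
    min_avg_count: float = 5.0,
) -> list[str]:
    """Pathways whose mean changed-protein count across subtypes is > threshold.

    Accepts either the per-subtype merged matrices or a prebuilt frame of
    changed counts (pathways x subtypes).  The inequality is strict.
    """
    if isinstance(matrices, pd.DataFrame):
        counts = matrices
    else:
        counts = pd.DataFrame({m.subtype or i: m.changed_counts() for i, m in enumerate(matrices)})
    means = counts.mean(axis=1)
    return [str(p) for p in means.index[means > min_avg_count]]


def build_network(
    db: PathwayDB,
    selected: Sequence[str] | None = None,
    changed_counts: Mapping[str, pd.Series] | pd.Series | None = None,
    min_similarity: float = 0.0,
) -> nx.Graph:
    """Build the pathway association graph on the selected pathways.

    Every pathway pair with Jaccard similarity strictly above
    *min_similarity* (default 0: any shared protein) gets an edge with the
    similarity as the ``jaccard`` attribute.  Nodes carry ``protein_count``
    and one ``changed_count`` attribute per supplied subtype, so the
    topology is identical across subtypes and only node annotations differ.
    """
    if selected is None:
        selected = db.names
    missing = [p for p in selected if p not in db.pathways]
    if missing:
        raise ValueError(f"pathways absent from database: {missing}")
    g = nx.Graph()
    for pw in selected:
        attrs = {"protein_count": len(db[pw])}
        if isinstance(changed_counts, pd.Series):
            attrs["changed_count"] = int(changed_counts.get(pw, 0))
        elif isinstance(changed_counts, Mapping):
            for subtype, counts in changed_counts.items():
                attrs[f"changed_count_{subtype}"] = int(counts.get(pw, 0))
        g.add_node(pw, **attrs)
    pws = list(selected)
    for i in range(len(pws)):
        for j in range(i + 1, len(pws)):
            s = jaccard(db[pws[i]], db[pws[j]])
            if s > min_similarity:
                g.add_edge(pws[i], pws[j], jaccard=s)
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Plain TSV edge list: pathway_a, pathway_b, jaccard."""
    rows = [
        {"pathway_a": a, "pathway_b": b, "jaccard": d["jaccard"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "jaccard"]).to_csv(
        path, sep="\t", index=False
    )
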