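"""Hypergeometric over-representation and enrichment-map term clustering.

Gene-set collections are read from GMT files (set name, description, member
ids per line) against a declared background universe.  Enrichment is the
upper-tail hypergeometric probability P[X >= k]; raw p < alpha flags a term
enriched (BH q-values reported alongside).  Enriched terms are linked when
their member sets overlap above a cutoff (Jaccard or overlap coefficient);
connected components form term clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p_value", "q_value", "enriched"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            members = frozenset(members) & self.universe
            if not members:
                raise ValidationError(
                    f"gene set {name!r} is empty after restriction to the universe"
                )
            restricted[name] = members
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file; the universe defaults to the union of all members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: GMT line needs name, description, >=1 member")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if name in sets:
            raise ValidationError(f"{path}: duplicate gene set {name!r}")
        sets[name] = frozenset(members)
        descriptions[name] = desc
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hypergeom_ora(
    query: Iterable[str], collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    Returns one row per set (:data:`ENRICHMENT_COLUMNS`), sorted by p-value
    then term name.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    query = frozenset(query) & collection.universe
    if not query:
        raise ValidationError("query has no genes in the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["enriched"] = table["p_value"] < alpha
    return table.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)


@dataclass
class TermGraph:
    """Overlap graph over enriched terms with connected-component clusters."""

    graph: nx.Graph
    clusters: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))


def _overlap_weight(a: frozenset, b: frozenset, metric: str) -> float:
    inter = len(a & b)
    if metric == "jaccard":
        union = len(a | b)
        return inter / union if union else 0.0
    if metric == "overlap_coefficient":
        smaller = min(len(a), len(b))
        return inter / smaller if smaller else 0.0
    raise ValidationError(f"unknown overlap metric {metric!r}")


def term_overlap_graph(
    enriched: pd.DataFrame,
    collection: GeneSetCollection,
    metric: str = "jaccard",
    cutoff: float = 0.25,
) -> TermGraph:
    """Link enriched terms whose gene-set overlap weight is >= cutoff."""
    if enriched.empty:
        raise ValidationError("enriched table is empty")
    if metric not in ("jaccard", "overlap_coefficient"):
        raise ValidationError(f"unknown overlap metric {metric!r}")
    terms = sorted(enriched.loc[enriched["enriched"], "term"]) if "enriched" in enriched else sorted(enriched["term"])
    graph = nx.Graph()
    graph.add_nodes_from(terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            weight = _overlap_weight(collection.sets[a], collection.sets[b], metric)
            if weight >= cutoff:
                graph.add_edge(a, b, weight=weight)
    clusters: dict[str, int] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for label, component in enumerate(components, start=1):
        for term in component:
            clusters[term] = label
    return TermGraph(graph, clusters)
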