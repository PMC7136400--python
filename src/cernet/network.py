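"""Dysregulated miRNA-mediated lncRNA-mRNA ceRNA network construction.

The filter chain, applied to differentially expressed (DE) gene sets over
the paired expression profiles:

1. Pearson correlation between every DE lncRNA and DE mRNA; pairs with
   ``r > pcc_threshold`` (default 0.5, strict) are candidate crosstalks.
2. Pearson correlation between DE miRNAs and each candidate member.
3. A candidate pair is accepted as a mediated ceRNA triplet for every DE
   miRNA that targets both members per the interaction table and is
   negatively co-expressed with both (``r < neg_threshold``, default 0,
   strict).
4. Accepted triplets are integrated into one typed network.

Correlations use all paired samples.  Constant-expression genes have
undefined correlation: they are flagged, logged, and never yield triplets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InteractionTable, ValidationError

logger = logging.getLogger("cernet")

EDGE_CERNA = "lnc_m_cerna"
EDGE_MI_MRNA = "mi_m_target"
EDGE_MI_LNCRNA = "mi_l_target"
EDGE_KINDS = (EDGE_CERNA, EDGE_MI_MRNA, EDGE_MI_LNCRNA)


class MissingCorrelationError(ValidationError):
    """A correlation required by the mediation filter was not supplied."""


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations with an undefined-correlation flag.

    ``frame`` has columns ``id_a, id_b, r, n, defined``; ``r`` is NaN where
    ``defined`` is False (a constant expression vector).  Lookup is
    symmetric in (a, b).
    """

    frame: pd.DataFrame
    _lookup: dict[tuple[str, str], tuple[float, bool]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        lookup = {}
        for id_a, id_b, r, defined in zip(
            self.frame["id_a"], self.frame["id_b"], self.frame["r"], self.frame["defined"]
        ):
            lookup[(id_a, id_b)] = (float(r), bool(defined))
            lookup[(id_b, id_a)] = (float(r), bool(defined))
        self._lookup = lookup

    def r(self, a: str, b: str) -> float:
        try:
            return self._lookup[(a, b)][0]
        except KeyError:
            raise MissingCorrelationError(f"no correlation entry for ({a!r}, {b!r})")

    def defined(self, a: str, b: str) -> bool:
        try:
            return self._lookup[(a, b)][1]
        except KeyError:
            raise MissingCorrelationError(f"no correlation entry for ({a!r}, {b!r})")

    def __len__(self) -> int:
        return len(self.frame)


def pairwise_pcc(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    genes_a: Sequence[str] | None = None,
    genes_b: Sequence[str] | None = None,
) -> CorrelationTable:
    """Pearson correlation for every (gene of a) x (gene of b) cross pair.

    Both matrices must carry identically ordered sample ids and >= 3 samples.
    """
    if matrix_a.sample_ids != matrix_b.sample_ids:
        raise ValidationError("matrices must share identically ordered sample ids")
    n = matrix_a.n_samples
    if n < 3:
        raise ValidationError(f"correlation needs >= 3 samples, got {n}")
    genes_a = list(genes_a) if genes_a is not None else matrix_a.gene_ids
    genes_b = list(genes_b) if genes_b is not None else matrix_b.gene_ids
    a = matrix_a.restrict(genes_a).values
    b = matrix_b.restrict(genes_b).values
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    bad_a = sa == 0
    bad_b = sb == 0
    n_bad = int(bad_a.sum() + bad_b.sum())
    if n_bad:
        logger.info("pairwise_pcc: %d constant genes flagged undefined", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(np.where(bad_a, 1.0, sa), np.where(bad_b, 1.0, sb))
    r = np.clip(r, -1.0, 1.0)
    defined = ~(bad_a[:, None] | bad_b[None, :])
    r = np.where(defined, r, np.nan)
    ia, ib = np.meshgrid(np.arange(len(genes_a)), np.arange(len(genes_b)), indexing="ij")
    frame = pd.DataFrame(
        {
            "id_a": np.array(genes_a, dtype=object)[ia.ravel()],
            "id_b": np.array(genes_b, dtype=object)[ib.ravel()],
            "r": r.ravel(),
            "n": n,
            "defined": defined.ravel(),
        }
    )
    return CorrelationTable(frame)


def candidate_pairs(corr: CorrelationTable, pcc_threshold: float = 0.5) -> pd.DataFrame:
    """Defined pairs with r strictly above ``pcc_threshold``.

    ``corr`` is expected to hold DE lncRNAs as ``id_a`` and DE mRNAs as
    ``id_b``; columns of the result are ``lncrna_id, mrna_id, r``.
    """
    kept = corr.frame[(corr.frame["defined"]) & (corr.frame["r"] > pcc_threshold)]
    out = kept.rename(columns={"id_a": "lncrna_id", "id_b": "mrna_id"})[
        ["lncrna_id", "mrna_id", "r"]
    ]
    return out.sort_values(["lncrna_id", "mrna_id"], kind="stable").reset_index(
        drop=True
    )


@dataclass(frozen=True, order=True)
class CeRNATriplet:
    lncrna_id: str
    mrna_id: str
    mirna_id: str
    r_lm: float
    r_im: float
    r_il: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mrna_id, self.mirna_id)


def mediation_filter(
    candidates: pd.DataFrame,
    interactions: InteractionTable,
    corr_im: CorrelationTable,
    corr_il: CorrelationTable,
    de_mirnas: Iterable[str],
    neg_threshold: float = 0.0,
) -> list[CeRNATriplet]:
    """Accept (lncRNA, mRNA, miRNA) triplets mediated by a shared DE miRNA.

    For each candidate pair and each DE miRNA that targets both members,
    the triplet is accepted when the miRNA is negatively co-expressed with
    both members (strict ``r < neg_threshold``).  A pair with k qualifying
    miRNAs yields k triplets.  Missing correlation entries raise
    :class:`MissingCorrelationError`; undefined (constant-gene) entries are
    skipped with a logged count.
    """
    de_mirnas = set(de_mirnas)
    triplets: list[CeRNATriplet] = []
    n_undefined = 0
    for lnc, mrna, r_lm in zip(
        candidates["lncrna_id"], candidates["mrna_id"], candidates["r"]
    ):
        shared = (
            interactions.mirnas_targeting(mrna, "mRNA")
            & interactions.mirnas_targeting(lnc, "lncRNA")
            & de_mirnas
        )
        for mi in sorted(shared):
            if not (corr_im.defined(mi, mrna) and corr_il.defined(mi, lnc)):
                n_undefined += 1
                continue
            r_im = corr_im.r(mi, mrna)
            r_il = corr_il.r(mi, lnc)
            if r_im < neg_threshold and r_il < neg_threshold:
                triplets.append(
                    CeRNATriplet(lnc, mrna, mi, float(r_lm), r_im, r_il)
                )
    if n_undefined:
        logger.info(
            "mediation_filter: skipped %d miRNA pairings with undefined correlation",
            n_undefined,
        )
    return sorted(triplets)


@dataclass
class CeRNANetwork:
    """Union graph of accepted ceRNA triplets.

    ``nodes`` maps id -> rna class; ``edges`` holds (source, target, kind)
    with kinds :data:`EDGE_KINDS`; ceRNA edges run lncRNA -> mRNA and
    target edges run miRNA -> target.
    """

    nodes: dict[str, str]
    edges: frozenset[tuple[str, str, str]]
    triplets: tuple[CeRNATriplet, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self, rna_class: str) -> set[str]:
        return {n for n, c in self.nodes.items() if c == rna_class}

    def to_networkx(self):
        import networkx as nx

        graph = nx.Graph()
        for node in sorted(self.nodes):
            graph.add_node(node, rna_class=self.nodes[node])
        for source, target, kind in sorted(self.edges):
            graph.add_edge(source, target, kind=kind)
        return graph


def build_network(
    triplets: Iterable[CeRNATriplet], provenance: dict | None = None
) -> CeRNANetwork:
    """Integrate triplets into one deduplicated typed network."""
    triplets = tuple(sorted(triplets))
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for t in triplets:
        nodes[t.lncrna_id] = "lncRNA"
        nodes[t.mrna_id] = "mRNA"
        nodes[t.mirna_id] = "miRNA"
        edges.add((t.lncrna_id, t.mrna_id, EDGE_CERNA))
        edges.add((t.mirna_id, t.mrna_id, EDGE_MI_MRNA))
        edges.add((t.mirna_id, t.lncrna_id, EDGE_MI_LNCRNA))
    return CeRNANetwork(nodes, frozenset(edges), triplets, provenance or {})


@dataclass(frozen=True)
class NetworkSummary:
    """Per-class node counts and per-kind edge counts; totals are derived."""

    n_mirna: int
    n_mrna: int
    n_lncrna: int
    n_cerna_edges: int = 0
    n_mi_mrna_edges: int = 0
    n_mi_lncrna_edges: int = 0
    degree_distribution: tuple[tuple[str, int], ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_mrna + self.n_lncrna

    @property
    def n_edges(self) -> int:
        return self.n_cerna_edges + self.n_mi_mrna_edges + self.n_mi_lncrna_edges

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_cerna_edges": self.n_cerna_edges,
            "n_mi_mrna_edges": self.n_mi_mrna_edges,
            "n_mi_lncrna_edges": self.n_mi_lncrna_edges,
            "degree_distribution": dict(self.degree_distribution),
        }


def network_summary(network: CeRNANetwork) -> NetworkSummary:
    degree: dict[str, int] = {n: 0 for n in network.nodes}
    for source, target, _ in network.edges:
        degree[source] += 1
        degree[target] += 1
    kinds = {kind: 0 for kind in EDGE_KINDS}
    for _, _, kind in network.edges:
        kinds[kind] += 1
    return NetworkSummary(
        n_mirna=len(network.node_ids("miRNA")),
        n_mrna=len(network.node_ids("mRNA")),
        n_lncrna=len(network.node_ids("lncRNA")),
        n_cerna_edges=kinds[EDGE_CERNA],
        n_mi_mrna_edges=kinds[EDGE_MI_MRNA],
        n_mi_lncrna_edges=kinds[EDGE_MI_LNCRNA],
        degree_distribution=tuple(sorted(degree.items())),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "edge_list")


def write_network(network: CeRNANetwork, path: str | Path, fmt: str = "edge_list") -> None:
    path = Path(path)
    if fmt == "sif":
        lines = [f"{s}\t{kind}\t{t}" for s, t, kind in sorted(network.edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "edge_list":
        rows = sorted(network.edges)
        pd.DataFrame(
            {
                "source": [s for s, _, _ in rows],
                "kind": [k for _, _, k in rows],
                "target": [t for _, t, _ in rows],
                "source_class": [network.nodes[s] for s, _, _ in rows],
                "target_class": [network.nodes[t] for _, t, _ in rows],
            }
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}; expected {NETWORK_FORMATS}")


def read_edge_list(path: str | Path) -> tuple[frozenset[tuple[str, str, str]], dict[str, str]]:
    """Reconstruct the (source, target, kind) edge set and node classes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = frozenset(zip(df["source"], df["target"], df["kind"]))
    nodes: dict[str, str] = {}
    nodes.update(zip(df["source"], df["source_class"]))
    nodes.update(zip(df["target"], df["target_class"]))
    return edges, nodes


def input_digest(*paths: str | Path) -> str:
    """SHA-256 over the concatenated bytes of the given files (provenance)."""
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()
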