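"""Integrated gene/protein network construction.

Two layers are built and fused into one weighted, undirected graph:

* a gene layer, where each gene carries a differential weight
  ``g_w = |t| + |logFC|`` and each gene pair a differential-correlation
  value ``Diff_corr = corr(normal) - corr(tumour)`` in [-2, 2];
* a protein layer (the PPI graph), where each protein carries its
  eigenvector centrality on the score-weighted adjacency (scaled so the
  global maximum is 1) and each edge the maximum of its endpoint
  centralities.

The final network keeps the protein layer's edge set; node weights are
``c1 * g_w + c2 * eigen`` and edge weights
``d1 * gene_link_weight + d2 * protein_link_weight`` with all four
tuning coefficients defaulting to 0.5.

Because |t| is unbounded while centrality lives in [0, 1], the default
``normalise="minmax"`` mode min-max scales |t| and |logFC| across genes
before summing, making the two terms of the node weight commensurate;
``normalise="raw"`` applies the formulas literally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .expression import ExpressionMatrix, GeneDEStats

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

__all__ = [
    "GeneLayerNetwork",
    "ProteinLayerNetwork",
    "IntegratedNetwork",
    "gene_node_weight",
    "gene_node_weights",
    "diff_correlation",
    "eigencentrality",
    "protein_edge_weight",
    "gene_link_weight",
    "build_gene_layer",
    "build_protein_layer",
    "integrate",
]


def _ekey(u: str, v: str) -> Edge:
    """Canonical unordered edge key."""
    return (u, v) if u <= v else (v, u)


@dataclass
class GeneLayerNetwork:
    """Differential layer: node weights and signed correlation differences."""

    node_weights: dict[str, float]
    diff_corr: pd.DataFrame  # genes x genes, signed, zero diagonal
    link_weights: dict[Edge, float]  # per PPI edge, in [0, 1]


@dataclass
class ProteinLayerNetwork:
    """Topological layer: PPI edges, eigenvector centralities, edge weights."""

    edges: dict[Edge, float]  # association score in [0, 1]
    eigen: dict[str, float]  # centrality scaled to max 1
    link_weights: dict[Edge, float]  # max of endpoint centralities


@dataclass
class IntegratedNetwork:
    """Final weighted network: PPI topology carrying fused weights.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes carry
    ``weight`` (plus the ``t``, ``lfc``, ``g_w`` and ``eigen`` components)
    and whose edges carry ``weight``.
    """

    graph: nx.Graph
    params: dict[str, float] = field(default_factory=dict)

    @property
    def node_weight(self) -> dict[str, float]:
        return {n: d["weight"] for n, d in self.graph.nodes(data=True)}

    @property
    def edge_weight(self) -> dict[Edge, float]:
        return {_ekey(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def gene_node_weight(stats: GeneDEStats) -> float:
    """Differential node weight of one gene: |t| + |log FC| (raw mode)."""
    if not (np.isfinite(stats.t_value) and np.isfinite(stats.log_fc)):
        raise ValueError(f"non-finite statistics for gene {stats.gene_id}")
    return abs(stats.t_value) + abs(stats.log_fc)


def gene_node_weights(
    stats: list[GeneDEStats], normalise: str = "minmax"
) -> dict[str, float]:
    """Differential node weights for a whole DE table.

    In ``"minmax"`` mode |t| and |logFC| are each min-max scaled to [0, 1]
    across the finite-statistic genes before summing, so every weight lies
    in [0, 2] and the most extreme gene contributes 1 from each term.
    Genes with infinite t (zero within-group variance) are dropped with a
    warning.
    """
    finite = [s for s in stats if np.isfinite(s.t_value) and np.isfinite(s.log_fc)]
    if len(finite) < len(stats):
        logger.warning("dropping %d genes with non-finite statistics", len(stats) - len(finite))
    if not finite:
        return {}
    if normalise == "raw":
        return {s.gene_id: gene_node_weight(s) for s in finite}
    if normalise != "minmax":
        raise ValueError(f"unknown normalise mode {normalise!r}")
    at = np.array([abs(s.t_value) for s in finite])
    al = np.array([abs(s.log_fc) for s in finite])

    def _scale(x: np.ndarray) -> np.ndarray:
        rng = x.max() - x.min()
        if rng == 0:
            return np.zeros_like(x)
        return (x - x.min()) / rng

    w = _scale(at) + _scale(al)
    return {s.gene_id: float(v) for s, v in zip(finite, w)}


def _group_corr(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows correlate as 0."""
    sd = values.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant gene(s) in a group; correlations set to 0", int(const.sum()))
    centred = values - values.mean(axis=1, keepdims=True)
    safe_sd = np.where(const, 1.0, sd)
    z = centred / safe_sd[:, None]
    corr = z @ z.T / values.shape[1]
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 0.0)
    return np.clip(corr, -1.0, 1.0)


def diff_correlation(expr: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Differential Pearson correlation matrix over ``genes``.

    Entry (i, j) is corr(i, j) over normal samples minus corr(i, j) over
    tumour samples, so values lie in [-2, 2]; the diagonal is zero.
    Requires >=3 samples per group.
    """
    sub = expr.subset(genes)
    nmask, tmask = sub.normal_mask, sub.tumour_mask
    if nmask.sum() < 3 or tmask.sum() < 3:
        raise ValueError("Pearson correlation needs >=3 samples per group")
    diff = _group_corr(sub.values[:, nmask]) - _group_corr(sub.values[:, tmask])
    return pd.DataFrame(diff, index=genes, columns=genes)


def eigencentrality(edges: dict[Edge, float]) -> dict[str, float]:
    """Eigenvector centrality on the score-weighted undirected adjacency.

    Computed from the principal eigenvector of each connected component's
    weighted adjacency matrix (Perron-Frobenius guarantees a non-negative
    vector), then globally rescaled so the maximum centrality is 1.
    Isolated nodes (none arise from an edge dict, but callers may add
    them) would receive 0.
    """
    if not edges:
        raise ValueError("empty PPI graph")
    g = nx.Graph()
    for (u, v), s in edges.items():
        g.add_edge(u, v, score=float(s))
    cent: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            cent[nodes[0]] = 0.0
            logger.warning("isolated node %s assigned centrality 0", nodes[0])
            continue
        idx = {n: i for i, n in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for u, v, d in g.subgraph(comp).edges(data=True):
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
            vals += [d["score"], d["score"]]
        a = sp.coo_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes))).tocsr()
        if len(nodes) <= 3:
            w, vec = np.linalg.eigh(a.toarray())
            v0 = vec[:, np.argmax(w)]
        else:
            _, vec = spla.eigsh(a, k=1, which="LA", v0=np.ones(len(nodes)))
            v0 = vec[:, 0]
        v0 = np.abs(v0)  # Perron vector sign fix
        for n in nodes:
            cent[n] = float(v0[idx[n]])
    top = max(cent.values())
    if top == 0:
        return cent
    return {n: v / top for n, v in cent.items()}


def protein_edge_weight(w_k: float, w_l: float) -> float:
    """Topological edge weight: the larger endpoint centrality."""
    if w_k < 0 or w_l < 0:
        raise ValueError("centrality weights must be non-negative")
    return max(w_k, w_l)


def gene_link_weight(diff_corr_ij: float, assoc_score_ij: float) -> float:
    """Gene-layer edge weight combining rewiring and association evidence.

    |Diff_corr| (range [0, 2]) and the association score (range [0, 1])
    are each mapped to [0, 1] and averaged with equal weight, mirroring
    the uniform 0.5/0.5 coefficient philosophy of the integration step.
    """
    if not 0.0 <= assoc_score_ij <= 1.0:
        raise ValueError(f"association score {assoc_score_ij} outside [0, 1]")
    return 0.5 * abs(diff_corr_ij) / 2.0 + 0.5 * assoc_score_ij


def build_protein_layer(edges: dict[Edge, float]) -> ProteinLayerNetwork:
    """Assemble the topological layer from a scored PPI edge dict."""
    edges = {_ekey(u, v): float(s) for (u, v), s in edges.items()}
    eig = eigencentrality(edges)
    lw = {e: protein_edge_weight(eig[e[0]], eig[e[1]]) for e in edges}
    return ProteinLayerNetwork(edges=edges, eigen=eig, link_weights=lw)


def build_gene_layer(
    expr: ExpressionMatrix,
    stats: list[GeneDEStats],
    ppi_edges: dict[Edge, float],
    normalise: str = "minmax",
) -> GeneLayerNetwork:
    """Assemble the differential layer restricted to the PPI edge set."""
    nw = gene_node_weights(stats, normalise=normalise)
    genes = [g for g in (s.gene_id for s in stats) if g in nw]
    dc = diff_correlation(expr, genes)
    lw: dict[Edge, float] = {}
    for (u, v), score in ppi_edges.items():
        e = _ekey(u, v)
        d = float(dc.at[u, v]) if (u in dc.index and v in dc.index) else 0.0
        lw[e] = gene_link_weight(d, score)
    return GeneLayerNetwork(node_weights=nw, diff_corr=dc, link_weights=lw)


def integrate(
    gl: GeneLayerNetwork,
    pl: ProteinLayerNetwork,
    c1: float = 0.5,
    c2: float = 0.5,
    d1: float = 0.5,
    d2: float = 0.5,
    stats: dict[str, GeneDEStats] | None = None,
) -> IntegratedNetwork:
    """Fuse the two layers into the final weighted network.

    Node weight = ``c1 * g_w + c2 * eigen``; the edge set is exactly the
    protein layer's; edge weight = ``d1 * gene_link + d2 * protein_link``.
    DE genes absent from the PPI are dropped (count logged); a network
    with no shared genes is an error.
    """
    for name, v in {"c1": c1, "c2": c2, "d1": d1, "d2": d2}.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"tuning parameter {name}={v} outside [0, 1]")
    shared = set(gl.node_weights) & set(pl.eigen)
    if not shared:
        raise ValueError("no DE gene appears in the PPI network")
    dropped = len(gl.node_weights) - len(shared)
    if dropped:
        logger.info("%d DE gene(s) have no PPI node and were dropped", dropped)
    g = nx.Graph()
    for n in sorted(shared):
        s = stats.get(n) if stats else None
        g.add_node(
            n,
            weight=c1 * gl.node_weights[n] + c2 * pl.eigen[n],
            g_w=gl.node_weights[n],
            eigen=pl.eigen[n],
            t=(s.t_value if s else float("nan")),
            lfc=(s.log_fc if s else float("nan")),
        )
    for (u, v) in pl.edges:
        if u in shared and v in shared:
            g.add_edge(
                u, v,
                weight=d1 * gl.link_weights[(u, v)] + d2 * pl.link_weights[(u, v)],
            )
    return IntegratedNetwork(graph=g, params={"c1": c1, "c2": c2, "d1": d1, "d2": d2})
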