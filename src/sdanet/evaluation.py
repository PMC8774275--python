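"""Module scoring and validation utilities.

Provides the local-modularity boundary-sharpness score R, an exhaustive
connected-subset oracle for small networks, a pure-greedy single-start
baseline, and tabulation of repeated runs.

Local modularity here follows the boundary-sharpness convention: among
all edges incident to the module's boundary nodes, R is the fraction
that cross out of the module, so low R means a sharp boundary.  The
literature's complementary reading (fraction of boundary-incident edges
that stay inside, high = good) is available via ``convention="internal"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import IntegratedNetwork
from .optimizer import ModuleResult, SDAParams, objective, run_sda, _as_graph, _ekey

Edge = tuple[str, str]

__all__ = [
    "ModularityDecomposition",
    "local_modularity",
    "brute_force_best_module",
    "greedy_baseline",
    "compare_runs",
    "random_connected_subset",
    "planted_recovery",
]


@dataclass
class ModularityDecomposition:
    """Boundary decomposition of a module S within a host graph.

    ``S_prime`` is the set of outside nodes adjacent to S; ``B`` the
    boundary nodes of S (members with at least one outside neighbour);
    ``boundary_incident_edges`` every edge touching B; ``R`` the local
    modularity value under the chosen convention.
    """

    S: set[str]
    S_prime: set[str]
    B: set[str]
    boundary_incident_edges: list[Edge]
    R: float


def local_modularity(
    node_set, net: IntegratedNetwork | nx.Graph, convention: str = "sharpness"
) -> ModularityDecomposition:
    """Local modularity R of a module.

    ``sharpness`` (default): R = crossing boundary-incident edges / all
    boundary-incident edges; 0 for a module with no external edges
    (perfectly isolated = maximally sharp).  ``internal``: complementary
    fraction of boundary-incident edges that stay within S.
    """
    g = _as_graph(net)
    S = set(node_set)
    if not S:
        raise ValueError("empty module")
    missing = S - set(g.nodes)
    if missing:
        raise ValueError(f"module nodes not in network: {sorted(missing)[:5]}")
    s_prime = {nb for n in S for nb in g.neighbors(n)} - S
    B = {n for n in S if any(nb in s_prime for nb in g.neighbors(n))}
    incident = [
        _ekey(u, v)
        for u, v in g.edges
        if u in B or v in B
    ]
    if not incident:
        return ModularityDecomposition(S, s_prime, B, [], 0.0)
    crossing = sum(1 for u, v in incident if (u in S) != (v in S))
    frac_cross = crossing / len(incident)
    if convention == "sharpness":
        r = frac_cross
    elif convention == "internal":
        internal = sum(1 for u, v in incident if u in S and v in S)
        r = internal / len(incident)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return ModularityDecomposition(S, s_prime, B, incident, float(r))


def _connected_subsets(g: nx.Graph, m: int):
    """Yield every connected node subset of size m as a sorted tuple.

    Plain combination scan with a connectivity check; fine under the
    small-graph guard of the brute-force oracle.
    """
    for subset in itertools.combinations(sorted(g.nodes), m):
        if nx.is_connected(g.subgraph(subset)):
            yield subset


def brute_force_best_module(
    net: IntegratedNetwork | nx.Graph, m: int, max_nodes: int = 15
) -> tuple[set[str], float]:
    """Exhaustive maximum-F connected subset of size m (small graphs only).

    Refuses graphs above ``max_nodes`` nodes — enumeration is
    exponential.  Ties resolve to the lexicographically smallest sorted
    node tuple.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n > max_nodes:
        raise ValueError(
            f"brute force limited to {max_nodes} nodes; got {n} "
            "(use the SDA search for larger networks)"
        )
    if m == 1:
        best_node = min(
            g.nodes, key=lambda x: (-float(g.nodes[x].get("weight", 0.0)), x)
        )
        return {best_node}, objective([best_node], g)
    best_set: tuple | None = None
    best_f = -np.inf
    for subset in _connected_subsets(g, m):
        f = objective(subset, g)
        if f > best_f or (f == best_f and (best_set is None or subset < best_set)):
            best_set, best_f = subset, f
    if best_set is None:
        raise ValueError(f"no connected subset of size {m} exists")
    return set(best_set), float(best_f)


def greedy_baseline(
    net: IntegratedNetwork | nx.Graph, start: str, m: int
) -> tuple[set[str], float]:
    """Single-start pure-greedy comparator: no smell, no backtracking.

    From ``start``, repeatedly append the unvisited neighbour of the
    current node with the heaviest connecting edge (ties: heavier node,
    then smaller id); stop at size ``m`` or at a dead end.  Scored by the
    same induced-subgraph objective as SDA.
    """
    g = _as_graph(net)
    if start not in g:
        raise ValueError(f"start node {start} not in network")
    path = [start]
    chosen = {start}
    current = start
    while len(path) < m:
        best, best_key = None, None
        for nb in sorted(g.neighbors(current)):
            if nb in chosen:
                continue
            key = (
                float(g.edges[current, nb].get("weight", 0.0)),
                float(g.nodes[nb].get("weight", 0.0)),
            )
            if best_key is None or key > best_key:
                best, best_key = nb, key
        if best is None:
            break
        path.append(best)
        chosen.add(best)
        current = best
    return chosen, objective(chosen, g)


def random_connected_subset(
    net: IntegratedNetwork | nx.Graph, m: int, rng: np.random.Generator
) -> set[str]:
    """Draw a random connected m-node subset by randomised frontier growth.

    Starts from a uniform node of a component with >= m nodes and
    repeatedly absorbs a uniformly chosen frontier neighbour.  Not the
    uniform distribution over connected subsets (no cheap sampler
    exists), but an unbiased-enough null for boundary-sharpness
    comparisons.
    """
    g = _as_graph(net)
    comps = [c for c in nx.connected_components(g) if len(c) >= m]
    if not comps:
        raise ValueError(f"no component with >= {m} nodes")
    comp = sorted(comps[int(rng.integers(len(comps)))])
    start = comp[int(rng.integers(len(comp)))]
    chosen = {start}
    frontier = sorted(set(g.neighbors(start)))
    while len(chosen) < m:
        pick = frontier[int(rng.integers(len(frontier)))]
        chosen.add(pick)
        frontier = sorted(
            {nb for n in chosen for nb in g.neighbors(n)} - chosen
        )
    return chosen


def planted_recovery(
    spec,
    seed: int,
    adj_p_cut: float = 0.01,
    abs_lfc_cut: float = 1.0,
    score_cut: float = 0.4,
    restarts: int = 10,
    n_agents: int = 8,
) -> tuple[float, ModuleResult | None]:
    """Run the full pipeline on one synthetic instance; score recovery.

    Generates an instance from ``spec``/``seed``, filters DE genes,
    builds the integrated network, runs SDA with ``module_size`` equal
    to the planted size (capped at the largest connected component so a
    weak-signal instance still yields a module), and returns the Jaccard
    index between the recovered and planted node sets.  A signal too
    weak to leave any usable network scores 0.
    """
    from .expression import compute_de_stats, filter_de_genes
    from .pipeline import build_network
    from .simulate import generate

    expr, ppi, truth = generate(spec, seed=seed)
    stats = compute_de_stats(expr)
    de_genes = filter_de_genes(stats, adj_p_cut, abs_lfc_cut)
    if not de_genes:
        return 0.0, None
    try:
        net = build_network(expr, stats, ppi, de_genes=de_genes, score_cut=score_cut)
    except Exception:
        return 0.0, None
    g = net.graph
    if g.number_of_nodes() == 0:
        return 0.0, None
    biggest = max(len(c) for c in nx.connected_components(g))
    m = min(spec.planted_size, biggest)
    params = SDAParams(module_size=m, n_agents=min(n_agents, g.number_of_nodes()),
                       restarts=restarts, seed=seed)
    result = run_sda(net, params)
    got = set(result.nodes)
    j = len(got & truth) / len(got | truth)
    return float(j), result


def compare_runs(results: list[ModuleResult], wall_times: list[float] | None = None) -> pd.DataFrame:
    """Summarise repeated runs: mean/min/max objective and wall time."""
    if not results:
        raise ValueError("need at least one result")
    f = np.array([r.objective for r in results], dtype=float)
    row = {
        "n_runs": len(results),
        "mean_F": float(f.mean()),
        "min_F": float(f.min()),
        "max_F": float(f.max()),
    }
    if wall_times is not None:
        if len(wall_times) != len(results):
            raise ValueError("wall_times length mismatch")
        row["mean_wall_s"] = float(np.mean(wall_times))
    return pd.DataFrame([row])
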