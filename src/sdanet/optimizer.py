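"""Smell-detection-agent (SDA) search for maximum-weight connected modules.

The optimiser mimics a pack of scent-marking dogs.  Every node of the
weighted network is a *smell spot* whose attractiveness combines its
differential and topological weight; every edge carries a *link smell*
initialised to the edge weight.  Agents walk greedily from random start
nodes, always moving to the unvisited neighbour with the strongest link
smell, marking nodes as visited (territory) so that paths of different
agents never overlap, and reinforcing traversed links in proportion to
the weight accumulated along their path (``s_l <- s_l + delta * p``).
A walk ends when it holds ``m`` nodes or no unvisited neighbour remains
even after backtracking.  Each agent's node set is scored on its induced
subgraph by

    F = (1/m) * sum(node weights) + (1/q) * sum(induced edge weights)

and the best full-size module over all agents and restarts is returned.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .network import IntegratedNetwork

Edge = tuple[str, str]

__all__ = [
    "SDAParams",
    "SmellState",
    "AgentPath",
    "ModuleResult",
    "node_smell",
    "choose_next",
    "update_link_smell",
    "run_agent",
    "objective",
    "run_sda",
]


def _ekey(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


def _as_graph(net: IntegratedNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, IntegratedNetwork) else net


@dataclass
class SDAParams:
    """Run configuration of the SDA search.

    Defaults follow the calibration of the method: 8 agents, smell
    increment constant ``delta = 0.5``, equal smell coefficients, and 10
    independent restarts with resampled start nodes.
    """

    module_size: int
    n_agents: int = 8
    delta: float = 0.5
    smell_c1: float = 0.5
    smell_c2: float = 0.5
    seed: int = 0
    start_nodes: list[str] | None = None
    restarts: int = 10
    per_agent_visited: bool = False  # experimental: drop territory sharing

    def __post_init__(self) -> None:
        if self.module_size < 1:
            raise ValueError("module_size must be >= 1")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "module_size": self.module_size,
            "n_agents": self.n_agents,
            "delta": self.delta,
            "smell_c1": self.smell_c1,
            "smell_c2": self.smell_c2,
            "seed": self.seed,
            "start_nodes": self.start_nodes,
            "restarts": self.restarts,
            "per_agent_visited": self.per_agent_visited,
        }


@dataclass
class SmellState:
    """Mutable smell environment shared by the agents of one restart."""

    node_smell: dict[str, float]
    link_smell: dict[Edge, float]
    visited: set[str] = field(default_factory=set)


@dataclass
class AgentPath:
    """One agent's walk: ordered accepted nodes and diagnostics.

    ``checkpoints`` holds the path lengths at which the walk was in a
    locally maximal state (a dead end forcing a backtrack, or the end of
    the walk); these are the states the objective is evaluated at.
    """

    agent_id: int
    start: str
    nodes: list[str]
    accumulated: list[float]  # p after each accepted node
    terminated_early: bool = False
    checkpoints: list[int] = field(default_factory=list)


@dataclass
class ModuleResult:
    """Best module of a run: node set, induced edges, objective and echo."""

    nodes: list[str]
    edges: list[Edge]
    objective: float
    agent_paths: list[AgentPath]
    params: dict
    seed: int
    restart_index: int = 0
    per_restart_objective: list[float] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "objective": self.objective,
            "params": self.params,
            "seed": self.seed,
            "restart_index": self.restart_index,
            "per_restart_objective": self.per_restart_objective,
            "agent_paths": [
                {
                    "agent_id": p.agent_id,
                    "start": p.start,
                    "nodes": p.nodes,
                    "accumulated": p.accumulated,
                    "terminated_early": p.terminated_early,
                }
                for p in self.agent_paths
            ],
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def node_smell(x: float, y: float, c1: float = 0.5, c2: float = 0.5) -> float:
    """Smell value of a node: ``c1 * x + c2 * y``.

    ``x`` is the differential weight, ``y`` the topological weight; with
    the integration coefficients this reproduces the fused node weight.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("node smell inputs must be finite")
    return c1 * x + c2 * y


def _make_smell_state(g: nx.Graph, c1: float, c2: float) -> SmellState:
    ns: dict[str, float] = {}
    for n, d in g.nodes(data=True):
        if "g_w" in d or "eigen" in d:
            ns[n] = node_smell(d.get("g_w", 0.0), d.get("eigen", 0.0), c1, c2)
        else:
            # plain weighted graph: the fused weight is the smell
            ns[n] = float(d.get("weight", 0.0))
    ls = {_ekey(u, v): float(d.get("weight", 0.0)) for u, v, d in g.edges(data=True)}
    return SmellState(node_smell=ns, link_smell=ls)


def choose_next(
    current: str,
    smell: SmellState,
    net: IntegratedNetwork | nx.Graph,
    rng: np.random.Generator | None = None,
) -> str | None:
    """Unvisited neighbour of ``current`` with maximal link smell.

    Ties fall to the higher node smell, then to the smaller node id, so
    the choice is deterministic; ``rng`` is accepted for interface
    symmetry but never consulted.
    """
    g = _as_graph(net)
    best: str | None = None
    best_key: tuple[float, float] | None = None
    for nb in sorted(g.neighbors(current)):
        if nb in smell.visited:
            continue
        key = (smell.link_smell[_ekey(current, nb)], smell.node_smell[nb])
        if best_key is None or key > best_key:
            best, best_key = nb, key
    return best


def update_link_smell(smell: SmellState, edge: Edge, p: float, delta: float) -> SmellState:
    """Reinforce one link: ``s_l <- s_l + delta * p``; other entries untouched."""
    e = _ekey(*edge)
    if e not in smell.link_smell:
        raise KeyError(f"edge {edge} not in network")
    smell.link_smell[e] = smell.link_smell[e] + delta * p
    return smell


def run_agent(
    start: str,
    smell: SmellState,
    net: IntegratedNetwork | nx.Graph,
    params: SDAParams,
    rng: np.random.Generator | None = None,
    agent_id: int = 0,
) -> AgentPath:
    """Greedy smell-guided walk from ``start`` collecting up to ``m`` nodes.

    Each accepted node is marked visited; each traversed edge is
    reinforced with the weight ``p`` accumulated up to the current node.
    On a dead end the agent backtracks along its own path to the most
    recent node that still has an unvisited neighbour; the walk ends when
    the path holds ``module_size`` nodes or backtracking is exhausted
    (``terminated_early``).
    """
    g = _as_graph(net)
    if start in smell.visited:
        raise ValueError(f"start node {start} already visited")
    weights = {n: float(d.get("weight", 0.0)) for n, d in g.nodes(data=True)}
    path = [start]
    smell.visited.add(start)
    p = weights[start]
    accumulated = [p]
    stack = [start]  # backtrack trail within this agent's own path
    current = start
    early = False
    checkpoints: list[int] = []
    while len(path) < params.module_size:
        nxt = choose_next(current, smell, g, rng)
        if nxt is None:
            # dead end: a locally maximal state worth scoring, then
            # retreat along own trail
            checkpoints.append(len(path))
            while stack and choose_next(stack[-1], smell, g, rng) is None:
                stack.pop()
            if not stack:
                early = True
                break
            current = stack[-1]
            continue
        update_link_smell(smell, (current, nxt), p, params.delta)
        path.append(nxt)
        smell.visited.add(nxt)
        p += weights[nxt]
        accumulated.append(p)
        stack.append(nxt)
        current = nxt
    if not checkpoints or checkpoints[-1] != len(path):
        checkpoints.append(len(path))
    return AgentPath(agent_id=agent_id, start=start, nodes=path,
                     accumulated=accumulated, terminated_early=early,
                     checkpoints=checkpoints)


def objective(node_set: Iterable[str], net: IntegratedNetwork | nx.Graph) -> float:
    """Module objective F: mean node weight plus mean induced-edge weight.

    With no induced edges the edge term is 0, so a singleton scores its
    own node weight.
    """
    g = _as_graph(net)
    nodes = list(node_set)
    if not nodes:
        raise ValueError("empty node set")
    sub = g.subgraph(nodes)
    node_term = sum(float(g.nodes[n].get("weight", 0.0)) for n in nodes) / len(nodes)
    q = sub.number_of_edges()
    if q == 0:
        return node_term
    edge_term = sum(float(d.get("weight", 0.0)) for _, _, d in sub.edges(data=True)) / q
    return node_term + edge_term


def _draw_starts(
    g: nx.Graph, params: SDAParams, rng: np.random.Generator, restart: int
) -> list[str]:
    """Start nodes of one restart: a cycled lead plus random companions.

    The first agent's start cycles deterministically through the sorted
    node list across restarts, so with at least as many restarts as
    nodes every node leads one restart on a fresh smell field; the
    remaining agents draw distinct random starts.
    """
    if params.start_nodes:
        return list(params.start_nodes)
    nodes = sorted(g.nodes)
    k = min(params.n_agents, len(nodes))
    lead = nodes[restart % len(nodes)]
    rest = [n for n in nodes if n != lead]
    idx = rng.choice(len(rest), size=k - 1, replace=False) if k > 1 else []
    return [lead] + [rest[i] for i in idx]


def run_sda(net: IntegratedNetwork | nx.Graph, params: SDAParams) -> ModuleResult:
    """Full SDA run: restarts x agents over a shared smell environment.

    Per restart a fresh :class:`SmellState` is built, ``n_agents``
    distinct start nodes are drawn (or taken from ``params.start_nodes``)
    and agents run sequentially; because visited marks are shared, agent
    paths are node-disjoint and later agents feel the smell reinforcement
    of earlier ones.  The objective is evaluated at every locally maximal
    state of every walk (each dead end and the completed path); the
    highest-F state over all agents and restarts is the returned module,
    ties going to the larger state.  The whole procedure is deterministic
    in (network, params, seed).
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comp_sizes = [len(c) for c in nx.connected_components(g)]
    if max(comp_sizes) < params.module_size:
        raise ValueError(
            f"no connected component has >= {params.module_size} nodes "
            f"(largest component: {max(comp_sizes)})"
        )
    rng = np.random.default_rng(params.seed)
    best: tuple[float, int] | None = None  # (F, state size), maximised
    best_result: ModuleResult | None = None
    per_restart_f: list[float] = []
    for r in range(params.restarts):
        smell = _make_smell_state(g, params.smell_c1, params.smell_c2)
        starts = _draw_starts(g, params, rng, r)
        paths: list[AgentPath] = []
        restart_best_f = -np.inf
        for a, start in enumerate(starts):
            state = (
                SmellState(smell.node_smell, dict(smell.link_smell))
                if params.per_agent_visited
                else smell
            )
            if start in state.visited:
                free = sorted(set(g.nodes) - state.visited)
                if not free:
                    break
                start = free[int(rng.integers(len(free)))]
            path = run_agent(start, state, g, params, rng, agent_id=a)
            paths.append(path)
            # score every locally maximal state of the walk; the path
            # only ever grows, so the state at checkpoint L is the
            # length-L prefix
            for length in path.checkpoints:
                cand = path.nodes[:length]
                f = objective(cand, g)
                restart_best_f = max(restart_best_f, f)
                key = (f, length)
                if best is None or key > best:
                    best = key
                    best_result = ModuleResult(
                        nodes=sorted(cand),
                        edges=sorted(_ekey(u, v) for u, v in g.subgraph(cand).edges),
                        objective=f,
                        agent_paths=paths,  # refreshed once restart completes
                        params=params.to_dict(),
                        seed=params.seed,
                        restart_index=r,
                    )
        if best_result is not None and best_result.restart_index == r:
            best_result.agent_paths = paths
        per_restart_f.append(float(restart_best_f))
    assert best_result is not None
    best_result.per_restart_objective = per_restart_f
    return best_result


def timed_run(net: IntegratedNetwork | nx.Graph, params: SDAParams) -> tuple[ModuleResult, float]:
    """Run SDA and report wall time in seconds."""
    t0 = time.perf_counter()
    res = run_sda(net, params)
    return res, time.perf_counter() - t0
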