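"""Biased targeted random walks on a bait-effector PPI network.

The network is built from a STRING-style edge list: edges below the
confidence threshold (default 0.7, strict "less than") are removed first,
then only nodes within a shortest-path distance of 4 from the effector
layer are retained.  The bait source connects to the effectors by
directed edges only; everything else is undirected.

A targeted walk starts at the source and, at each node, steps to a
neighbour drawn from a distribution that favours nodes found in the
condition's measured interactome by ``bias_factor`` (default 20)::

    P(step to neighbour in AP-MS evidence) = 20 * P(step to neighbour not in evidence)

normalised over the neighbourhood.  A walk succeeds when it reaches its
target within ``walklen = shortest_path(source, target) + 2`` steps.  The
resulting path multiset is filtered (frequency >= 1e-6, the scale-free
form of 100 per 1e8 walks), the top 10 paths per target are kept, paths
are decomposed into edges to give a condition-specific information-flow
network, and per-effector traversal weights summarise how strongly each
effector pathway carries the flow.

``enumerate_paths_exact`` expands the same walk process exactly on small
graphs and serves as the independent oracle for the sampler.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

SOURCE_ID = -1  # internal integer id of the source node


@dataclasses.dataclass
class EffectorNetwork:
    """Undirected weighted PPI graph plus a bait source and effector layer.

    ``graph`` holds only the undirected part (the source is not a node of
    it); the directed source->effector edges are implied by ``effectors``.
    """

    graph: nx.Graph
    source: str
    effectors: set

    def __post_init__(self) -> None:
        if self.source in self.graph:
            raise ValueError("source must not appear in the undirected graph")
        missing = set(self.effectors) - set(self.graph.nodes)
        if missing:
            raise ValueError(f"effectors absent from the graph: {sorted(missing)}")

    @property
    def directed_source_edges(self) -> list[tuple[str, str]]:
        return [(self.source, e) for e in sorted(self.effectors)]

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": u, "node_b": v, "score": d.get("score", 1.0)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])


@dataclasses.dataclass
class WalkSpec:
    """Parameters of one target's walk ensemble."""

    target: str
    walklen: int | None = None  # None -> shortest_path(source, target) + 2
    n_walks: int = 100_000
    bias_factor: float = 20.0
    evidence: frozenset = frozenset()
    seed: int = 0
    allow_revisit: bool = True

    def __post_init__(self) -> None:
        if self.bias_factor < 1:
            raise ValueError("bias_factor must be >= 1")
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        self.evidence = frozenset(self.evidence)


@dataclasses.dataclass
class PathEnsemble:
    """Multiset of successful source->target node sequences."""

    paths: dict  # tuple of node ids -> count
    n_walks: int
    n_success: int

    def frequencies(self) -> dict:
        return {p: c / self.n_walks for p, c in self.paths.items()}


# --------------------------------------------------------------------- #
# network construction
# --------------------------------------------------------------------- #
def build_network(
    edges: pd.DataFrame,
    effectors: Iterable[str],
    source: str,
    min_score: float = 0.7,
    max_sp: int = 4,
) -> EffectorNetwork:
    """Construct the walk network from a weighted edge list.

    Edges with score < ``min_score`` are removed first (equal-to-threshold
    edges survive); then all nodes with shortest-path distance greater
    than ``max_sp`` from the effector layer are dropped with their
    incident edges.  Effectors isolated by the score filter are kept with
    a warning.
    """
    effectors = set(effectors)
    universe = set(edges["node_a"]) | set(edges["node_b"])
    unknown = effectors - universe
    if unknown:
        raise ValueError(f"effectors not in the edge list: {sorted(unknown)}")

    g = nx.Graph()
    kept = edges[edges["score"] >= min_score]
    for row in kept.itertuples():
        if source in (row.node_a, row.node_b):
            continue  # source connects via directed effector edges only
        g.add_edge(row.node_a, row.node_b, score=float(row.score))

    isolated = effectors - set(g.nodes)
    if isolated:
        warnings.warn(
            f"effectors isolated after score filtering: {sorted(isolated)}",
            stacklevel=2,
        )
        g.add_nodes_from(isolated)

    seeds = [e for e in effectors if e in g]
    dist = nx.multi_source_dijkstra_path_length(g, seeds, weight=None) if seeds else {}
    keep_nodes = {n for n, d in dist.items() if d <= max_sp} | effectors
    sub = nx.Graph(g.subgraph(keep_nodes))
    return EffectorNetwork(graph=sub, source=source, effectors=effectors)


def step_distribution(
    network: EffectorNetwork,
    current: str,
    evidence: Iterable[str] = (),
    bias_factor: float = 20.0,
) -> tuple[list[str], np.ndarray]:
    """Neighbour list and step probabilities from ``current``.

    Neighbours in the AP-MS evidence set get weight ``bias_factor``,
    others weight 1; the vector is normalised over the neighbourhood (so
    the actual probability depends on the number of connecting nodes).
    From the source the neighbourhood is the effector layer.
    """
    evidence = set(evidence)
    if current == network.source:
        nbrs = sorted(network.effectors)
    else:
        nbrs = sorted(network.graph.neighbors(current))
    if not nbrs:
        raise ValueError(f"node {current!r} has no neighbours")
    w = np.array([bias_factor if n in evidence else 1.0 for n in nbrs])
    return nbrs, w / w.sum()


def walk_length(network: EffectorNetwork, target: str) -> int:
    """``walklen = shortest_path(source, target) + 2`` with the directed
    source->effector edges respected."""
    if target == network.source:
        raise ValueError("target must differ from the source")
    if target not in network.graph:
        raise ValueError(f"target {target!r} not in the network")
    best = np.inf
    lengths = nx.multi_source_dijkstra_path_length(
        network.graph, [e for e in network.effectors if e in network.graph], weight=None
    )
    if target in lengths:
        best = lengths[target] + 1  # +1 for the source->effector step
    if not np.isfinite(best):
        raise ValueError(f"target {target!r} unreachable from the source")
    return int(best) + 2


# --------------------------------------------------------------------- #
# the walk engine
# --------------------------------------------------------------------- #
def _index_network(network: EffectorNetwork):
    nodes = sorted(network.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    return nodes, idx


def _transition_tables(
    network: EffectorNetwork,
    idx: Mapping[str, int],
    evidence: frozenset,
    bias_factor: float,
):
    """Per-node neighbour ids and cumulative step probabilities."""
    nbr_ids: dict[int, np.ndarray] = {}
    cums: dict[int, np.ndarray] = {}
    for node, i in idx.items():
        nbrs = sorted(network.graph.neighbors(node))
        if not nbrs:
            continue
        w = np.array([bias_factor if n in evidence else 1.0 for n in nbrs])
        p = w / w.sum()
        nbr_ids[i] = np.array([idx[n] for n in nbrs], dtype=np.int64)
        cums[i] = np.cumsum(p)
    # source row
    eff = sorted(network.effectors)
    w = np.array([bias_factor if n in evidence else 1.0 for n in eff])
    p = w / w.sum()
    nbr_ids[SOURCE_ID] = np.array([idx[n] for n in eff], dtype=np.int64)
    cums[SOURCE_ID] = np.cumsum(p)
    return nbr_ids, cums


def run_walks(network: EffectorNetwork, spec: WalkSpec) -> PathEnsemble:
    """Sample ``spec.n_walks`` biased targeted walks; reproducible under
    ``spec.seed``.  Node revisits are allowed by default (the bias rule is
    memoryless); ``allow_revisit=False`` switches to a slower
    non-revisiting sampler."""
    if spec.target == network.source:
        raise ValueError("target must differ from the source")
    walklen = spec.walklen if spec.walklen is not None else walk_length(network, spec.target)
    nodes, idx = _index_network(network)
    if spec.target not in idx:
        raise ValueError(f"target {spec.target!r} not in the network")
    target_id = idx[spec.target]
    rng = np.random.default_rng(spec.seed)

    if not spec.allow_revisit:
        return _run_walks_no_revisit(network, spec, walklen, rng)

    nbr_ids, cums = _transition_tables(network, idx, spec.evidence, spec.bias_factor)
    n = spec.n_walks
    paths = np.full((n, walklen + 1), -9, dtype=np.int64)
    paths[:, 0] = SOURCE_ID
    cur = np.full(n, SOURCE_ID, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    done_step = np.full(n, -1, dtype=np.int64)

    for step in range(1, walklen + 1):
        if not active.any():
            break
        u = rng.random(n)
        nxt = cur.copy()
        for node_id in np.unique(cur[active]):
            mask = active & (cur == node_id)
            if node_id not in nbr_ids:  # dead end: walk fails
                active[mask] = False
                continue
            choice = np.searchsorted(cums[node_id], u[mask], side="right")
            choice = np.minimum(choice, len(nbr_ids[node_id]) - 1)
            nxt[mask] = nbr_ids[node_id][choice]
        paths[active, step] = nxt[active]
        reached = active & (nxt == target_id)
        done_step[reached] = step
        active &= ~reached
        cur = nxt

    success = done_step >= 0
    counts: dict[tuple, int] = {}
    for length in np.unique(done_step[success]):
        rows = paths[done_step == length, : length + 1]
        uniq, cnt = np.unique(rows, axis=0, return_counts=True)
        for row, c in zip(uniq, cnt):
            path = tuple(
                network.source if v == SOURCE_ID else nodes[v] for v in row
            )
            counts[path] = counts.get(path, 0) + int(c)
    return PathEnsemble(paths=counts, n_walks=spec.n_walks, n_success=int(success.sum()))


def _run_walks_no_revisit(network, spec, walklen, rng):
    """Python-loop sampler that forbids revisiting a node within a walk."""
    counts: dict[tuple, int] = {}
    n_success = 0
    for _ in range(spec.n_walks):
        path = [network.source]
        visited = {network.source}
        ok = False
        for _step in range(walklen):
            nbrs, probs = step_distribution(
                network, path[-1], spec.evidence, spec.bias_factor
            )
            allowed = [i for i, n in enumerate(nbrs) if n not in visited]
            if not allowed:
                break
            p = probs[allowed] / probs[allowed].sum()
            nxt = nbrs[allowed[int(rng.choice(len(allowed), p=p))]]
            path.append(nxt)
            visited.add(nxt)
            if nxt == spec.target:
                ok = True
                break
        if ok:
            key = tuple(path)
            counts[key] = counts.get(key, 0) + 1
            n_success += 1
    return PathEnsemble(paths=counts, n_walks=spec.n_walks, n_success=n_success)


# --------------------------------------------------------------------- #
# exact enumeration oracle
# --------------------------------------------------------------------- #
def enumerate_paths_exact(
    network: EffectorNetwork,
    spec: WalkSpec,
    max_states: int = 1_000_000,
) -> dict:
    """Exact path probabilities of the walk process by depth-limited
    expansion, absorbing at the target.  Probabilities of successful paths
    plus the failure mass sum to 1.  Guarded at ``max_states`` partial
    states; feasible only on small graphs."""
    if spec.target == network.source:
        raise ValueError("target must differ from the source")
    walklen = spec.walklen if spec.walklen is not None else walk_length(network, spec.target)
    out: dict[tuple, float] = {}
    stack = [((network.source,), 1.0)]
    states = 0
    while stack:
        path, prob = stack.pop()
        states += 1
        if states > max_states:
            raise RuntimeError("state budget exceeded in exact enumeration")
        if len(path) - 1 >= walklen:
            continue
        try:
            nbrs, probs = step_distribution(
                network, path[-1], spec.evidence, spec.bias_factor
            )
        except ValueError:
            continue  # dead end
        for nbr, p_step in zip(nbrs, probs):
            if not spec.allow_revisit and nbr in path:
                continue
            new_prob = prob * float(p_step)
            new_path = path + (nbr,)
            if nbr == spec.target:
                out[new_path] = out.get(new_path, 0.0) + new_prob
            else:
                stack.append((new_path, new_prob))
    return out


# --------------------------------------------------------------------- #
# path aggregation
# --------------------------------------------------------------------- #
def filter_and_rank_paths(
    pe: PathEnsemble, min_freq: float = 1e-6, k: int = 10
) -> list[tuple[tuple, float]]:
    """Drop paths below ``min_freq`` (the scale-free form of 100 per 1e8
    walks) and keep the top ``k`` by frequency; ties break toward shorter
    then lexicographically earlier paths."""
    freqs = [
        (path, count / pe.n_walks)
        for path, count in pe.paths.items()
        if count / pe.n_walks >= min_freq
    ]
    freqs.sort(key=lambda item: (-item[1], len(item[0]), item[0]))
    return freqs[:k]


def condition_network(
    ranked_paths: Iterable[tuple[tuple, float]],
    source: str | None = None,
) -> dict:
    """Decompose retained paths into edges weighted by path frequency.

    Undirected edges are canonicalised (sorted node pair); edges leaving
    the ``source`` stay directed.  Weights accumulate across paths and
    targets."""
    edges: dict[tuple, float] = {}
    for path, freq in ranked_paths:
        for u, v in zip(path[:-1], path[1:]):
            key = (u, v) if (source is not None and u == source) else tuple(sorted((u, v)))
            edges[key] = edges.get(key, 0.0) + freq
    return edges


def effector_traversal(
    ranked_paths: Iterable[tuple[tuple, float]],
    effectors: Iterable[str],
    mode: str = "frequency",
) -> dict:
    """Traversal weight per effector over the retained paths.

    ``frequency`` sums each containing path's frequency (scale-free in the
    number of walks); ``count`` counts containing paths."""
    if mode not in {"frequency", "count"}:
        raise ValueError(f"unknown mode {mode!r}")
    out = {e: 0.0 for e in effectors}
    for path, freq in ranked_paths:
        members = set(path)
        for e in out:
            if e in members:
                out[e] += freq if mode == "frequency" else 1.0
    return out


def effector_traversal_matrix(
    ranked_by_condition: Mapping[str, Iterable[tuple[tuple, float]]],
    effectors: Sequence[str],
    mode: str = "frequency",
) -> pd.DataFrame:
    """Effectors x conditions traversal-weight matrix for one GO term."""
    cols = {
        cond: effector_traversal(paths, effectors, mode=mode)
        for cond, paths in ranked_by_condition.items()
    }
    mat = pd.DataFrame(cols).reindex(list(effectors))
    return mat.fillna(0.0)
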