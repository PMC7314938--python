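"""Discrete Bayesian-network structure learning and DOT export.

Learning is hybrid: candidate parents for each node are first restricted to
its top-m pairwise-dependent partners ("sparse candidates"), then a greedy
first-improvement hill climb over add/delete/reverse edge moves maximizes
the BDeu network score, with seeded random restarts.  Per-edge strengths are
log10 Bayes factors between the learned model and the model with the edge
removed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .discretize import DiscretizedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreConfig",
    "BayesianNetworkModel",
    "family_score",
    "sparse_candidates",
    "learn_structure",
    "edge_strength",
    "compute_edge_strengths",
    "export_dot",
]

_EPS = 1e-9  # minimum score gain for a move to count as an improvement


@dataclass(frozen=True)
class ScoreConfig:
    score: str = "bdeu"
    ess: float = 1.0
    max_parents: int = 4
    candidates_per_node: int = 10
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score != "bdeu":
            raise ValueError(f"unsupported score {self.score!r}")
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.candidates_per_node < self.max_parents:
            raise ValueError("candidates_per_node must be >= max_parents")


def _encode_parent_configs(
    data: DiscretizedDataset, parents: Sequence[str]
) -> tuple[np.ndarray, int]:
    """Mixed-radix encoding of parent value tuples; returns (codes, q)."""
    q = 1
    codes = np.zeros(data.n_samples, dtype=np.int64)
    for p in parents:
        card = data.cardinalities[data.index(p)]
        codes = codes * card + data.column(p)
        q *= card
    return codes, q


def family_score(
    data: DiscretizedDataset,
    child: str,
    parents: Sequence[str],
    cfg: ScoreConfig = ScoreConfig(),
) -> float:
    """BDeu log marginal likelihood of one child given its parent set.

    With q parent configurations and r child levels, the prior puts mass
    ess/(q*r) on each cell; parent configurations unobserved in the data
    contribute nothing to the log score.
    """
    parents = list(parents)
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    r = data.cardinalities[data.index(child)]
    child_vals = data.column(child)
    codes, q = _encode_parent_configs(data, parents)

    # counts over observed (parent config, child level) cells
    joint = codes * r + child_vals
    observed_configs, config_inverse = np.unique(codes, return_inverse=True)
    counts = np.zeros((observed_configs.size, r))
    np.add.at(counts, (config_inverse, child_vals), 1.0)

    a_jk = cfg.ess / (q * r)
    a_j = cfg.ess / q
    n_j = counts.sum(axis=1)
    score = (gammaln(a_j) - gammaln(a_j + n_j)).sum()
    score += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    return float(score)


def _pairwise_plugin_mi(data: DiscretizedDataset) -> np.ndarray:
    """Plug-in contingency-table MI (nats) for every variable pair."""
    nv = len(data.variables)
    n = data.n_samples
    mi = np.zeros((nv, nv))
    cols = data.data
    cards = data.cardinalities
    for i in range(nv):
        for j in range(i + 1, nv):
            ri, rj = cards[i], cards[j]
            joint = np.bincount(cols[i] * rj + cols[j], minlength=ri * rj).reshape(ri, rj)
            p = joint / n
            pi = p.sum(axis=1, keepdims=True)
            pj = p.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = p * np.log(p / (pi * pj))
            mi[i, j] = mi[j, i] = np.nansum(terms)
    return mi


def sparse_candidates(
    data: DiscretizedDataset, m: int
) -> dict[str, frozenset[str]]:
    """Top-m pairwise-MI partners per node, symmetrically closed.

    The closure (a in cand(b) implies b in cand(a)) keeps edge-reversal
    moves well-defined during search.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    mi = _pairwise_plugin_mi(data)
    nv = len(data.variables)
    cand: dict[int, set[int]] = {i: set() for i in range(nv)}
    for i in range(nv):
        others = [j for j in range(nv) if j != i]
        # deterministic tie-break on index
        top = sorted(others, key=lambda j: (-mi[i, j], j))[:m]
        cand[i].update(top)
    for i in range(nv):
        for j in list(cand[i]):
            cand[j].add(i)
    names = data.variables
    return {names[i]: frozenset(names[j] for j in cand[i]) for i in range(nv)}


@dataclass
class BayesianNetworkModel:
    """A learned DAG with per-family BDeu scores and edge strengths."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    log_score: float
    edge_strengths: dict[tuple[str, str], float] = field(default_factory=dict)
    config: ScoreConfig = field(default_factory=ScoreConfig)
    score_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has an unknown endpoint")
        if _has_cycle(self.nodes, self.edges):
            raise ValueError("edge set contains a directed cycle")

    def parents_of(self, node: str) -> list[str]:
        return [u for u, v in self.edges if v == node]

    def undirected_adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def total_score(self, data: DiscretizedDataset) -> float:
        """Recompute the decomposable score from scratch (for audits)."""
        return sum(family_score(data, n, self.parents_of(n), self.config) for n in self.nodes)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "log_score": self.log_score,
            "edge_strengths": {f"{u}->{v}": s for (u, v), s in self.edge_strengths.items()},
            "edge_strength_units": "log10 marginal-likelihood ratio",
            "config": asdict(self.config),
            "score_trace": self.score_trace,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesianNetworkModel":
        payload = json.loads(Path(path).read_text())
        strengths = {}
        for key, s in payload.get("edge_strengths", {}).items():
            u, v = key.split("->", 1)
            strengths[(u, v)] = float(s)
        return cls(
            nodes=list(payload["nodes"]),
            edges=[tuple(e) for e in payload["edges"]],
            log_score=float(payload["log_score"]),
            edge_strengths=strengths,
            config=ScoreConfig(**payload.get("config", {})),
            score_trace=list(payload.get("score_trace", [])),
        )


def _has_cycle(nodes: Sequence[str], edges: Sequence[tuple[str, str]]) -> bool:
    children: dict[str, set[str]] = {n: set() for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        if v not in children[u]:
            children[u].add(v)
            indeg[v] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen < len(nodes)


class _Graph:
    """Mutable DAG state for the hill climb (adjacency as index sets)."""

    def __init__(self, nv: int):
        self.parents: list[set[int]] = [set() for _ in range(nv)]
        self.children: list[set[int]] = [set() for _ in range(nv)]

    def add(self, u: int, v: int) -> None:
        self.parents[v].add(u)
        self.children[u].add(v)

    def remove(self, u: int, v: int) -> None:
        self.parents[v].discard(u)
        self.children[u].discard(v)

    def has(self, u: int, v: int) -> bool:
        return v in self.children[u]

    def reaches(self, src: int, dst: int) -> bool:
        """True if a directed path src -> ... -> dst exists."""
        stack = [src]
        seen = {src}
        while stack:
            n = stack.pop()
            if n == dst:
                return True
            for c in self.children[n]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False


def learn_structure(
    data: DiscretizedDataset, cfg: ScoreConfig = ScoreConfig()
) -> BayesianNetworkModel:
    """Greedy search-and-score restricted to sparse candidate sets.

    Runs ``cfg.restarts`` seeded hill climbs (the first from the empty
    graph, the rest from random candidate-edge seedings), each accepting
    the best-scoring add/delete/reverse move until no move improves, and
    returns the highest-scoring local optimum.  The accepted-move score
    trace of the winning restart is kept on the model and is monotone by
    construction.
    """
    nv = len(data.variables)
    if nv < 2:
        raise ValueError("need at least 2 variables")
    if data.n_samples < 10:
        raise ValueError("need at least 10 samples")
    names = data.variables
    idx_of = {n: i for i, n in enumerate(names)}
    cand_names = sparse_candidates(data, cfg.candidates_per_node)
    cand = [
        sorted(idx_of[c] for c in cand_names[names[i]]) for i in range(nv)
    ]
    rng = np.random.default_rng(cfg.seed)

    cache: dict[tuple[int, frozenset[int]], float] = {}

    def fs(child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        if key not in cache:
            cache[key] = family_score(
                data, names[child], [names[p] for p in sorted(parents)], cfg
            )
        return cache[key]

    def climb(graph: _Graph) -> tuple[_Graph, float, list[float]]:
        total = sum(fs(v, frozenset(graph.parents[v])) for v in range(nv))
        trace = [total]
        while True:
            moves = _enumerate_moves(graph, cand, cfg.max_parents, nv)
            rng.shuffle(moves)  # tie-break among equal-delta moves varies
            best_delta, best_move = _EPS, None
            for kind, u, v in moves:
                delta = _move_delta(graph, kind, u, v, fs, cfg.max_parents)
                if delta > best_delta:
                    best_delta, best_move = delta, (kind, u, v)
            if best_move is None:
                return graph, total, trace
            _apply_move(graph, *best_move)
            total += best_delta
            trace.append(total)

    best: tuple[_Graph, float, list[float]] | None = None
    for restart in range(max(1, cfg.restarts)):
        graph = _Graph(nv)
        if restart > 0:
            _random_seed_edges(graph, cand, cfg.max_parents, nv, rng)
        graph, total, trace = climb(graph)
        if best is None or total > best[1] + _EPS:
            best = (graph, total, trace)

    graph, total, trace = best
    edges = [
        (names[u], names[v]) for v in range(nv) for u in sorted(graph.parents[v])
    ]
    model = BayesianNetworkModel(
        nodes=list(names),
        edges=sorted(edges),
        log_score=total,
        config=cfg,
        score_trace=trace,
    )
    compute_edge_strengths(model, data)
    return model


def _enumerate_moves(
    graph: _Graph, cand: list[list[int]], max_parents: int, nv: int
) -> list[tuple[str, int, int]]:
    moves: list[tuple[str, int, int]] = []
    for v in range(nv):
        for u in cand[v]:
            if u == v:
                continue
            if graph.has(u, v):
                moves.append(("del", u, v))
                moves.append(("rev", u, v))
            elif not graph.has(v, u):
                moves.append(("add", u, v))
    return moves


def _move_delta(
    graph: _Graph, kind: str, u: int, v: int, fs, max_parents: int
) -> float:
    pv = frozenset(graph.parents[v])
    if kind == "add":
        if len(pv) >= max_parents or graph.reaches(v, u):
            return -math.inf
        return fs(v, pv | {u}) - fs(v, pv)
    if kind == "del":
        return fs(v, pv - {u}) - fs(v, pv)
    # reverse u->v into v->u
    pu = frozenset(graph.parents[u])
    if len(pu) >= max_parents:
        return -math.inf
    graph.remove(u, v)
    cyclic = graph.reaches(u, v)
    graph.add(u, v)
    if cyclic:
        return -math.inf
    return (
        fs(v, pv - {u})
        - fs(v, pv)
        + fs(u, pu | {v})
        - fs(u, pu)
    )


def _apply_move(graph: _Graph, kind: str, u: int, v: int) -> None:
    if kind == "add":
        graph.add(u, v)
    elif kind == "del":
        graph.remove(u, v)
    else:
        graph.remove(u, v)
        graph.add(v, u)


def _random_seed_edges(
    graph: _Graph, cand: list[list[int]], max_parents: int, nv: int, rng
) -> None:
    pairs = [(u, v) for v in range(nv) for u in cand[v] if u != v]
    rng.shuffle(pairs)
    target = min(nv, len(pairs))
    added = 0
    for u, v in pairs:
        if added >= target:
            break
        if graph.has(u, v) or graph.has(v, u) or len(graph.parents[v]) >= max_parents:
            continue
        if graph.reaches(v, u):
            continue
        graph.add(u, v)
        added += 1


def edge_strength(
    model: BayesianNetworkModel,
    data: DiscretizedDataset,
    edge: tuple[str, str],
    cfg: ScoreConfig | None = None,
) -> float:
    """log10 Bayes factor of the model against the same model minus ``edge``.

    By decomposability this is the child's family-score difference with and
    without the parent, converted from nats to log10.
    """
    if edge not in model.edges:
        raise ValueError(f"edge {edge} not in model")
    cfg = cfg or model.config
    u, v = edge
    parents = model.parents_of(v)
    with_edge = family_score(data, v, parents, cfg)
    without = family_score(data, v, [p for p in parents if p != u], cfg)
    return (with_edge - without) / math.log(10)


def compute_edge_strengths(
    model: BayesianNetworkModel, data: DiscretizedDataset
) -> dict[tuple[str, str], float]:
    """Attach log10 strengths for every edge of the model."""
    model.edge_strengths = {
        e: edge_strength(model, data, e) for e in model.edges
    }
    return model.edge_strengths


def _dot_quote(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def export_dot(model: BayesianNetworkModel, graph_name: str = "bn") -> str:
    """Render the model as a Graphviz digraph.

    Edge labels carry the strength rounded to 2 decimals and pen width grows
    proportionally with strength, so stronger dependencies draw bolder.
    """
    lines = [f"digraph {graph_name} {{"]
    for node in model.nodes:
        lines.append(f"  {_dot_quote(node)};")
    for u, v in model.edges:
        s = model.edge_strengths.get((u, v), 0.0)
        penwidth = max(0.5, 1.0 + 0.35 * s)
        lines.append(
            f"  {_dot_quote(u)} -> {_dot_quote(v)} "
            f'[label="{s:.2f}", penwidth={penwidth:.2f}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
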