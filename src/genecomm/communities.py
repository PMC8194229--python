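"""Cohesive overlapping community detection by greedy growth.

A candidate gene set S on the weighted graph is scored by its cohesiveness

    CS(S) = W_in / (W_in + W_bound + p * |S|)

where W_in is the total weight of edges with both endpoints in S, W_bound the
total weight of boundary edges (exactly one endpoint in S), and p * |S| a
penalty for undetected interactions (p defaults to 0.2). Growth starts from a
seed gene and repeatedly applies the single best strictly-improving move —
adding an external gene incident on a boundary edge, or removing an internal
gene incident on a boundary edge — until no move improves CS; the result is
locally optimal under that move set. Seeds are chosen greedily by maximal
degree among genes not yet covered by any community, so communities may
overlap: coverage governs only seed selection, not membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .data import InvalidInputError

DEFAULT_PENALTY = 0.2


@dataclass(frozen=True)
class Community:
    """A detected gene community with its cohesiveness score."""

    id: int
    genes: frozenset
    cohesiveness: float
    seed_gene: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GrowthTrace:
    """Per-iteration CS values of one greedy growth (strictly increasing)."""

    scores: list[float] = field(default_factory=list)


def _edge_sums(graph: nx.Graph, node_set: set) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u in sorted(node_set):  # fixed order keeps float sums reproducible
        for v, d in graph[u].items():
            w = d["weight"]
            if v in node_set:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(
    graph: nx.Graph,
    node_set,
    penalty: float = DEFAULT_PENALTY,
    literal: bool = False,
) -> float:
    """Cohesiveness CS(S) of a gene set on the weighted graph.

    With ``literal=True`` the ratio is multiplied by |S| (the printed form of
    the score, which leaves the unit interval); the default is the ratio
    itself, the form the greedy growth optimises.
    """
    s = set(node_set)
    if not s:
        raise InvalidInputError("cohesiveness of the empty set is undefined")
    for g in s:
        if g not in graph:
            raise InvalidInputError(f"gene {g!r} is not a graph node")
    if penalty < 0:
        raise InvalidInputError("penalty p must be >= 0")
    w_in, w_bound = _edge_sums(graph, s)
    denom = w_in + w_bound + penalty * len(s)
    if denom == 0:
        return 0.0
    cs = w_in / denom
    return cs * len(s) if literal else cs


class _GrowState:
    """Incremental W_in / W_bound bookkeeping for one greedy growth."""

    def __init__(self, graph: nx.Graph, seed: str, penalty: float):
        self.graph = graph
        self.p = penalty
        self.members: set = {seed}
        self.wdeg = {}  # cache of total weighted degree
        self.w_in = 0.0
        self.w_bound = self._wdeg(seed)

    def _wdeg(self, u) -> float:
        if u not in self.wdeg:
            self.wdeg[u] = sum(d["weight"] for d in self.graph[u].values())
        return self.wdeg[u]

    def _w_to_members(self, u) -> float:
        return sum(
            d["weight"] for v, d in self.graph[u].items() if v in self.members
        )

    def score(self, w_in: float, w_bound: float, size: int) -> float:
        denom = w_in + w_bound + self.p * size
        return 0.0 if denom == 0 else w_in / denom

    def current(self) -> float:
        return self.score(self.w_in, self.w_bound, len(self.members))

    def add_candidates(self):
        """External genes incident on a boundary edge, in sorted order."""
        ext = set()
        for u in self.members:
            ext.update(v for v in self.graph[u] if v not in self.members)
        return sorted(ext)

    def remove_candidates(self):
        """Internal genes incident on a boundary edge, in sorted order."""
        return sorted(
            u
            for u in self.members
            if any(v not in self.members for v in self.graph[u])
        )

    def score_add(self, u) -> float:
        w_us = self._w_to_members(u)
        w_in = self.w_in + w_us
        w_bound = self.w_bound - w_us + (self._wdeg(u) - w_us)
        return self.score(w_in, w_bound, len(self.members) + 1)

    def score_remove(self, u) -> float:
        w_us = self._w_to_members(u)
        w_in = self.w_in - w_us
        w_bound = self.w_bound - (self._wdeg(u) - w_us) + w_us
        return self.score(w_in, w_bound, len(self.members) - 1)

    def apply_add(self, u) -> None:
        w_us = self._w_to_members(u)
        self.w_in += w_us
        self.w_bound += self._wdeg(u) - 2.0 * w_us
        self.members.add(u)

    def apply_remove(self, u) -> None:
        w_us = self._w_to_members(u)
        self.members.remove(u)
        self.w_in -= w_us
        self.w_bound -= self._wdeg(u) - 2.0 * w_us


def grow_community(
    graph: nx.Graph,
    seed_gene: str,
    penalty: float = DEFAULT_PENALTY,
    trace: GrowthTrace | None = None,
) -> frozenset:
    """Grow a locally optimal cohesive community from ``seed_gene``.

    Each iteration scans every boundary-incident addition candidate and then
    every boundary-incident removal candidate (both in lexicographic order),
    keeps the best strictly-improving move seen, applies it, and repeats
    until no move improves CS. Equal-score moves are rejected, so the CS
    trace is strictly increasing and the loop terminates.
    """
    if seed_gene not in graph:
        raise InvalidInputError(f"seed gene {seed_gene!r} is not a graph node")
    state = _GrowState(graph, seed_gene, penalty)
    if trace is not None:
        trace.scores.append(state.current())
    while True:
        best_score = state.current()
        best_move = None  # ("add"/"remove", gene)
        for u in state.add_candidates():
            sc = state.score_add(u)
            if sc > best_score:
                best_score, best_move = sc, ("add", u)
        for u in state.remove_candidates():
            sc = state.score_remove(u)
            if sc > best_score:
                best_score, best_move = sc, ("remove", u)
        if best_move is None:
            return frozenset(state.members)
        kind, gene = best_move
        state.apply_add(gene) if kind == "add" else state.apply_remove(gene)
        if trace is not None:
            trace.scores.append(state.current())


def detect_communities(
    graph: nx.Graph,
    penalty: float = DEFAULT_PENALTY,
    min_size: int = 2,
    weighted_degree: bool = False,
) -> list[Community]:
    """Detect all cohesive communities on the graph.

    Seeds are picked greedily: the not-yet-covered gene of maximal degree
    (incident-edge count by default, weighted degree behind the flag), ties
    broken lexicographically. Members of each grown community are marked
    covered; communities below ``min_size`` are dropped but their members
    still count as considered, so every gene is visited exactly once as a
    potential seed region. Membership may overlap across communities.
    """
    if graph.number_of_nodes() == 0:
        raise InvalidInputError("graph has no nodes")

    def deg(u):
        if weighted_degree:
            return sum(d["weight"] for d in graph[u].values())
        return graph.degree(u)

    covered: set = set()
    out: list[Community] = []
    next_id = 1
    remaining = sorted(graph.nodes)
    while True:
        candidates = [u for u in remaining if u not in covered]
        if not candidates:
            break
        seed = min(candidates, key=lambda u: (-deg(u), u))  # max degree, lex ties
        genes = grow_community(graph, seed, penalty)
        covered |= genes
        covered.add(seed)
        if len(genes) >= min_size:
            out.append(
                Community(
                    id=next_id,
                    genes=genes,
                    cohesiveness=cohesiveness(graph, genes, penalty),
                    seed_gene=seed,
                )
            )
            next_id += 1
    return out


def grow_community_literal(
    graph: nx.Graph, seed_gene: str, penalty: float = DEFAULT_PENALTY
) -> frozenset:
    """Literal, non-incremental transcription of the five growth steps.

    Recomputes CS(S) from scratch for every candidate; used as an
    independent cross-check of :func:`grow_community` in the test-suite and
    acceptance harness. Step 2 sets the incumbent S_{t+1} = S_t; step 3
    replaces it by S_t + {s} whenever that strictly beats the incumbent;
    step 4 likewise for S_t - {s}; step 5 loops until S_{t+1} == S_t.
    """
    if seed_gene not in graph:
        raise InvalidInputError(f"seed gene {seed_gene!r} is not a graph node")

    def cs(nodes) -> float:
        return cohesiveness(graph, nodes, penalty)

    s_t = frozenset({seed_gene})
    while True:
        s_next = s_t
        best = cs(s_next)
        externals = sorted(
            {v for u in s_t for v in graph[u] if v not in s_t}
        )
        for s in externals:
            cand = s_t | {s}
            if cs(cand) > best:
                s_next, best = cand, cs(cand)
        internals = sorted(
            u for u in s_t if any(v not in s_t for v in graph[u])
        )
        for s in internals:
            cand = s_t - {s}
            if cand and cs(cand) > best:
                s_next, best = cand, cs(cand)
        if s_next == s_t:
            return s_t
        s_t = s_next
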