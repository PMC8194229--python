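"""Pairwise overlap scoring and community classification / merging.

Two communities S1, S2 are compared by the overlap score

    omega(S1, S2) = |S1 ∩ S2|^2 / (|S1| * |S2|)

which is 1 iff the sets are equal and 0 iff they are disjoint. Community
pairs with omega at or above a threshold (default 0.8) are merged into one
community (single linkage: connected components of the threshold graph, so a
chain of pairwise overlaps fuses many communities at once, as happens in
practice); merging is iterated to a fixpoint, after which no surviving pair
reaches the threshold. Surviving communities are labelled Independent (IC)
when disjoint from every other community, else Dependent (DC). All overlap
comparisons use exact integer arithmetic, so the IC test omega == 0 and the
merge test omega >= threshold carry no floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx

from .communities import Community, cohesiveness
from .data import InvalidInputError

IC = "IC"
DC = "DC"


def overlap_score(genes_a, genes_b) -> float:
    """Overlap score |A∩B|² / (|A|·|B|) of two non-empty gene sets."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise InvalidInputError("overlap_score requires non-empty gene sets")
    return len(a & b) ** 2 / (len(a) * len(b))


def _overlap_fraction(a: frozenset, b: frozenset) -> Fraction:
    return Fraction(len(a & b) ** 2, len(a) * len(b))


@dataclass
class CommunityCatalog:
    """Post-merge communities with overlaps, IC/DC labels and merge lineage.

    ``merge_lineage`` maps each surviving community id to the list of
    original (pre-merge) community ids it absorbed; unmerged communities
    carry their own singleton lineage.
    """

    communities: list[Community]
    pair_overlaps: dict[frozenset, float]
    labels: dict[int, str]
    merge_lineage: dict[int, list[int]]
    n_before: int = 0

    @property
    def n_after(self) -> int:
        return len(self.communities)

    @property
    def n_independent(self) -> int:
        return sum(1 for v in self.labels.values() if v == IC)

    @property
    def n_dependent(self) -> int:
        return sum(1 for v in self.labels.values() if v == DC)

    @property
    def n_merges(self) -> int:
        """Total reduction in community count: sum over lineages of len-1."""
        return sum(len(src) - 1 for src in self.merge_lineage.values())

    def community(self, cid: int) -> Community:
        for c in self.communities:
            if c.id == cid:
                return c
        raise KeyError(cid)


def classify_and_merge(
    communities: list[Community],
    omega_threshold: float = 0.8,
    graph: nx.Graph | None = None,
) -> CommunityCatalog:
    """Merge high-overlap communities and label the survivors IC / DC.

    Merging is single-linkage on the omega >= threshold graph, iterated to a
    fixpoint; merged gene sets are unions (no re-growth) and their
    cohesiveness is recomputed on ``graph`` when provided. The threshold is
    compared exactly (a decimal threshold like 0.8 is interpreted as the
    rational 8/10), so omega exactly equal to the threshold merges.
    """
    if not (0 < omega_threshold <= 1):
        raise InvalidInputError("omega_threshold must be in (0, 1]")
    thresh = Fraction(str(omega_threshold)) if not isinstance(
        omega_threshold, Fraction
    ) else omega_threshold

    current: list[Community] = list(communities)
    lineage: dict[int, list[int]] = {c.id: [c.id] for c in communities}
    next_id = max((c.id for c in communities), default=0) + 1

    while True:
        merge_graph = nx.Graph()
        merge_graph.add_nodes_from(c.id for c in current)
        by_id = {c.id: c for c in current}
        ids = sorted(by_id)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if _overlap_fraction(by_id[a].genes, by_id[b].genes) >= thresh:
                    merge_graph.add_edge(a, b)
        components = [sorted(comp) for comp in nx.connected_components(merge_graph)]
        if all(len(comp) == 1 for comp in components):
            break
        merged: list[Community] = []
        for comp in sorted(components):
            if len(comp) == 1:
                merged.append(by_id[comp[0]])
                continue
            genes = frozenset().union(*(by_id[cid].genes for cid in comp))
            cs = (
                cohesiveness(graph, genes) if graph is not None else float("nan")
            )
            merged.append(Community(id=next_id, genes=genes, cohesiveness=cs))
            lineage[next_id] = sorted(
                src for cid in comp for src in lineage.pop(cid)
            )
            next_id += 1
        current = merged

    pair_overlaps: dict[frozenset, float] = {}
    exact: dict[frozenset, Fraction] = {}
    ids = sorted(c.id for c in current)
    by_id = {c.id: c for c in current}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            om = _overlap_fraction(by_id[a].genes, by_id[b].genes)
            exact[frozenset((a, b))] = om
            pair_overlaps[frozenset((a, b))] = float(om)

    labels = {}
    for cid in ids:
        others = [exact[frozenset((cid, o))] for o in ids if o != cid]
        labels[cid] = IC if all(om == 0 for om in others) else DC

    return CommunityCatalog(
        communities=current,
        pair_overlaps=pair_overlaps,
        labels=labels,
        merge_lineage=lineage,
        n_before=len(communities),
    )
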