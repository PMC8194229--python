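"""Consensus co-clustering network construction and PPI fusion.

The K binary co-clustering matrices from the Gibbs runs are averaged into a
co-occurrence frequency matrix M (entry M_ij = fraction of runs in which
genes i and j share a cluster). Pairs with M_ij strictly above the frequency
threshold (default 0.4) become weighted edges E_ij = M_ij. STRING-style PPI
confidences P_ij then strengthen the graph: wherever P_ij exceeds the current
weight (including pairs with no consensus edge at all, treated as weight 0)
the edge weight is raised to P_ij. Weights therefore never decrease, and the
final weight of every pair is max(consensus weight if above threshold else 0,
PPI weight if above threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class CoClusterFrequency:
    """Symmetric co-occurrence frequency matrix over an ordered gene list."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.genes)):
            raise InvalidInputError("frequency matrix shape does not match gene list")
        if not np.allclose(v, v.T):
            raise InvalidInputError("frequency matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise InvalidInputError("frequencies must lie in [0, 1]")
        self.values = v


def coclustering_frequency(run_matrices) -> "CoClusterFrequency | np.ndarray":
    """Entrywise mean of K binary co-clustering matrices (same gene order).

    Accepts raw arrays (returns an array) or ``(genes, matrix)`` handling via
    :func:`consensus_frequency` below; kept array-in/array-out so callers can
    feed matrices straight from :func:`gibbs.assignment_to_coclustering`.
    """
    mats = [np.asarray(m) for m in run_matrices]
    if not mats:
        raise InvalidInputError("need at least one run matrix")
    shape = mats[0].shape
    for i, m in enumerate(mats):
        if m.shape != shape:
            raise InvalidInputError(f"run matrix {i} shape {m.shape} != {shape}")
        if not np.array_equal(m, m.T):
            raise InvalidInputError(f"run matrix {i} is not symmetric")
        if not np.isin(m, (0, 1)).all():
            raise InvalidInputError(f"run matrix {i} is not binary")
    return np.mean(mats, axis=0)


def consensus_frequency(assignments, gene_universe) -> CoClusterFrequency:
    """Build the co-occurrence frequency matrix from run partitions."""
    from .gibbs import assignment_to_coclustering

    mats = [assignment_to_coclustering(a, gene_universe) for a in assignments]
    return CoClusterFrequency(list(gene_universe), coclustering_frequency(mats))


def build_weighted_graph(
    freq: CoClusterFrequency, freq_threshold: float = 0.4
) -> nx.Graph:
    """Threshold the frequency matrix into a weighted gene graph.

    An edge (i, j) exists iff M_ij > freq_threshold (strict), with weight
    M_ij and provenance ``"consensus"``. Every gene stays a node even if
    isolated, so the universe is preserved for later stages.
    """
    if not (0 <= freq_threshold < 1):
        raise InvalidInputError("freq_threshold must be in [0, 1)")
    g = nx.Graph()
    g.add_nodes_from(freq.genes)
    vals = freq.values
    idx_i, idx_j = np.nonzero(np.triu(vals, k=1) > freq_threshold)
    for i, j in zip(idx_i, idx_j):
        g.add_edge(
            freq.genes[i], freq.genes[j], weight=float(vals[i, j]), provenance="consensus"
        )
    return g


def read_string_edges(
    path, score_threshold: float = 0.4, scale: str | None = None
) -> dict[frozenset, float]:
    """Read a STRING-like edge list ``protein_a protein_b combined_score``.

    Both common score dialects are accepted: the 0-1000 integer scale (divided
    by 1000) and the already-normalised [0, 1] scale. With ``scale=None`` the
    dialect is auto-detected; an ambiguous mix raises and demands an explicit
    ``scale`` of ``"milli"`` or ``"unit"``. Pairs are kept where the
    normalised score is strictly above ``score_threshold``; duplicates keep
    the maximum score.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise InvalidInputError(f"line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise InvalidInputError(
                    f"line {lineno}: non-numeric score {parts[2]!r}"
                ) from None
            if score < 0:
                raise InvalidInputError(f"line {lineno}: negative score {score}")
            rows.append((parts[0], parts[1], score))

    if not rows:
        return {}
    scores = np.array([r[2] for r in rows])
    if scale is None:
        if scores.max() <= 1.0:
            scale = "unit"
        elif np.allclose(scores, np.round(scores)):
            scale = "milli"
        else:
            raise InvalidInputError(
                "cannot auto-detect STRING score scale (non-integer values above 1 "
                "mixed with values <= 1); pass scale='milli' or scale='unit'"
            )
    if scale not in ("milli", "unit"):
        raise InvalidInputError(f"unknown scale {scale!r}")
    div = 1000.0 if scale == "milli" else 1.0

    out: dict[frozenset, float] = {}
    for a, b, score in rows:
        if a == b:
            continue
        w = score / div
        if w > score_threshold:
            key = frozenset((a, b))
            out[key] = max(out.get(key, 0.0), w)
    return out


def integrate_ppi(graph: nx.Graph, ppi: dict[frozenset, float]) -> nx.Graph:
    """Fuse PPI confidences into the consensus graph (weights never decrease).

    For each PPI pair whose genes are both graph nodes: an existing edge with
    weight below P_ij is raised to P_ij (provenance ``"fused"``); a missing
    edge is created with weight P_ij (provenance ``"ppi"``). Pairs touching
    unknown genes are skipped and counted in a log summary.
    """
    g = graph.copy()
    skipped = 0
    for pair, w in sorted(ppi.items(), key=lambda kv: sorted(kv[0])):
        if not (0 < w <= 1):
            raise InvalidInputError(f"PPI weight {w} outside (0, 1]")
        nodes = sorted(pair)
        if len(nodes) != 2:
            continue
        a, b = nodes
        if a not in g or b not in g:
            skipped += 1
            continue
        if g.has_edge(a, b):
            if g[a][b]["weight"] < w:
                g[a][b]["weight"] = w
                g[a][b]["provenance"] = "fused"
        else:
            g.add_edge(a, b, weight=w, provenance="ppi")
    if skipped:
        logger.info("integrate_ppi: skipped %d PPI pairs with unknown genes", skipped)
    return g


def graph_to_tsv(graph: nx.Graph, path) -> None:
    rows = [
        {"gene_a": min(a, b), "gene_b": max(a, b),
         "weight": d["weight"], "provenance": d.get("provenance", "")}
        for a, b, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "provenance"])
    df = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
    with open(path, "w") as fh:
        fh.write("# isolated: " + ",".join(isolated) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def graph_from_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# isolated:"):
            names = first.split(":", 1)[1].strip()
            if names:
                g.add_nodes_from(names.split(","))
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    for _, r in df.iterrows():
        g.add_edge(
            str(r["gene_a"]), str(r["gene_b"]),
            weight=float(r["weight"]), provenance=str(r.get("provenance", "")),
        )
    return g
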