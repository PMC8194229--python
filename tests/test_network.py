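"""Consensus frequency matrix, graph thresholding, STRING parsing, fusion."""

import numpy as np
import pytest

from genecomm.data import InvalidInputError
from genecomm.gibbs import ClusterAssignment, assignment_to_coclustering
from genecomm.network import (
    CoClusterFrequency,
    build_weighted_graph,
    coclustering_frequency,
    consensus_frequency,
    graph_from_tsv,
    graph_to_tsv,
    integrate_ppi,
    read_string_edges,
)


def _pair_matrix(together: bool):
    m = np.eye(2, dtype=int)
    if together:
        m[:] = 1
    return m


def test_frequency_is_mean_of_indicators():
    mats = [_pair_matrix(t) for t in (1, 1, 1, 0, 0)]
    freq = coclustering_frequency(mats)
    assert freq[0, 1] == pytest.approx(0.6)
    assert coclustering_frequency([_pair_matrix(1)] * 4)[0, 1] == 1.0
    single = _pair_matrix(1)
    assert np.array_equal(coclustering_frequency([single]), single)


def test_frequency_entries_multiples_of_one_over_k():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(8)]
    assignments = []
    for k in range(1, 6):
        labels = rng.integers(1, 4, size=8)
        # renumber contiguously
        uniq = {v: i + 1 for i, v in enumerate(dict.fromkeys(labels))}
        assignments.append(
            ClusterAssignment(k, {g: uniq[l] for g, l in zip(genes, labels)}, len(uniq))
        )
    freq = consensus_frequency(assignments, genes)
    assert np.allclose(freq.values * 5, np.round(freq.values * 5))
    assert np.array_equal(freq.values, freq.values.T)
    assert (np.diag(freq.values) == 1).all()


def test_frequency_rejects_bad_inputs():
    with pytest.raises(InvalidInputError):
        coclustering_frequency([])
    with pytest.raises(InvalidInputError):
        coclustering_frequency([np.eye(2), np.eye(3)])
    with pytest.raises(InvalidInputError):
        coclustering_frequency([np.array([[1, 1], [0, 1]])])


def test_graph_thresholding_is_strict():
    genes = ["A", "B", "C"]
    vals = np.array([[1.0, 0.6, 0.4], [0.6, 1.0, 0.0], [0.4, 0.0, 1.0]])
    g = build_weighted_graph(CoClusterFrequency(genes, vals), 0.4)
    assert g.has_edge("A", "B") and g["A"]["B"]["weight"] == pytest.approx(0.6)
    assert not g.has_edge("A", "C")  # 0.4 is not > 0.4
    assert set(g.nodes) == set(genes)  # isolated genes kept


def test_edgeless_graph_keeps_all_nodes():
    genes = ["A", "B"]
    g = build_weighted_graph(CoClusterFrequency(genes, np.eye(2)), 0.4)
    assert g.number_of_edges() == 0 and set(g.nodes) == {"A", "B"}


def test_string_reader_milli_scale(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("protein1 protein2 combined_score\nA B 700\nA C 400\nB A 900\n")
    edges = read_string_edges(p, 0.4)
    assert edges == {frozenset(("A", "B")): 0.9}  # 0.7 and 0.9 duplicate -> max; 400 dropped


def test_string_reader_unit_scale_and_duplicates(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("A B 0.5\nB A 0.9\nC D 0.41\n")
    edges = read_string_edges(p, 0.4)
    assert edges[frozenset(("A", "B"))] == 0.9
    assert edges[frozenset(("C", "D"))] == pytest.approx(0.41)


def test_string_reader_malformed_line_numbered(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("A B 700\nA C\n")
    with pytest.raises(InvalidInputError, match="line 2"):
        read_string_edges(p)


def test_string_reader_ambiguous_scale_demands_flag(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("A B 0.5\nA C 700.5\n")
    with pytest.raises(InvalidInputError, match="scale"):
        read_string_edges(p)
    assert read_string_edges(p, scale="milli") == {frozenset(("A", "C")): pytest.approx(0.7005)}


def test_ppi_fusion_update_rules():
    genes = ["A", "B", "C", "D"]
    vals = np.eye(4)
    vals[0, 1] = vals[1, 0] = 0.6
    vals[0, 2] = vals[2, 0] = 0.8
    g = build_weighted_graph(CoClusterFrequency(genes, vals), 0.4)
    ppi = {
        frozenset(("A", "B")): 0.7,   # raises 0.6 -> 0.7
        frozenset(("A", "C")): 0.5,   # 0.8 stays
        frozenset(("B", "D")): 0.9,   # creates new edge
        frozenset(("A", "Z")): 0.9,   # unknown gene, skipped
    }
    fused = integrate_ppi(g, ppi)
    assert fused["A"]["B"]["weight"] == 0.7 and fused["A"]["B"]["provenance"] == "fused"
    assert fused["A"]["C"]["weight"] == 0.8 and fused["A"]["C"]["provenance"] == "consensus"
    assert fused["B"]["D"]["weight"] == 0.9 and fused["B"]["D"]["provenance"] == "ppi"
    assert "Z" not in fused


def test_ppi_weight_range_validated(triangle_graph):
    with pytest.raises(InvalidInputError):
        integrate_ppi(triangle_graph, {frozenset(("A", "B")): 1.5})


def test_fused_weight_equals_bruteforce_max_rule():
    """Final weight of every pair = max(consensus freq if > 0.4 else 0,
    PPI weight), recomputed independently from the raw run matrices."""
    rng = np.random.default_rng(21)
    genes = [f"g{i}" for i in range(10)]
    for rep in range(10):
        assignments = []
        for k in range(1, 6):
            labels = rng.integers(1, 4, size=10)
            uniq = {v: i + 1 for i, v in enumerate(dict.fromkeys(labels))}
            assignments.append(
                ClusterAssignment(k, {g: uniq[l] for g, l in zip(genes, labels)}, len(uniq))
            )
        ppi = {}
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.3:
                    ppi[frozenset((genes[i], genes[j]))] = float(rng.uniform(0.41, 1.0))
        freq = consensus_frequency(assignments, genes)
        fused = integrate_ppi(build_weighted_graph(freq, 0.4), ppi)
        mats = [assignment_to_coclustering(a, genes) for a in assignments]
        mean = np.mean(mats, axis=0)
        for i in range(10):
            for j in range(i + 1, 10):
                consensus = mean[i, j] if mean[i, j] > 0.4 else 0.0
                expected = max(consensus, ppi.get(frozenset((genes[i], genes[j])), 0.0))
                got = (
                    fused[genes[i]][genes[j]]["weight"]
                    if fused.has_edge(genes[i], genes[j])
                    else 0.0
                )
                assert got == pytest.approx(expected, abs=1e-12)


def test_graph_tsv_round_trip(tmp_path, triangle_graph):
    triangle_graph.add_node("LONER")
    for _, _, d in triangle_graph.edges(data=True):
        d["provenance"] = "consensus"
    path = tmp_path / "graph.tsv"
    graph_to_tsv(triangle_graph, path)
    back = graph_from_tsv(path)
    assert set(back.nodes) == set(triangle_graph.nodes)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, triangle_graph.edges))
    assert back["A"]["B"]["weight"] == triangle_graph["A"]["B"]["weight"]
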