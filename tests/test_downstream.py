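"""Survival splits, driver ranking, enrichment, subtype tests, per-gene AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import chi2

from genecomm.communities import Community
from genecomm.data import ClinicalTable, InvalidInputError, MutationTable
from genecomm.downstream import (
    candidate_drivers,
    gene_classification_auc,
    geneset_enrichment,
    rank_drivers,
    regulation_score,
    subtype_mutation_enrichment,
    survival_split_test,
)
from genecomm.simulate import generate_expression, generate_survival, make_planted_truth

from conftest import make_expression, unit_clique


def _comm(genes):
    return Community(id=1, genes=frozenset(genes), cohesiveness=0.5)


@pytest.fixture(scope="module")
def planted_survival():
    truth = make_planted_truth(1, 10, 0, 0)
    comm = _comm(truth.communities[1])
    expr = generate_expression(truth, n_samples_per_class=100, seed=50)
    clin = generate_survival(expr, comm, hazard_ratio=3.0, seed=60, samples="all")
    return comm, expr, clin


def test_planted_hazard_detected(planted_survival):
    comm, expr, clin = planted_survival
    res = survival_split_test(comm, expr, clin)
    assert res.logrank_p <= 0.01
    assert res.cox_hazard_ratio > 1.5


def test_short_survivors_excluded(planted_survival):
    comm, expr, clin = planted_survival
    t = clin.table.copy()
    short = t.index[0]
    t.loc[short, "os_days"] = 10
    res = survival_split_test(comm, expr, ClinicalTable(t))
    assert short not in res.group_labels.index


def test_km_curves_cover_both_groups(planted_survival):
    comm, expr, clin = planted_survival
    res = survival_split_test(comm, expr, clin)
    assert set(res.km_curves) == {"high", "low"}
    for curve in res.km_curves.values():
        surv = curve["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all() and surv[0] == 1.0


def test_degenerate_split_rejected():
    vals = np.ones((3, 20))
    expr = make_expression(vals, n_tumor=10)
    clin = ClinicalTable(
        pd.DataFrame(
            {"os_days": np.arange(100, 120), "event": 1},
            index=pd.Index(expr.sample_ids, name="sample"),
        )
    )
    with pytest.raises(InvalidInputError, match="degenerate"):
        survival_split_test(_comm(expr.gene_ids), expr, clin)


def test_logrank_matches_hand_lifetable():
    """Two groups of four patients, no censoring: the log-rank statistic
    (O-E)^2/V from the hand-computed lifetable gives the same p as the
    package path."""
    rng_vals = np.array(
        [[10.0, 9.0, 8.0, 11.0, 10.5, 1.0, 2.0, 0.5, 1.5, 1.2]] * 2
    )  # two genes, high group = first five samples
    expr = make_expression(rng_vals, n_tumor=5)
    times = np.array([40, 55, 70, 90, 120, 150, 200, 260, 310, 400])
    clin = ClinicalTable(
        pd.DataFrame(
            {"os_days": times, "event": 1},
            index=pd.Index(expr.sample_ids, name="sample"),
        )
    )
    res = survival_split_test(_comm(expr.gene_ids), expr, clin, fit_cox=False)

    # hand lifetable over distinct event times
    high = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    at_risk = np.ones(10, dtype=bool)
    for t in np.sort(times):
        d = times == t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d_tot = d.sum()
        o_minus_e += (d & high).sum() - d_tot * n1 / n
        if n > 1:
            var += d_tot * (n1 / n) * (1 - n1 / n) * (n - d_tot) / (n - 1)
        at_risk &= ~d
    stat = o_minus_e**2 / var
    p_hand = chi2.sf(stat, df=1)
    assert res.logrank_p == pytest.approx(p_hand, rel=1e-6)


def test_candidate_driver_threshold_is_strict():
    vals = pd.DataFrame(
        {
            "s1": [1, 1, 1, 0],
            "s2": [1, 0, 1, 0],
            "s3": [1, 1, 0, 0],
            "s4": [0, 0, 0, 0],
            "s5": [1, 1, 1, 0],
        },
        index=["A", "B", "C", "D"],
    )
    mt = MutationTable(vals)
    assert mt.frequencies["A"] == pytest.approx(0.8)
    assert mt.frequencies["B"] == pytest.approx(0.6)
    assert candidate_drivers(mt, 0.6) == ["A"]  # exactly 0.6 excluded
    assert candidate_drivers(MutationTable(vals * 0), 0.6) == []


def test_rank_drivers_star_hub_first():
    g = unit_clique([])
    for leaf in ("L1", "L2", "L3", "L4"):
        g.add_edge("HUB", leaf, weight=1.0)
    comm = _comm({"HUB", "L1", "L2", "L3", "L4"})
    scores = regulation_score(comm, g)
    assert scores["HUB"] == 4.0 and scores["L1"] == 1.0
    ranked = rank_drivers(comm, g, ["HUB", "L1", "L2", "L3", "L4"], top_fraction=0.2)
    assert ranked == ["HUB"]


def test_rank_drivers_minimum_one_and_empty():
    g = unit_clique(["A", "B", "C", "D", "E"])
    comm = _comm({"A", "B", "C", "D", "E"})
    assert rank_drivers(comm, g, ["C"], top_fraction=0.01) == ["C"]
    assert rank_drivers(comm, g, ["Z"], top_fraction=0.01) == []


def test_enrichment_fully_recovered_term_exact_p():
    background = {f"g{i}" for i in range(20)}
    term = {f"g{i}" for i in range(5)}
    res = geneset_enrichment(term, {"T": term}, background)
    expected = 1 / comb(20, 5)
    assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-10)
    assert res.loc[0, "corrected_p"] == pytest.approx(expected, abs=1e-10)  # m=1
    assert bool(res.loc[0, "significant"])


def test_enrichment_tail_matches_enumeration():
    """Hypergeometric upper tail agrees with exhaustive enumeration of all
    query draws from a small background."""
    background = [f"g{i}" for i in range(12)]
    term = set(background[:4])
    query = set(background[:3]) | {background[6], background[7]}  # overlap 3
    res = geneset_enrichment(query, {"T": term}, set(background))
    k_obs = len(query & term)
    total = 0
    hits = 0
    for combo in itertools.combinations(background, len(query)):
        total += 1
        if len(set(combo) & term) >= k_obs:
            hits += 1
    assert res.loc[0, "p"] == pytest.approx(hits / total, rel=1e-10)


def test_enrichment_disjoint_query_not_flagged():
    background = {f"g{i}" for i in range(20)}
    res = geneset_enrichment(
        {"g10", "g11"}, {"T": {"g0", "g1", "g2"}}, background
    )
    assert not res["significant"].any()


def test_enrichment_validates_inputs():
    with pytest.raises(InvalidInputError):
        geneset_enrichment({"a"}, {}, set())
    with pytest.raises(InvalidInputError):
        geneset_enrichment({"z"}, {"T": {"a"}}, {"a", "b"})


def test_subtype_fisher_extreme_table_matches_enumeration():
    """[[10,0],[0,10]]: compare the two-sided Fisher p with exhaustive
    enumeration of all 2x2 tables with the same margins."""
    # samples 0-9 mutated (subtype A), 10-19 not (subtype B)
    vals = pd.DataFrame(
        [[1] * 10 + [0] * 10], index=["X"], columns=[f"s{i}" for i in range(20)]
    )
    mut = MutationTable(vals)
    sub = pd.Series(["A"] * 10 + ["B"] * 10, index=vals.columns)
    res = subtype_mutation_enrichment(_comm({"X"}), mut, sub)
    pa = float(res.set_index("subtype").loc["A", "fisher_p"])

    # enumeration: P(X = k) hypergeometric over tables with margins (10,10,10)
    probs = {
        k: comb(10, k) * comb(10, 10 - k) / comb(20, 10) for k in range(0, 11)
    }
    p_obs = probs[10]
    p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    assert pa == pytest.approx(p_two, rel=1e-9)
    assert pa == pytest.approx(1.0825e-5, rel=1e-3)


def test_subtype_uniform_mutation_gives_p_one():
    vals = pd.DataFrame(
        [[1] * 20], index=["X"], columns=[f"s{i}" for i in range(20)]
    )
    sub = pd.Series(["A"] * 10 + ["B"] * 10, index=vals.columns)
    res = subtype_mutation_enrichment(_comm({"X"}), MutationTable(vals), sub)
    assert (res["fisher_p"] == 1.0).all()


def test_subtype_absent_gene_gives_p_one():
    vals = pd.DataFrame(
        [[1] * 10 + [0] * 10], index=["Y"], columns=[f"s{i}" for i in range(20)]
    )
    sub = pd.Series(["A"] * 10 + ["B"] * 10, index=vals.columns)
    res = subtype_mutation_enrichment(_comm({"NOT_PRESENT"}), MutationTable(vals), sub)
    assert (res["fisher_p"] == 1.0).all()


def test_subtype_needs_two_groups():
    vals = pd.DataFrame([[1, 0]], index=["X"], columns=["s1", "s2"])
    sub = pd.Series(["A", "A"], index=["s1", "s2"])
    with pytest.raises(InvalidInputError):
        subtype_mutation_enrichment(_comm({"X"}), MutationTable(vals), sub)


def test_auc_perfectly_separated_gene():
    vals = np.r_[np.linspace(5, 6, 30), np.linspace(1, 2, 30)][None, :]
    expr = make_expression(vals, n_tumor=30)
    res = gene_classification_auc("G000", expr, folds=10, seed=0)
    assert res.auc == 1.0


def test_auc_null_gene_near_half():
    rng = np.random.default_rng(8)
    aucs = []
    for s in range(3):
        vals = rng.standard_normal((1, 200))
        expr = make_expression(vals, n_tumor=100)
        aucs.append(gene_classification_auc("G000", expr, folds=10, seed=s).auc)
    assert 0.4 <= np.mean(aucs) <= 0.6


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(13)
    vals = rng.standard_normal((1, 80)) + np.r_[[0.8] * 40, [0.0] * 40][None, :]
    expr = make_expression(vals, n_tumor=40)
    base = gene_classification_auc("G000", expr, folds=10, seed=4).auc
    for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
        expr2 = make_expression(f(vals), n_tumor=40)
        assert gene_classification_auc("G000", expr2, folds=10, seed=4).auc == pytest.approx(
            base, abs=0.05
        )


def test_auc_fold_structure():
    rng = np.random.default_rng(21)
    expr = make_expression(rng.standard_normal((1, 60)), n_tumor=30)
    res = gene_classification_auc("G000", expr, folds=10, seed=1)
    assert res.fold_assignments.nunique() == 10
    assert len(res.fold_assignments) == 60  # each sample out-of-fold once


def test_auc_small_class_suggests_smaller_k():
    rng = np.random.default_rng(22)
    expr = make_expression(rng.standard_normal((1, 14)), n_tumor=7)
    with pytest.raises(InvalidInputError, match="smaller k"):
        gene_classification_auc("G000", expr, folds=10, seed=0)


def test_auc_holdout_mode_runs():
    vals = np.r_[np.linspace(5, 6, 40), np.linspace(1, 2, 40)][None, :]
    expr = make_expression(vals, n_tumor=40)
    res = gene_classification_auc("G000", expr, mode="holdout", seed=0)
    assert res.auc == 1.0
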