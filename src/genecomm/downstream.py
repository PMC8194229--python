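"""Validation battery for detected communities.

Covers: survival stratification of patients by community expression score
(Kaplan-Meier / log-rank / Cox), driver-gene candidacy by mutation frequency
and ranking by within-community regulation score, hypergeometric gene-set
enrichment with BH correction, per-subtype Fisher mutation enrichment, and
per-gene tumor/normal classification AUC with a cross-validated RBF support
vector machine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import fisher_exact, hypergeom
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .communities import Community
from .data import TUMOR, ClinicalTable, ExpressionMatrix, InvalidInputError, MutationTable

MIN_OS_DAYS = 30


@dataclass
class SurvivalResult:
    group_labels: pd.Series          # "high" / "low" per eligible patient
    logrank_p: float
    cox_hazard_ratio: float
    cox_p: float
    km_curves: dict[str, pd.DataFrame]


def community_score(community, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample mean expression over the community's genes."""
    genes = community.genes if isinstance(community, Community) else set(community)
    present = [g for g in expr.gene_ids if g in genes]
    if len(present) < 2:
        raise InvalidInputError(
            f"need >= 2 community genes in the expression matrix, got {len(present)}"
        )
    return expr.values.loc[present].mean(axis=0)


def survival_split_test(
    community,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    min_days: float = MIN_OS_DAYS,
    split: str = "mean",
    fit_cox: bool = True,
) -> SurvivalResult:
    """Dichotomize patients by community expression and test survival.

    Patients need at least ``min_days`` of overall survival to enter. Each
    patient's community score is the mean expression over community genes;
    the cohort splits into high/low at the cohort mean of that score (median
    behind ``split="median"``). Group difference is tested by the log-rank
    statistic and a Cox proportional-hazards fit on the binary group.
    """
    score = community_score(community, expr)
    elig = clinical.eligible(min_days)
    common = [s for s in elig.index if s in score.index]
    if len(common) < 10:
        raise InvalidInputError(
            f"need >= 10 eligible patients with expression, got {len(common)}"
        )
    score = score[common]
    elig = elig.loc[common]
    center = score.mean() if split == "mean" else score.median()
    if score.nunique() == 1:
        raise InvalidInputError("degenerate split: all community scores identical")
    high = score > center
    if high.sum() < 2 or (~high).sum() < 2:
        raise InvalidInputError("fewer than 2 eligible patients in a group")

    groups = pd.Series(np.where(high, "high", "low"), index=score.index, name="group")
    t, e = elig["os_days"], elig["event"]
    lr = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])

    if fit_cox:
        cox_df = pd.DataFrame({"os_days": t, "event": e, "high": high.astype(int)})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(cox_df, duration_col="os_days", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        cox_p = float(cph.summary.loc["high", "p"])
    else:
        hr = float("nan")
        cox_p = float("nan")

    km_curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask], label=name)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        km_curves[name] = curve

    return SurvivalResult(
        group_labels=groups,
        logrank_p=float(lr.p_value),
        cox_hazard_ratio=hr,
        cox_p=cox_p,
        km_curves=km_curves,
    )


def candidate_drivers(
    mutations: MutationTable, freq_threshold: float = 0.6
) -> list[str]:
    """Genes whose mutation frequency is strictly above the threshold,
    sorted by descending frequency then gene id."""
    fre = mutations.frequencies
    hits = fre[fre > freq_threshold]
    return sorted(hits.index, key=lambda g: (-hits[g], g))


def regulation_score(community, graph) -> pd.Series:
    """Within-community weighted degree of each community gene: the sum of
    incident edge weights to other members, the graph-native notion of
    regulatory centrality used to rank drivers."""
    genes = community.genes if isinstance(community, Community) else set(community)
    scores = {}
    for g in genes:
        if g in graph:
            scores[g] = sum(
                d["weight"] for v, d in graph[g].items() if v in genes
            )
        else:
            scores[g] = 0.0
    return pd.Series(scores).sort_index()


def rank_drivers(
    community,
    graph,
    candidates,
    top_fraction: float = 0.01,
) -> list[str]:
    """Rank candidate drivers inside a community by regulation score.

    Returns the top ``ceil(top_fraction * |community|)`` candidates (at least
    one whenever any candidate lies in the community), ranked by descending
    within-community weighted degree with lexicographic tie-break.
    """
    if not (0 < top_fraction <= 1):
        raise InvalidInputError("top_fraction must be in (0, 1]")
    genes = community.genes if isinstance(community, Community) else set(community)
    pool = sorted(genes & set(candidates))
    if not pool:
        return []
    scores = regulation_score(community, graph)
    ranked = sorted(pool, key=lambda g: (-scores[g], g))
    k = max(1, math.ceil(top_fraction * len(genes)))
    return ranked[:k]


def geneset_enrichment(
    genes,
    collection: dict[str, set],
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each gene set.

    Each term is intersected with the background before testing; the p-value
    is the upper tail P(X >= k) of the hypergeometric for the observed
    overlap k. BH correction runs across terms; ``significant`` flags rows
    with corrected p below ``alpha`` (strict).
    """
    bg = set(background)
    if not bg:
        raise InvalidInputError("empty background")
    query = set(genes)
    if not query <= bg:
        raise InvalidInputError("query genes must be a subset of the background")
    rows = []
    for term in sorted(collection):
        term_genes = collection[term] & bg
        k = len(query & term_genes)
        p = float(hypergeom.sf(k - 1, len(bg), len(term_genes), len(query)))
        rows.append({"term": term, "overlap": k, "term_size": len(term_genes), "p": p})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(df):
        df["corrected_p"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["corrected_p"] < alpha
    else:
        df["corrected_p"] = []
        df["significant"] = []
    return df


def subtype_mutation_enrichment(
    community,
    mutations: MutationTable,
    subtypes: pd.Series,
) -> pd.DataFrame:
    """Fisher's exact association of community mutation with each subtype.

    A sample counts as mutated when it carries a mutation in at least one
    community gene. For each subtype the 2x2 table (mutated x in-subtype)
    is tested two-sided; subtypes with zero samples are skipped with a
    warning.
    """
    if subtypes.nunique() < 2:
        raise InvalidInputError("need >= 2 subtypes")
    genes = community.genes if isinstance(community, Community) else set(community)
    present = [g for g in mutations.values.index if g in genes]
    samples = [s for s in subtypes.index if s in mutations.values.columns]
    if not samples:
        raise InvalidInputError("no overlap between subtype samples and mutation table")
    if present:
        mutated = mutations.values.loc[present, samples].any(axis=0)
    else:
        mutated = pd.Series(False, index=samples)
    sub = subtypes[samples]
    rows = []
    for label in sorted(sub.unique()):
        in_sub = sub == label
        if in_sub.sum() == 0:
            warnings.warn(f"subtype {label!r} has zero samples; skipped", stacklevel=2)
            continue
        table = [
            [int((mutated & in_sub).sum()), int((mutated & ~in_sub).sum())],
            [int((~mutated & in_sub).sum()), int((~mutated & ~in_sub).sum())],
        ]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append({"subtype": label, "odds_ratio": float(odds), "fisher_p": float(p)})
    return pd.DataFrame(rows, columns=["subtype", "odds_ratio", "fisher_p"])


@dataclass
class AucResult:
    auc: float
    roc_points: pd.DataFrame       # fpr, tpr, threshold
    fold_assignments: pd.Series    # fold index per sample (CV mode)


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF gamma = 1 / (2 sigma^2) with sigma the median pairwise distance."""
    d = np.abs(x[:, None] - x[None, :])
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med == 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def gene_classification_auc(
    gene: str,
    expr: ExpressionMatrix,
    folds: int = 10,
    cost: float = 10.0,
    seed: int = 0,
    mode: str = "cv",
    holdout_fraction: float = 0.2,
) -> AucResult:
    """Tumor-vs-normal classification AUC from one gene's expression.

    A soft-margin SVM with Gaussian kernel (cost C, default 10; kernel width
    from the median heuristic on the training values) is evaluated by
    stratified k-fold cross-validation (default k=10) with out-of-fold
    decision scores pooled into a single ROC. ``mode="holdout"`` instead
    trains on a stratified (1 - holdout_fraction) split and scores the rest.
    """
    if gene not in expr.values.index:
        raise InvalidInputError(f"gene {gene!r} not in expression matrix")
    x = expr.values.loc[gene].to_numpy(dtype=float)
    y = (expr.sample_class == TUMOR).to_numpy().astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())

    if mode == "cv":
        if min(n_pos, n_neg) < folds:
            raise InvalidInputError(
                f"each class needs >= {folds} samples for {folds}-fold CV "
                f"(got {n_pos} tumor / {n_neg} normal); use a smaller k"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = np.empty_like(x)
        fold_of = np.empty(len(x), dtype=int)
        for f, (train, test) in enumerate(skf.split(x[:, None], y)):
            clf = SVC(C=cost, kernel="rbf", gamma=_median_heuristic_gamma(x[train]))
            clf.fit(x[train, None], y[train])
            scores[test] = clf.decision_function(x[test, None])
            fold_of[test] = f
        fold_assignments = pd.Series(fold_of, index=expr.sample_ids, name="fold")
    elif mode == "holdout":
        idx = np.arange(len(x))
        train, test = train_test_split(
            idx, test_size=holdout_fraction, stratify=y, random_state=seed
        )
        clf = SVC(C=cost, kernel="rbf", gamma=_median_heuristic_gamma(x[train]))
        clf.fit(x[train, None], y[train])
        scores = np.full(len(x), np.nan)
        scores[test] = clf.decision_function(x[test, None])
        y = y[test]
        scores = scores[test]
        fold_assignments = pd.Series(dtype=int)
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return AucResult(auc=auc, roc_points=roc, fold_assignments=fold_assignments)
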