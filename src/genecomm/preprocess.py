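"""Candidate-gene selection by tumor/normal distributional difference.

Genes are scored by the 1-D earth mover's distance (EMD) between their
empirical expression distributions in the two sample classes. Significance
comes from a class-label permutation null (the labels are exchangeable under
the null of no differential expression), with Benjamini-Hochberg control
across genes; genes with q < 0.1 form the working universe for all later
stages. The same filter applies unchanged to copy-number matrices, and the
expression- and CNV-selected sets are combined by union.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from statsmodels.stats.multitest import multipletests

from .data import NORMAL, TUMOR, ExpressionMatrix, InvalidInputError


def emd_distance(values_a, values_b) -> float:
    """1-D earth mover's distance between two empirical distributions.

    Both samples carry total mass 1, so this is the L1 distance between the
    two empirical CDFs. Symmetric; zero iff the empirical distributions are
    identical.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("emd_distance requires non-empty samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidInputError("emd_distance requires finite values")
    return float(wasserstein_distance(a, b))


def _emd_by_gene(sorted_vals: np.ndarray, order: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """EMD per gene between columns where ``mask`` is True and the rest.

    ``sorted_vals`` is the genes x samples matrix with each row sorted
    ascending, ``order`` the argsort indices producing it. Works for any
    class sizes; vectorised across genes so the permutation null stays cheap.
    """
    n_a = int(mask.sum())
    n_b = mask.size - n_a
    in_a = mask[order]  # genes x samples, class membership in sorted order
    cum_a = np.cumsum(in_a, axis=1)[:, :-1] / n_a
    cum_b = (np.arange(1, mask.size)[None, :] - cum_a * n_a) / n_b
    dx = np.diff(sorted_vals, axis=1)
    return (np.abs(cum_a - cum_b) * dx).sum(axis=1)


def differential_gene_filter(
    matrix: ExpressionMatrix,
    q_threshold: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-EMD differential filter with BH correction.

    Returns a DataFrame indexed by gene id with columns ``emd_stat``,
    ``p_value``, ``q_value`` and ``selected`` (q < q_threshold, strict).
    p-values use the add-one rule p = (1 + #{perm >= obs}) / (1 + B) so they
    are never zero.
    """
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    tumor_cols = matrix.class_columns(TUMOR)
    normal_cols = matrix.class_columns(NORMAL)
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise InvalidInputError(
            "differential filtering needs both classes with >= 2 samples "
            f"(got {len(tumor_cols)} tumor, {len(normal_cols)} normal)"
        )

    vals = matrix.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=1)
    mask = (matrix.sample_class == TUMOR).to_numpy()

    observed = _emd_by_gene(sorted_vals, order, mask)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.n_genes, dtype=np.int64)
    perm_mask = mask.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm_mask)
        exceed += _emd_by_gene(sorted_vals, order, perm_mask) >= observed - 1e-15
    p = (1 + exceed) / (1 + n_permutations)
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "emd_stat": observed,
            "p_value": p,
            "q_value": q,
            "selected": q < q_threshold,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def combine_gene_sets(expr_selected, cnv_selected) -> list[str]:
    """Union of the expression- and CNV-selected gene sets, sorted."""
    return sorted(set(expr_selected) | set(cnv_selected))
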