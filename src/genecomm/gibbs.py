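"""Model-based stochastic gene clustering via a collapsed CRP Gibbs sampler.

Each run partitions the genes of an expression matrix under a Dirichlet
process (Chinese restaurant process) prior with a conjugate Normal-Gamma
observation model per cluster and per sample: genes in a cluster share a
per-sample mean/precision, so the collapsed predictive for a gene row is a
product of Student-t densities over samples. The number of clusters is
inferred, not fixed. Several independent runs (default 5) seed the consensus
co-clustering network; the consensus across runs, not any single partition,
is the noise-control mechanism, so each run simply reports its final-sweep
partition.

Genes are scanned in lexicographic id order inside the sampler, which makes
runs invariant to the row order of the input matrix under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import ExpressionMatrix, InvalidInputError


@dataclass
class ClusterAssignment:
    """One run's gene partition: gene id -> cluster index in 1..n_clusters."""

    run_index: int
    gene_to_cluster: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        labels = set(self.gene_to_cluster.values())
        if labels != set(range(1, self.n_clusters + 1)):
            raise InvalidInputError(
                "cluster indices must be contiguous 1..n_clusters with no empty cluster"
            )

    def labels(self, gene_order) -> np.ndarray:
        return np.array([self.gene_to_cluster[g] for g in gene_order])


@dataclass
class GibbsConfig:
    """Hyperparameters of the CRP / Normal-Gamma sampler.

    alpha is the CRP concentration (larger -> more clusters a priori);
    (mu0, kappa0, a0, b0) the Normal-Gamma base measure. kappa0 is small so
    cluster means are weakly tied to the grand mean; a0 = b0 = 1 puts a
    broad prior on the per-sample precision.
    """

    alpha: float = 1.0
    kappa0: float = 0.01
    a0: float = 1.0
    b0: float = 1.0
    mu0: float | None = None  # default: grand mean of the matrix


class _CrpState:
    """Sufficient statistics for the collapsed sampler; clusters are rows."""

    def __init__(self, n_samples: int, cfg: GibbsConfig, mu0: float):
        self.cfg = cfg
        self.mu0 = mu0
        self.m = n_samples
        self.n = np.zeros(0, dtype=np.int64)        # genes per cluster
        self.s = np.zeros((0, n_samples))           # per-sample sums
        self.ss = np.zeros((0, n_samples))          # per-sample sums of squares

    def add(self, c: int, x: np.ndarray) -> None:
        self.n[c] += 1
        self.s[c] += x
        self.ss[c] += x * x

    def remove(self, c: int, x: np.ndarray) -> None:
        self.n[c] -= 1
        self.s[c] -= x
        self.ss[c] -= x * x

    def new_cluster(self) -> int:
        self.n = np.append(self.n, 0)
        self.s = np.vstack([self.s, np.zeros(self.m)])
        self.ss = np.vstack([self.ss, np.zeros(self.m)])
        return len(self.n) - 1

    def drop_empty(self, assignments: np.ndarray) -> None:
        keep = self.n > 0
        if keep.all():
            return
        remap = np.full(len(self.n), -1, dtype=np.int64)
        remap[keep] = np.arange(keep.sum())
        self.n, self.s, self.ss = self.n[keep], self.s[keep], self.ss[keep]
        live = assignments >= 0
        assignments[live] = remap[assignments[live]]

    def log_predictive(self, x: np.ndarray) -> np.ndarray:
        """Log posterior-predictive of row ``x`` under each cluster plus a
        new cluster (last entry), summed over samples."""
        cfg = self.cfg
        n = np.append(self.n, 0).astype(float)
        s = np.vstack([self.s, np.zeros(self.m)])
        ss = np.vstack([self.ss, np.zeros(self.m)])

        kap = cfg.kappa0 + n
        a = cfg.a0 + n / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            xbar = np.where(n[:, None] > 0, s / np.maximum(n, 1)[:, None], 0.0)
        sse = ss - n[:, None] * xbar**2
        b = (
            cfg.b0
            + 0.5 * sse
            + (cfg.kappa0 * n / (2.0 * kap))[:, None] * (xbar - self.mu0) ** 2
        )
        mu = (cfg.kappa0 * self.mu0 + s) / kap[:, None]
        # Student-t predictive: df = 2a, scale^2 = b (kap+1) / (a kap)
        df = 2.0 * a
        scale2 = b * ((kap + 1.0) / (a * kap))[:, None]
        z2 = (x[None, :] - mu) ** 2 / (df[:, None] * scale2)
        ll = (
            gammaln((df + 1.0) / 2.0)[:, None]
            - gammaln(df / 2.0)[:, None]
            - 0.5 * (np.log(df * np.pi)[:, None] + np.log(scale2))
            - ((df + 1.0) / 2.0)[:, None] * np.log1p(z2)
        )
        return ll.sum(axis=1)


def _single_run(
    vals: np.ndarray, scan: np.ndarray, cfg: GibbsConfig, n_sweeps: int, seed: int
) -> np.ndarray:
    """Run the collapsed sampler; returns integer labels per gene row."""
    rng = np.random.default_rng(seed)
    n_genes, m = vals.shape
    mu0 = float(vals.mean()) if cfg.mu0 is None else cfg.mu0
    state = _CrpState(m, cfg, mu0)
    z = np.full(n_genes, -1, dtype=np.int64)
    # singleton initialisation: coalescence is the direction single-site
    # Gibbs mixes well in, so starting maximally split avoids getting stuck
    # in merged modes
    for g in scan:
        c = state.new_cluster()
        state.add(c, vals[g])
        z[g] = c

    for sweep in range(n_sweeps):
        for g in scan:
            x = vals[g]
            if z[g] >= 0:
                state.remove(z[g], x)
                z[g] = -1
                state.drop_empty(z)
            logp = state.log_predictive(x)
            prior = np.log(np.append(state.n, cfg.alpha).astype(float))
            logp = logp + prior
            logp -= logp.max()
            prob = np.exp(logp)
            choice = rng.choice(len(prob), p=prob / prob.sum())
            if choice == len(state.n):
                choice = state.new_cluster()
            state.add(choice, x)
            z[g] = choice
    return z


def gibbs_cluster(
    matrix: ExpressionMatrix,
    n_runs: int = 5,
    n_sweeps: int = 100,
    seed: int = 0,
    config: GibbsConfig | None = None,
) -> list[ClusterAssignment]:
    """Run ``n_runs`` independent CRP Gibbs clusterings of the genes.

    Per-run seeds are ``seed + run_index`` (run_index 1..n_runs), so runs are
    independent but the whole ensemble is reproducible from one master seed.
    A matrix that is constant everywhere has no cluster structure to infer;
    it yields a single-cluster partition per run with a warning.
    """
    if n_runs < 1 or n_sweeps < 1:
        raise InvalidInputError("n_runs and n_sweeps must be >= 1")
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise InvalidInputError("clustering needs >= 2 genes and >= 2 samples")
    cfg = config or GibbsConfig()
    genes = matrix.gene_ids
    vals = matrix.values.to_numpy(dtype=float)

    if np.ptp(vals) == 0:
        warnings.warn(
            "expression matrix is constant; returning single-cluster partitions",
            stacklevel=2,
        )
        return [
            ClusterAssignment(k, {g: 1 for g in genes}, 1)
            for k in range(1, n_runs + 1)
        ]

    # lexicographic scan order: row-permutation invariance under a fixed seed
    scan = np.array(sorted(range(len(genes)), key=lambda i: genes[i]))
    out = []
    for k in range(1, n_runs + 1):
        z = _single_run(vals, scan, cfg, n_sweeps, seed + k)
        # relabel 1..S_k by first appearance in lexicographic gene order
        relabel: dict[int, int] = {}
        for i in scan:
            if z[i] not in relabel:
                relabel[z[i]] = len(relabel) + 1
        out.append(
            ClusterAssignment(
                k, {genes[i]: relabel[z[i]] for i in range(len(genes))}, len(relabel)
            )
        )
    return out


def assignment_to_coclustering(
    assignment: ClusterAssignment, gene_universe
) -> np.ndarray:
    """Binary co-clustering matrix over ``gene_universe`` order: entry (i, j)
    is 1 iff the genes share a cluster. Symmetric with unit diagonal."""
    missing = [g for g in gene_universe if g not in assignment.gene_to_cluster]
    if missing:
        raise InvalidInputError(f"gene {missing[0]!r} missing from assignment")
    labels = assignment.labels(gene_universe)
    return (labels[:, None] == labels[None, :]).astype(np.int8)
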