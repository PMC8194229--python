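"""Synthetic fixture generation with planted ground truth.

Every stage of the pipeline has a generator here that emulates the
statistical structure the stage assumes: class-conditional expression with
planted gene clusters and tumor-shifted differential genes, weighted gene
graphs with planted overlapping communities whose pairwise overlap scores
are realized exactly by set construction, exponential survival with a
planted hazard difference between community-score groups, and Bernoulli
mutation matrices. A single master seed fans out deterministically to the
sub-generators, and :func:`simulate_dataset` writes a complete on-disk
fixture in the exact file dialects the pipeline readers accept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
import pandas as pd

from .data import ClinicalTable, ExpressionMatrix, MutationTable, write_gmt
from .overlap import overlap_score


@dataclass
class PlantedTruth:
    """Ground truth shared by the generators.

    communities maps community id -> gene set (possibly overlapping);
    differential_genes is disjoint from the null background genes.
    """

    communities: dict[int, set[str]]
    differential_genes: set[str]
    background_genes: set[str]
    survival_community: int | None = None
    hazard_ratio: float = 1.0
    mutation_freqs: dict[str, float] = dc_field(default_factory=dict)

    @property
    def all_genes(self) -> list[str]:
        pool = set(self.background_genes) | {
            g for s in self.communities.values() for g in s
        }
        return sorted(pool)

    @property
    def intended_overlaps(self) -> dict[str, float]:
        """Realized pairwise overlap scores of the planted communities."""
        out = {}
        ids = sorted(self.communities)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                out[f"{a}-{b}"] = overlap_score(
                    self.communities[a], self.communities[b]
                )
        return out

    @property
    def overlap_genes(self) -> set[str]:
        seen: set[str] = set()
        out: set[str] = set()
        for s in self.communities.values():
            out |= seen & s
            seen |= s
        return out

    def to_json(self, path) -> None:
        payload = {
            "communities": {str(k): sorted(v) for k, v in self.communities.items()},
            "differential_genes": sorted(self.differential_genes),
            "background_genes": sorted(self.background_genes),
            "survival_community": self.survival_community,
            "hazard_ratio": self.hazard_ratio,
            "mutation_freqs": dict(sorted(self.mutation_freqs.items())),
            "intended_overlaps": self.intended_overlaps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            communities={int(k): set(v) for k, v in d["communities"].items()},
            differential_genes=set(d["differential_genes"]),
            background_genes=set(d["background_genes"]),
            survival_community=d.get("survival_community"),
            hazard_ratio=d.get("hazard_ratio", 1.0),
            mutation_freqs=d.get("mutation_freqs", {}),
        )


def make_planted_truth(
    n_communities: int = 3,
    community_size: int = 20,
    shared: int = 3,
    n_background: int = 20,
) -> PlantedTruth:
    """Construct overlapping planted communities by exact set arithmetic.

    Communities sit on a cycle; each adjacent pair shares exactly ``shared``
    genes (for three communities the cycle covers all pairs, giving equal
    pairwise overlap). Overlap scores follow directly from the set sizes,
    e.g. size 20 with 3 shared gives omega = 9/400.
    """
    if n_communities < 1 or community_size < 1:
        raise ValueError("need >= 1 community of >= 1 gene")
    n_pairs = 0 if n_communities < 2 else (1 if n_communities == 2 else n_communities)
    if shared * 2 > community_size and n_pairs:
        raise ValueError("shared genes cannot exceed half the community size")

    counter = 0

    def take(n: int) -> list[str]:
        nonlocal counter
        out = [f"G{counter + i:04d}" for i in range(n)]
        counter += n
        return out

    shared_blocks = {}  # (c, c_next) -> genes
    for i in range(n_pairs):
        a, b = i + 1, (i + 1) % n_communities + 1
        shared_blocks[(a, b)] = take(shared)
    communities: dict[int, set[str]] = {}
    for c in range(1, n_communities + 1):
        own = community_size - sum(
            shared for pair in shared_blocks if c in pair
        )
        genes = set(take(own))
        for pair, block in shared_blocks.items():
            if c in pair:
                genes |= set(block)
        communities[c] = genes
    background = set(take(n_background))
    differential = {g for s in communities.values() for g in s}
    return PlantedTruth(
        communities=communities,
        differential_genes=differential,
        background_genes=background,
    )


def generate_expression(
    truth: PlantedTruth,
    n_samples_per_class: int = 30,
    cluster_effect_size: float = 3.0,
    noise_sd: float = 1.0,
    differential_shift: float = 3.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression matrix with planted co-expression clusters.

    Genes of a community share a latent per-sample Gaussian profile scaled
    by ``cluster_effect_size`` (genes in several communities average their
    profiles); i.i.d. Gaussian noise of ``noise_sd`` is added everywhere,
    and differential genes get a ``differential_shift`` mean shift in tumor
    samples. With noise_sd -> 0 the within-cluster correlation tends to 1;
    with cluster_effect_size = 0 there is no co-clustering signal.
    """
    rng = np.random.default_rng(seed)
    genes = truth.all_genes
    n = 2 * n_samples_per_class
    samples = [f"T{i:03d}" for i in range(n_samples_per_class)] + [
        f"N{i:03d}" for i in range(n_samples_per_class)
    ]
    labels = pd.Series(
        ["tumor"] * n_samples_per_class + ["normal"] * n_samples_per_class,
        index=samples,
    )
    profiles = {
        c: rng.standard_normal(n) for c in sorted(truth.communities)
    }
    vals = np.zeros((len(genes), n))
    for i, g in enumerate(genes):
        member_of = [c for c, s in truth.communities.items() if g in s]
        if member_of:
            vals[i] = cluster_effect_size * np.mean(
                [profiles[c] for c in member_of], axis=0
            )
    vals += noise_sd * rng.standard_normal(vals.shape)
    tumor_mask = (labels == "tumor").to_numpy()
    for i, g in enumerate(genes):
        if g in truth.differential_genes:
            vals[i, tumor_mask] += differential_shift
    df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df, labels)


def generate_overlapping_graph(
    truth: PlantedTruth,
    w_in: float = 0.9,
    w_out: float = 0.2,
    density_in: float = 0.9,
    density_out: float = 0.05,
    jitter: float = 0.05,
    seed: int = 0,
) -> nx.Graph:
    """Weighted gene graph with the planted communities as dense subgraphs.

    Pairs sharing a community get an edge with probability ``density_in``
    and weight near ``w_in``; all other pairs with probability
    ``density_out`` and weight near ``w_out`` (weights jittered uniformly by
    +-``jitter`` and clipped to (0, 1]). With equal weights and densities
    there is no community signal by construction.
    """
    rng = np.random.default_rng(seed)
    genes = truth.all_genes
    g = nx.Graph()
    g.add_nodes_from(genes)
    member = {
        gene: {c for c, s in truth.communities.items() if gene in s}
        for gene in genes
    }
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            together = bool(member[a] & member[b])
            dens, w = (density_in, w_in) if together else (density_out, w_out)
            if rng.random() < dens:
                weight = float(
                    np.clip(w + rng.uniform(-jitter, jitter), 1e-3, 1.0)
                )
                g.add_edge(a, b, weight=weight, provenance="synthetic")
    return g


def generate_survival(
    expr: ExpressionMatrix,
    community,
    hazard_ratio: float = 3.0,
    censoring_rate: float = 0.2,
    baseline_scale: float = 1000.0,
    seed: int = 0,
    samples: str = "tumor",
) -> ClinicalTable:
    """Exponential survival with a planted hazard difference.

    Patients (tumor samples by default, ``samples="all"`` for every column)
    whose community score exceeds the cohort mean get their event rate
    multiplied by ``hazard_ratio``. Censoring is independent exponential
    with rate chosen so a baseline patient is censored with probability
    ``censoring_rate``; all recorded times are >= 1 day.
    """
    from .downstream import community_score

    rng = np.random.default_rng(seed)
    score = community_score(community, expr)
    if samples == "tumor":
        keep = [s for s in score.index if expr.sample_class[s] == "tumor"]
        score = score[keep]
    high = (score > score.mean()).to_numpy()
    lam0 = 1.0 / baseline_scale
    rates = lam0 * np.where(high, hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        lam_c = lam0 * censoring_rate / (1.0 - censoring_rate)
        censor_t = rng.exponential(1.0 / lam_c, size=len(score))
    else:
        censor_t = np.full(len(score), np.inf)
    obs = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    days = np.maximum(1, np.round(obs)).astype(int)
    table = pd.DataFrame(
        {"os_days": days, "event": event},
        index=pd.Index(score.index, name="sample"),
    )
    return ClinicalTable(table)


def generate_mutations(
    freqs, n_samples: int, seed: int = 0, sample_ids=None
) -> MutationTable:
    """Independent Bernoulli mutation matrix at per-gene rates."""
    freqs = pd.Series(freqs).sort_index()
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"T{i:03d}" for i in range(n_samples)]
    vals = (
        rng.random((len(freqs), n_samples)) < freqs.to_numpy()[:, None]
    ).astype(int)
    df = pd.DataFrame(
        vals, index=pd.Index(freqs.index, name="gene"), columns=sample_ids
    )
    return MutationTable(df)


PRESETS = {
    "small": dict(
        n_communities=3, community_size=12, shared=2, n_background=20,
        n_samples_per_class=25,
    ),
    "paper-like": dict(
        n_communities=5, community_size=20, shared=3, n_background=60,
        n_samples_per_class=40,
    ),
}


def _write_ppi(truth: PlantedTruth, path, seed: int) -> None:
    """STRING-dialect edge file (0-1000 integer scores) concentrated within
    the planted communities, with sub-threshold background pairs."""
    rng = np.random.default_rng(seed)
    genes = truth.all_genes
    member = {
        gene: {c for c, s in truth.communities.items() if gene in s}
        for gene in genes
    }
    lines = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if member[a] & member[b]:
                if rng.random() < 0.5:
                    lines.append((a, b, int(rng.integers(600, 950))))
            elif rng.random() < 0.02:
                lines.append((a, b, int(rng.integers(150, 500))))
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, s in lines:
            fh.write(f"{a} {b} {s}\n")


def simulate_dataset(preset: str = "small", seed: int = 0, outdir=".") -> PlantedTruth:
    """Write a complete synthetic study to ``outdir``.

    Emits expression + label TSVs, a STRING-dialect PPI file, clinical and
    mutation TSVs, a GMT collection whose first terms are the planted
    communities, and the ground truth as JSON. Sub-generator seeds are
    fixed offsets of the master seed.
    """
    from pathlib import Path

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    truth = make_planted_truth(
        p["n_communities"], p["community_size"], p["shared"], p["n_background"]
    )
    truth.survival_community = 1
    truth.hazard_ratio = 3.0
    truth.mutation_freqs = {
        g: (0.7 if g in truth.communities[1] else 0.05) for g in truth.all_genes
    }

    expr = generate_expression(
        truth, n_samples_per_class=p["n_samples_per_class"], seed=seed + 11
    )
    expr.to_tsv(out / "expression.tsv", out / "labels.tsv")

    _write_ppi(truth, out / "ppi.txt", seed + 23)

    clinical = generate_survival(
        expr, truth.communities[1], hazard_ratio=truth.hazard_ratio, seed=seed + 31
    )
    clinical.to_tsv(out / "clinical.tsv")

    tumor_samples = expr.class_columns("tumor")
    mut = generate_mutations(
        truth.mutation_freqs, len(tumor_samples), seed=seed + 41,
        sample_ids=tumor_samples,
    )
    mut.to_tsv(out / "mutations.tsv")

    rng = np.random.default_rng(seed + 53)
    gmt = {
        f"PLANTED_C{c}": set(truth.communities[c]) for c in truth.communities
    }
    pool = truth.all_genes
    for d in range(1, 4):
        gmt[f"DECOY_{d}"] = set(rng.choice(pool, size=8, replace=False))
    write_gmt(gmt, out / "genesets.gmt")

    truth.to_json(out / "truth.json")
    return truth
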