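"""Model/Results facade over the community-detection pipeline.

:class:`GeneCommunityModel` is built from an expression matrix (plus
optional copy-number matrix and PPI weights); :meth:`fit` runs the full
inference chain — differential gene filtering, repeated Gibbs clustering,
consensus network construction, PPI fusion, cohesive community growth, and
overlap classification/merging — and returns a
:class:`GeneCommunityResults` carrying every intermediate product, a text
``summary()``, and the downstream validation methods (survival split,
driver ranking, enrichment, per-gene AUC) as result-object methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .communities import Community, detect_communities
from .data import (
    ClinicalTable,
    ExpressionMatrix,
    InvalidInputError,
    MutationTable,
    read_gmt,
)
from .downstream import (
    candidate_drivers,
    gene_classification_auc,
    geneset_enrichment,
    rank_drivers,
    subtype_mutation_enrichment,
    survival_split_test,
)
from .gibbs import GibbsConfig, gibbs_cluster
from .network import (
    build_weighted_graph,
    consensus_frequency,
    graph_from_tsv,
    graph_to_tsv,
    integrate_ppi,
    read_string_edges,
)
from .overlap import CommunityCatalog, classify_and_merge
from .preprocess import combine_gene_sets, differential_gene_filter


@dataclass
class PipelineConfig:
    """All stage parameters, with the study defaults.

    q_threshold 0.1 (differential q-value cut), n_runs 5 (Gibbs runs),
    freq_threshold 0.4 (consensus edge cut), ppi_threshold 0.4 (STRING
    combined-score cut), penalty 0.2 (cohesiveness size penalty p),
    omega_threshold 0.8 (merge cut), min_os_days 30, mutation_freq_threshold
    0.6, top_fraction 0.01 (driver ranking), folds 10 and cost 10 (SVM).
    """

    q_threshold: float = 0.1
    n_permutations: int = 1000
    n_runs: int = 5
    n_sweeps: int = 100
    freq_threshold: float = 0.4
    ppi_threshold: float = 0.4
    penalty: float = 0.2
    min_size: int = 2
    omega_threshold: float = 0.8
    min_os_days: float = 30
    mutation_freq_threshold: float = 0.6
    top_fraction: float = 0.01
    folds: int = 10
    cost: float = 10.0
    seed: int = 0
    # input paths (used by run_pipeline; optional for the in-memory API)
    expression: str | None = None
    labels: str | None = None
    cnv: str | None = None
    ppi: str | None = None
    clinical: str | None = None
    mutations: str | None = None
    genesets: str | None = None
    subtypes: str | None = None

    def __post_init__(self) -> None:
        checks = [
            ("q_threshold", self.q_threshold, 0, 1, "[)"),
            ("freq_threshold", self.freq_threshold, 0, 1, "[)"),
            ("ppi_threshold", self.ppi_threshold, 0, 1, "[)"),
            ("omega_threshold", self.omega_threshold, 0, 1, "(]"),
            ("top_fraction", self.top_fraction, 0, 1, "(]"),
        ]
        for name, v, lo, hi, kind in checks:
            lo_ok = v >= lo if kind[0] == "[" else v > lo
            hi_ok = v <= hi if kind[1] == "]" else v < hi
            if not (lo_ok and hi_ok):
                raise InvalidInputError(f"{name}={v} outside {kind[0]}{lo},{hi}{kind[1]}")
        if self.penalty < 0:
            raise InvalidInputError("penalty must be >= 0")
        for name in ("n_permutations", "n_runs", "n_sweeps", "min_size", "folds"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class GeneCommunityModel:
    """Overlapping gene-community model for a tumor/normal expression study.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples with tumor/normal labels.
    cnv : ExpressionMatrix, optional
        Copy-number matrix over the same classes; filtered with the same
        differential rule and combined with the expression genes by union.
    ppi : dict, optional
        Pre-thresholded PPI weights (frozenset pair -> weight in (0, 1]),
        e.g. from :func:`genecomm.network.read_string_edges`.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        cnv: ExpressionMatrix | None = None,
        ppi: dict | None = None,
        config: PipelineConfig | None = None,
        gibbs_config: GibbsConfig | None = None,
    ):
        self.expression = expression
        self.cnv = cnv
        self.ppi = ppi
        self.config = config or PipelineConfig()
        self.gibbs_config = gibbs_config

    @classmethod
    def from_files(
        cls,
        expr_path,
        labels_path,
        cnv_path=None,
        ppi_path=None,
        config: PipelineConfig | None = None,
    ) -> "GeneCommunityModel":
        config = config or PipelineConfig()
        expr = ExpressionMatrix.from_tsv(expr_path, labels_path)
        cnv = (
            ExpressionMatrix.from_tsv(cnv_path, labels_path)
            if cnv_path is not None
            else None
        )
        ppi = (
            read_string_edges(ppi_path, score_threshold=config.ppi_threshold)
            if ppi_path is not None
            else None
        )
        return cls(expr, cnv=cnv, ppi=ppi, config=config)

    def fit(self, seed: int | None = None) -> "GeneCommunityResults":
        """Run the full inference chain; deterministic under a fixed seed."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed

        diff_expr = differential_gene_filter(
            self.expression, cfg.q_threshold, cfg.n_permutations, seed
        )
        expr_selected = set(diff_expr.index[diff_expr["selected"]])
        diff_cnv = None
        if self.cnv is not None:
            diff_cnv = differential_gene_filter(
                self.cnv, cfg.q_threshold, cfg.n_permutations, seed + 1
            )
            cnv_selected = set(diff_cnv.index[diff_cnv["selected"]])
        else:
            cnv_selected = set()
        universe = combine_gene_sets(expr_selected, cnv_selected)
        universe = [g for g in universe if g in self.expression.values.index]
        if len(universe) < 2:
            raise InvalidInputError(
                f"only {len(universe)} genes pass the differential filter; "
                "cannot cluster"
            )
        sub = self.expression.subset_genes(universe)

        assignments = gibbs_cluster(
            sub, cfg.n_runs, cfg.n_sweeps, seed, config=self.gibbs_config
        )
        frequency = consensus_frequency(assignments, sub.gene_ids)
        graph = build_weighted_graph(frequency, cfg.freq_threshold)
        if self.ppi:
            graph = integrate_ppi(graph, self.ppi)

        communities = detect_communities(graph, cfg.penalty, cfg.min_size)
        catalog = classify_and_merge(communities, cfg.omega_threshold, graph)

        return GeneCommunityResults(
            model=self,
            seed=seed,
            differential=diff_expr,
            differential_cnv=diff_cnv,
            selected_genes=universe,
            assignments=assignments,
            frequency=frequency,
            graph=graph,
            communities_premerge=communities,
            catalog=catalog,
        )


@dataclass
class GeneCommunityResults:
    """Fitted communities plus every intermediate pipeline product."""

    model: GeneCommunityModel
    seed: int
    differential: pd.DataFrame
    differential_cnv: pd.DataFrame | None
    selected_genes: list[str]
    assignments: list
    frequency: object
    graph: nx.Graph
    communities_premerge: list[Community]
    catalog: CommunityCatalog

    # -- reporting -----------------------------------------------------------

    def community_table(self) -> pd.DataFrame:
        rows = [
            {
                "community": c.id,
                "size": c.size,
                "cohesiveness": c.cohesiveness,
                "label": self.catalog.labels[c.id],
                "sources": ",".join(map(str, self.catalog.merge_lineage[c.id])),
            }
            for c in sorted(self.catalog.communities, key=lambda c: c.id)
        ]
        return pd.DataFrame(
            rows, columns=["community", "size", "cohesiveness", "label", "sources"]
        )

    def summary(self) -> str:
        cfg = self.model.config
        cat = self.catalog
        lines = [
            "Gene Community Detection Results",
            "=" * 48,
            f"genes in matrix:           {self.model.expression.n_genes}",
            f"samples (tumor/normal):    "
            f"{len(self.model.expression.class_columns('tumor'))}/"
            f"{len(self.model.expression.class_columns('normal'))}",
            f"differential genes (q<{cfg.q_threshold}): {len(self.selected_genes)}",
            f"gibbs runs x sweeps:       {cfg.n_runs} x {cfg.n_sweeps}",
            f"graph nodes / edges:       {self.graph.number_of_nodes()} / "
            f"{self.graph.number_of_edges()}",
            f"communities before merge:  {cat.n_before}",
            f"communities after merge:   {cat.n_after} "
            f"(reduction {cat.n_merges})",
            f"independent / dependent:   {cat.n_independent} / {cat.n_dependent}",
            "-" * 48,
        ]
        table = self.community_table()
        if len(table):
            lines.append(
                table.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)

    # -- downstream validations ---------------------------------------------

    def survival_test(self, clinical: ClinicalTable, community_id: int):
        """Survival split test for one post-merge community."""
        cfg = self.model.config
        return survival_split_test(
            self.catalog.community(community_id),
            self.model.expression,
            clinical,
            min_days=cfg.min_os_days,
        )

    def driver_genes(self, mutations: MutationTable) -> pd.DataFrame:
        """Candidate drivers (fre above threshold) ranked per community by
        within-community regulation score; top fraction per community."""
        cfg = self.model.config
        candidates = candidate_drivers(mutations, cfg.mutation_freq_threshold)
        rows = []
        for c in sorted(self.catalog.communities, key=lambda c: c.id):
            for rank, g in enumerate(
                rank_drivers(c, self.graph, candidates, cfg.top_fraction), 1
            ):
                rows.append({"community": c.id, "gene": g, "rank": rank})
        return pd.DataFrame(rows, columns=["community", "gene", "rank"])

    def enrichment(
        self, collection: dict[str, set], community_id: int, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Gene-set enrichment of one community against the post-filter
        gene universe."""
        background = set(self.selected_genes)
        genes = set(self.catalog.community(community_id).genes) & background
        return geneset_enrichment(genes, collection, background, alpha)

    def subtype_enrichment(self, mutations, subtypes, community_id: int):
        return subtype_mutation_enrichment(
            self.catalog.community(community_id), mutations, subtypes
        )

    def classification_auc(self, gene: str, seed: int | None = None):
        cfg = self.model.config
        return gene_classification_auc(
            gene,
            self.model.expression,
            folds=cfg.folds,
            cost=cfg.cost,
            seed=self.seed if seed is None else seed,
        )

    # -- plotting ------------------------------------------------------------

    def plot_network(self, ax=None):
        """Draw the fused gene graph with post-merge communities coloured."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        pos = nx.spring_layout(self.graph, seed=self.seed)
        nx.draw_networkx_edges(self.graph, pos, ax=ax, alpha=0.2)
        cmap = plt.get_cmap("tab10")
        for i, c in enumerate(self.catalog.communities):
            nx.draw_networkx_nodes(
                self.graph, pos, nodelist=sorted(c.genes), ax=ax,
                node_color=[cmap(i % 10)], node_size=40,
                label=f"C{c.id} ({self.catalog.labels[c.id]})",
            )
        ax.legend(loc="best", fontsize=8)
        ax.set_axis_off()
        return ax

    # -- persistence ---------------------------------------------------------

    def save(self, outdir) -> dict:
        """Write every stage product as TSV/text plus a manifest with
        parameter values and output hashes; byte-stable under a fixed seed."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        self.differential.to_csv(out / "differential.tsv", sep="\t")
        if self.differential_cnv is not None:
            self.differential_cnv.to_csv(out / "differential_cnv.tsv", sep="\t")
        (out / "genes.txt").write_text("".join(g + "\n" for g in self.selected_genes))

        runs_dir = out / "runs"
        runs_dir.mkdir(exist_ok=True)
        for a in self.assignments:
            pd.Series(a.gene_to_cluster, name="cluster").sort_index().to_csv(
                runs_dir / f"run_{a.run_index}.tsv", sep="\t", index_label="gene"
            )

        graph_to_tsv(self.graph, out / "graph.tsv")

        pre = pd.DataFrame(
            [
                {"community": c.id, "gene": g}
                for c in self.communities_premerge
                for g in sorted(c.genes)
            ],
            columns=["community", "gene"],
        )
        pre.to_csv(out / "communities_premerge.tsv", sep="\t", index=False)

        membership = pd.DataFrame(
            [
                {"community": c.id, "gene": g}
                for c in sorted(self.catalog.communities, key=lambda c: c.id)
                for g in sorted(c.genes)
            ],
            columns=["community", "gene"],
        )
        membership.to_csv(out / "membership.tsv", sep="\t", index=False)
        self.community_table().to_csv(out / "labels.tsv", sep="\t", index=False)
        overlaps = pd.DataFrame(
            [
                {"community_a": min(p), "community_b": max(p), "omega": w}
                for p, w in sorted(
                    self.catalog.pair_overlaps.items(), key=lambda kv: sorted(kv[0])
                )
            ],
            columns=["community_a", "community_b", "omega"],
        )
        overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
        lineage = pd.DataFrame(
            [
                {"community": cid, "sources": ",".join(map(str, src)),
                 "n_sources": len(src)}
                for cid, src in sorted(self.catalog.merge_lineage.items())
            ],
            columns=["community", "sources", "n_sources"],
        )
        lineage.to_csv(out / "lineage.tsv", sep="\t", index=False)

        (out / "summary.txt").write_text(self.summary() + "\n")

        manifest = {
            "version": __version__,
            "seed": self.seed,
            "parameters": {
                k: v
                for k, v in asdict(self.model.config).items()
                if not isinstance(v, (type(None),))
            },
            "outputs": {},
        }
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                digest = hashlib.sha256(path.read_bytes()).hexdigest()
                manifest["outputs"][str(path.relative_to(out))] = digest
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return manifest


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """File-to-file pipeline: load the configured inputs, fit the model,
    write all stage outputs plus downstream validations into ``outdir``.

    Returns the output manifest. Any stage failure raises
    :class:`PipelineError` naming the stage and the offending input.
    """
    seed = config.seed if seed is None else seed
    out = Path(outdir)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FileNotFoundError as exc:
            raise PipelineError(f"stage {name}: missing input file {exc.filename}") from exc
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    if config.expression is None or config.labels is None:
        raise PipelineError("stage load: config must set expression and labels paths")
    for name, path in (("expression", config.expression), ("labels", config.labels),
                       ("cnv", config.cnv), ("ppi", config.ppi),
                       ("clinical", config.clinical), ("mutations", config.mutations),
                       ("genesets", config.genesets)):
        if path is not None and not Path(path).exists():
            raise PipelineError(f"stage load: missing {name} file {path}")

    model = stage(
        "load",
        GeneCommunityModel.from_files,
        config.expression,
        config.labels,
        cnv_path=config.cnv,
        ppi_path=config.ppi,
        config=config,
    )
    results = stage("fit", model.fit, seed)
    manifest = stage("save", results.save, out)

    extra_files = []
    if config.clinical is not None:
        clinical = ClinicalTable.from_tsv(config.clinical)
        rows = []
        for c in sorted(results.catalog.communities, key=lambda c: c.id):
            try:
                sr = results.survival_test(clinical, c.id)
                rows.append(
                    {"community": c.id, "logrank_p": sr.logrank_p,
                     "cox_hazard_ratio": sr.cox_hazard_ratio, "cox_p": sr.cox_p}
                )
            except InvalidInputError:
                continue
        pd.DataFrame(
            rows, columns=["community", "logrank_p", "cox_hazard_ratio", "cox_p"]
        ).to_csv(out / "survival.tsv", sep="\t", index=False)
        extra_files.append("survival.tsv")

    if config.mutations is not None:
        mutations = MutationTable.from_tsv(config.mutations)
        results.driver_genes(mutations).to_csv(
            out / "drivers.tsv", sep="\t", index=False
        )
        extra_files.append("drivers.tsv")

    if config.genesets is not None:
        collection = read_gmt(config.genesets)
        frames = []
        for c in sorted(results.catalog.communities, key=lambda c: c.id):
            df = results.enrichment(collection, c.id)
            df.insert(0, "community", c.id)
            frames.append(df[df["significant"]])
        enr = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["community", "term", "overlap", "term_size",
                                       "p", "corrected_p", "significant"])
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        extra_files.append("enrichment.tsv")

    if extra_files:  # refresh manifest hashes to cover downstream outputs
        manifest = _rehash_manifest(out, manifest)
    return manifest


def _rehash_manifest(out: Path, manifest: dict) -> dict:
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["outputs"][str(path.relative_to(out))] = digest
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def load_results_graph(rundir) -> nx.Graph:
    """Reload the fused graph written by a previous run (resumability)."""
    return graph_from_tsv(Path(rundir) / "graph.tsv")
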