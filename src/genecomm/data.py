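"""Core data containers: expression matrices, clinical tables, mutation tables.

All tabular I/O is TSV-based so that fixtures stay plain text. The containers
are thin, validated wrappers around pandas objects; downstream modules accept
and return them rather than raw frames so invariants are checked once, at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_CLASSES = (TUMOR, NORMAL)


class InvalidInputError(ValueError):
    """Raised when an input violates a documented pre-condition."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with per-sample tumor/normal labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id. Arbitrary expression
        units (the methods are distribution- or rank-based throughout).
    sample_class : pandas.Series
        Per-sample label, one of ``"tumor"`` / ``"normal"``, indexed by
        sample id and covering every column of *values*.
    """

    values: pd.DataFrame
    sample_class: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            raise InvalidInputError("duplicate sample ids")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise InvalidInputError(
                "expression matrix contains missing or non-finite values; "
                "pass impute=True to from_tsv to impute by per-gene median"
            )
        missing = v.columns.difference(self.sample_class.index)
        if len(missing):
            raise InvalidInputError(f"samples without class label: {list(missing)[:5]}")
        self.sample_class = self.sample_class.reindex(v.columns)
        bad = set(self.sample_class.unique()) - set(VALID_CLASSES)
        if bad:
            raise InvalidInputError(f"unknown sample class labels: {sorted(bad)}")

    # -- accessors -----------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_columns(self, label: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == label])

    def class_values(self, label: str) -> pd.DataFrame:
        """Sub-matrix restricted to samples of one class."""
        return self.values[self.class_columns(label)]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.sample_class)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, expr_path, labels_path, impute: bool = False) -> "ExpressionMatrix":
        """Load from an expression TSV (first column gene id, header row of
        sample ids) and a two-column label TSV mapping sample id -> class."""
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        labels.index = labels.index.astype(str)
        if impute and values.isna().to_numpy().any():
            med = values.median(axis=1)
            values = values.apply(lambda row: row.fillna(med[row.name]), axis=1)
        return cls(values, labels.astype(str))

    def to_tsv(self, expr_path, labels_path=None) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        if labels_path is not None:
            self.sample_class.rename("class").to_csv(
                labels_path, sep="\t", index_label="sample"
            )


@dataclass
class ClinicalTable:
    """Per-patient overall survival: sample id, OS days, event flag.

    Only patients with at least ``min_days`` (default 30) of overall survival
    enter survival analyses; :meth:`eligible` applies that filter.
    """

    table: pd.DataFrame  # index: sample id; columns: os_days, event

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise InvalidInputError("duplicate sample ids in clinical table")
        for col in ("os_days", "event"):
            if col not in t.columns:
                raise InvalidInputError(f"clinical table missing column {col!r}")
        if (t["os_days"] < 0).any():
            raise InvalidInputError("negative overall-survival days")
        self.table = t.assign(
            os_days=t["os_days"].astype(float), event=t["event"].astype(int)
        )

    def eligible(self, min_days: float = 30) -> pd.DataFrame:
        return self.table[self.table["os_days"] >= min_days]

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        t = pd.read_csv(path, sep="\t", index_col=0)
        t.index = t.index.astype(str)
        return cls(t)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


@dataclass
class MutationTable:
    """Binary genes x samples mutation indicator matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise InvalidInputError("mutation table entries must be 0/1")
        self.values = self.values.astype(int)

    @property
    def frequencies(self) -> pd.Series:
        """Per-gene mutation frequency ``fre`` = row mean over samples."""
        return self.values.mean(axis=1)

    @classmethod
    def from_tsv(cls, path) -> "MutationTable":
        t = pd.read_csv(path, sep="\t", index_col=0)
        t.index = t.index.astype(str)
        t.columns = t.columns.astype(str)
        return cls(t)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
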