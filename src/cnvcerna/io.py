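"""Domain containers and readers/writers for the tabular formats the pipeline touches.

Matrices are stored genes-as-rows, samples-as-columns (TCGA table convention)
and all downstream code addresses cells by (feature id, sample id), never by
position. Missing expression is kept as NaN and excluded pairwise from
correlations; it is never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALLOWED_CALLS = (-2, -1, 0, 1, 2)
FEATURE_CLASSES = ("mRNA", "lncRNA", "miRNA")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Expression on log2(x+1) scale, features x samples; NaN marks missing."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}")
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (not np.all(np.isfinite(finite)) or finite.min() < 0):
            raise ValueError("expression values must be finite and >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class CopyNumberCallMatrix:
    """Discrete GISTIC-style per-gene per-sample calls in {-2,-1,0,1,2}."""

    calls: pd.DataFrame  # index = gene ids, columns = sample ids, int

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "gene id")
        _check_unique(self.calls.columns, "sample id")
        bad = ~self.calls.isin(ALLOWED_CALLS)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"copy-number call {self.calls.iat[r, c]!r} outside {ALLOWED_CALLS} "
                f"at gene {self.calls.index[r]!r}, sample {self.calls.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class TargetInteractionSet:
    """miRNA -> target edges (StarBase-style), deduplicated."""

    edges: pd.DataFrame  # columns: mirna_id, target_id, target_class

    def __post_init__(self) -> None:
        need = ["mirna_id", "target_id", "target_class"]
        if list(self.edges.columns)[:3] != need:
            raise FormatError(f"interaction table must have columns {need}")
        bad = ~self.edges["target_class"].isin(["mRNA", "lncRNA"])
        if bad.any():
            raise FormatError(
                f"invalid target_class values: {self.edges.loc[bad, 'target_class'].unique()[:5]}"
            )
        n0 = len(self.edges)
        self.edges = self.edges.drop_duplicates(ignore_index=True)
        if len(self.edges) < n0:
            log.info("deduplicated %d duplicate interaction edges", n0 - len(self.edges))
        cls = self.edges.groupby("target_id")["target_class"].nunique()
        if (cls > 1).any():
            raise FormatError(
                f"inconsistent target_class for target(s) {cls[cls > 1].index.tolist()[:5]}"
            )

    def targets_by_mirna(self) -> dict[str, set[str]]:
        return {m: set(g["target_id"]) for m, g in self.edges.groupby("mirna_id")}

    def mirnas_by_target(self) -> dict[str, set[str]]:
        return {t: set(g["mirna_id"]) for t, g in self.edges.groupby("target_id")}


@dataclass
class ClinicalTable:
    """Per-sample overall survival (days), event indicator and subtype."""

    table: pd.DataFrame  # index = sample ids; os_days, os_event, subtype, [covariates]

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        for col in ("os_days", "os_event", "subtype"):
            if col not in self.table.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if (self.table["os_days"].astype(float) < 0).any():
            raise ValueError("os_days must be non-negative")
        if not self.table["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneSetCollection:
    """Named gene sets with a description string each (GMT carrier)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path: str | Path, dtype: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, f"feature id in {path.name}")
    _check_unique(df.columns, f"sample id in {path.name}")
    out = df.apply(pd.to_numeric, errors="coerce")
    # cells that were non-empty text but failed numeric conversion are errors,
    # empty cells are legitimate missing values
    was_text = df.notna() & (df != "")
    bad = was_text & out.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path.name}"
        )
    return out


def read_expression_matrix(path: str | Path, feature_class: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample ids, first column = ids)."""
    return ExpressionMatrix(_read_matrix_tsv(path, "float"), feature_class)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="")


def read_cnv_calls(path: str | Path) -> CopyNumberCallMatrix:
    df = _read_matrix_tsv(path, "int")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"missing copy-number call at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if not (df.to_numpy() == df.to_numpy().astype(int)).all():
        raise FormatError("copy-number calls must be integers")
    return CopyNumberCallMatrix(df.astype(int))


def write_cnv_calls(calls: CopyNumberCallMatrix, path: str | Path) -> None:
    calls.calls.to_csv(path, sep="\t", index_label="gene_id")


def read_interactions(path: str | Path) -> TargetInteractionSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TargetInteractionSet(df)


def write_interactions(ix: TargetInteractionSet, path: str | Path) -> None:
    ix.edges.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected name, description, members")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
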