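"""Identify genes whose expression tracks their copy-number state.

Pipeline order: recode low-level calls (+/-1) to neutral, drop genes without
recurrent CNV, resolve genes that mix high-level amplification and deletion
with an exact binomial noise test, then test aberrant-vs-neutral expression
with a two-sided Wilcoxon rank-sum test gated on median concordance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CopyNumberCallMatrix, ExpressionMatrix

log = logging.getLogger(__name__)

AMP, DEL = "amplification", "deletion"


@dataclass
class StatusGrouping:
    """Disjoint sample sets of one gene's copy-number statuses."""

    gene_id: str
    amplified_samples: set[str]
    deleted_samples: set[str]
    normal_samples: set[str]

    def __post_init__(self) -> None:
        a, d, n = self.amplified_samples, self.deleted_samples, self.normal_samples
        if a & d or a & n or d & n:
            raise ValueError(f"status groups of {self.gene_id} overlap")


@dataclass
class CnvDriverResult:
    gene_id: str
    direction: str  # amplification | deletion
    ranksum_p: float
    median_aberrant: float
    median_normal: float
    concordant: bool
    is_driver: bool
    n_aberrant: int
    n_normal: int
    reason: str = ""


def filter_expression(
    expr: ExpressionMatrix,
    min_expr_fraction: float = 0.30,
    max_missing_fraction: float = 0.10,
) -> ExpressionMatrix:
    """Detection-fraction prefilter: keep features observed (non-missing and
    non-zero) in at least ``min_expr_fraction`` of samples and missing in at
    most ``max_missing_fraction``."""
    vals = expr.values
    n = vals.shape[1]
    detected = ((vals.notna()) & (vals != 0)).sum(axis=1) / n
    missing = vals.isna().sum(axis=1) / n
    keep = (detected >= min_expr_fraction) & (missing <= max_missing_fraction)
    dropped = int((~keep).sum())
    if dropped:
        log.info("expression prefilter dropped %d/%d %s features",
                 dropped, len(keep), expr.feature_class)
    return ExpressionMatrix(vals.loc[keep].copy(), expr.feature_class)


def recode_low_level(calls: CopyNumberCallMatrix) -> CopyNumberCallMatrix:
    """Recode +/-1 calls to 0: only high-level amplifications and homozygous
    deletions are analysed."""
    c = calls.calls.copy()
    c[(c == 1) | (c == -1)] = 0
    return CopyNumberCallMatrix(c)


def filter_low_cnv_genes(
    calls: CopyNumberCallMatrix, min_fraction: float = 0.10
) -> CopyNumberCallMatrix:
    """Keep genes with a copy-number call in at least ``min_fraction`` of samples."""
    frac = (calls.calls != 0).sum(axis=1) / calls.calls.shape[1]
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("no gene passes the recurrent-CNV filter", stacklevel=2)
    return CopyNumberCallMatrix(calls.calls.loc[keep].copy())


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p by doubling the smaller tail, capped at 1."""
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def resolve_mixed_states(
    calls_row: pd.Series, alpha: float = 0.05
) -> pd.Series | None:
    """Resolve genes carrying both +2 and -2: the minority state is treated as
    noise and zeroed when an exact binomial test (against 0.5) rejects;
    otherwise the gene is ambiguous and removed (None)."""
    row = calls_row.copy()
    n_amp = int((row == 2).sum())
    n_del = int((row == -2).sum())
    if n_amp == 0 or n_del == 0:
        return row
    k = min(n_amp, n_del)
    p = binomial_two_sided(k, n_amp + n_del)
    if p < alpha:
        minority = 2 if n_amp < n_del else -2
        row[row == minority] = 0
        return row
    return None


def clean_calls(
    calls: CopyNumberCallMatrix,
    min_fraction: float = 0.10,
    binomial_alpha: float = 0.05,
) -> CopyNumberCallMatrix:
    """Full call cleanup: recode, recurrence filter, mixed-state resolution."""
    filtered = filter_low_cnv_genes(recode_low_level(calls), min_fraction)
    rows, removed = [], []
    for gene, row in filtered.calls.iterrows():
        resolved = resolve_mixed_states(row, binomial_alpha)
        if resolved is None:
            removed.append(gene)
        else:
            rows.append(resolved)
    if removed:
        log.info("removed %d gene(s) with ambiguous mixed CNV states: %s",
                 len(removed), removed[:5])
    frame = pd.DataFrame(rows) if rows else filtered.calls.iloc[:0]
    return CopyNumberCallMatrix(frame)


def status_grouping(calls: CopyNumberCallMatrix, gene_id: str) -> StatusGrouping:
    row = calls.calls.loc[gene_id]
    return StatusGrouping(
        gene_id=gene_id,
        amplified_samples=set(row.index[row == 2]),
        deleted_samples=set(row.index[row == -2]),
        normal_samples=set(row.index[row == 0]),
    )


def ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact enumeration for small tie-free
    groups, tie-corrected normal approximation otherwise."""
    exact_ok = (
        max(len(x), len(y)) <= 10
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def test_cnv_driver(
    expr: ExpressionMatrix,
    grouping: StatusGrouping,
    alpha: float = 0.05,
    min_group: int = 3,
) -> list[CnvDriverResult]:
    """Rank-sum + concordance driver test, one result per aberrant direction
    present for the gene. Small groups yield a non-driver result with a reason
    code rather than an exception."""
    results: list[CnvDriverResult] = []
    if grouping.gene_id not in expr.values.index:
        return results
    vec = expr.values.loc[grouping.gene_id]
    normal = vec.reindex(sorted(grouping.normal_samples)).dropna().to_numpy()
    for direction, members in (
        (AMP, grouping.amplified_samples),
        (DEL, grouping.deleted_samples),
    ):
        if not members:
            continue
        aberrant = vec.reindex(sorted(members)).dropna().to_numpy()
        if len(aberrant) < min_group or len(normal) < min_group:
            results.append(CnvDriverResult(
                grouping.gene_id, direction, np.nan,
                float(np.median(aberrant)) if len(aberrant) else np.nan,
                float(np.median(normal)) if len(normal) else np.nan,
                False, False, len(aberrant), len(normal), reason="group_too_small",
            ))
            continue
        p = ranksum_two_sided(aberrant, normal)
        med_a, med_n = float(np.median(aberrant)), float(np.median(normal))
        concordant = (direction == AMP and med_a > med_n) or (
            direction == DEL and med_a < med_n
        )
        results.append(CnvDriverResult(
            grouping.gene_id, direction, p, med_a, med_n,
            concordant, bool(p < alpha and concordant),
            len(aberrant), len(normal),
        ))
    return results


def find_drivers(
    cnv: CopyNumberCallMatrix,
    expr_mrna: ExpressionMatrix,
    expr_lnc: ExpressionMatrix,
    alpha: float = 0.05,
    min_fraction: float = 0.10,
    binomial_alpha: float = 0.05,
    pre_cleaned: bool = False,
) -> tuple[pd.DataFrame, CopyNumberCallMatrix]:
    """Run the full driver stage; returns (results table, cleaned call matrix).

    The expression matrices are assumed to be prefiltered; genes absent from
    both matrices are not tested.
    """
    cleaned = cnv if pre_cleaned else clean_calls(cnv, min_fraction, binomial_alpha)
    rows = []
    for gene in cleaned.gene_ids:
        expr = expr_mrna if gene in expr_mrna.values.index else (
            expr_lnc if gene in expr_lnc.values.index else None)
        if expr is None:
            continue
        for res in test_cnv_driver(expr, status_grouping(cleaned, gene), alpha):
            rows.append(asdict(res) | {"feature_class": expr.feature_class})
    cols = ["gene_id", "direction", "ranksum_p", "median_aberrant", "median_normal",
            "concordant", "is_driver", "n_aberrant", "n_normal", "reason",
            "feature_class"]
    table = pd.DataFrame(rows, columns=cols)
    return table, cleaned
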