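"""Clinical association of CNV-driven ceRNAs: Kaplan-Meier / log-rank survival
by copy-number status, Cox proportional-hazards on expression (Efron ties),
and an exact r x c Fisher test against histological subtype.

The r x c Fisher p-value is the probability mass of all tables with the
observed margins whose multivariate-hypergeometric probability does not
exceed the observed table's (the standard two-sided definition for tables
larger than 2 x 2), computed by exact enumeration in log space.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ClinicalTable, CopyNumberCallMatrix
from scipy.special import gammaln

log = logging.getLogger(__name__)


@dataclass
class SurvivalStratum:
    label: str
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.size == 0:
            raise ValueError(f"stratum {self.label!r} is empty")
        if (self.times < 0).any():
            raise ValueError("survival times must be non-negative")


def km_estimate(stratum: SurvivalStratum) -> pd.Series:
    """Product-limit survival curve S(t) indexed by time (right-censoring
    handled); an all-censored stratum yields a flat curve at 1."""
    if stratum.events.sum() == 0:
        log.warning("stratum %r has no events; survival curve is flat", stratum.label)
    kmf = KaplanMeierFitter()
    kmf.fit(stratum.times, stratum.events, label=stratum.label)
    return kmf.survival_function_[stratum.label]


def logrank_test(a: SurvivalStratum, b: SurvivalStratum) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p."""
    if a.events.sum() + b.events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    clinical: ClinicalTable,
    covariates: list[str],
    mode: str = "univariate",
) -> pd.DataFrame:
    """Cox proportional-hazards fit(s) returning HR, Wald 95% CI and p per
    covariate. ``univariate`` fits each covariate alone; ``multivariate``
    enters them jointly."""
    df = clinical.table
    events = int(df["os_event"].sum())
    if events < 10 * (len(covariates) if mode == "multivariate" else 1):
        log.warning("few events (%d) for %d covariate(s); estimates may be unstable",
                    events, len(covariates))
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")

    def _one(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(df[["os_days", "os_event", *cols]], duration_col="os_days",
                event_col="os_event")
        s = cph.summary
        return pd.DataFrame({
            "covariate": s.index,
            "HR": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        })

    if mode == "multivariate":
        out = _one(list(covariates))
    elif mode == "univariate":
        out = pd.concat([_one([c]) for c in covariates], ignore_index=True)
    else:
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    out["mode"] = mode
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact r x c Fisher test
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("need at least a 2 x 2 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def _enumeration_bound(row_sums: np.ndarray, col_sums: np.ndarray) -> int:
    bound = 1
    for r in row_sums[:-1]:
        for c in col_sums[:-1]:
            bound *= int(min(r, c)) + 1
            if bound > 10**12:
                return bound
    return bound


def _iter_tables(row_sums: list[int], col_rem: list[int]):
    """Yield all non-negative integer tables with the given margins."""
    if len(row_sums) == 1:
        if all(v >= 0 for v in col_rem) and sum(col_rem) == row_sums[0]:
            yield [list(col_rem)]
        return
    r = row_sums[0]
    ranges = [range(0, min(r, c) + 1) for c in col_rem[:-1]]
    for head in itertools.product(*ranges):
        last = r - sum(head)
        if last < 0 or last > col_rem[-1]:
            continue
        row = [*head, last]
        rem = [c - x for c, x in zip(col_rem, row)]
        for rest in _iter_tables(row_sums[1:], rem):
            yield [row, *rest]


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray, budget: int = 10**7, rel_tol: float = 1e-7
) -> float:
    """Exact two-sided Fisher p for an r x c table: the total probability of
    all margin-preserving tables no more probable than the observed one
    (within relative tolerance ``rel_tol`` on the probability comparison)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty table")
    if _enumeration_bound(row_sums, col_sums) > budget:
        raise ValueError(
            "table too large for exact enumeration; use a Monte-Carlo fallback"
        )
    log_const = (
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    )

    def logprob(tbl: np.ndarray) -> float:
        return float(log_const - gammaln(tbl + 1.0).sum())

    lp_obs = logprob(counts)
    cutoff = lp_obs + np.log1p(rel_tol)
    total = 0.0
    for tbl in _iter_tables(list(map(int, row_sums)), list(map(int, col_sums))):
        lp = logprob(np.array(tbl))
        if lp <= cutoff:
            total += np.exp(lp)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# driver-level association
# ---------------------------------------------------------------------------


def strata_for_gene(
    cnv: CopyNumberCallMatrix, clinical: ClinicalTable, gene: str, state: int
) -> tuple[SurvivalStratum, SurvivalStratum, pd.Series]:
    """Carrier (state) vs neutral (0) survival strata for one gene; +/-1 calls
    are excluded. Also returns the per-sample carrier indicator."""
    calls = cnv.calls.loc[gene]
    shared = [s for s in clinical.sample_ids if s in calls.index]
    calls = calls.loc[shared]
    carrier_ids = calls.index[calls == state]
    neutral_ids = calls.index[calls == 0]
    tab = clinical.table
    carrier = SurvivalStratum(
        f"{gene} state {state}",
        tab.loc[carrier_ids, "os_days"].to_numpy(),
        tab.loc[carrier_ids, "os_event"].to_numpy(),
    )
    neutral = SurvivalStratum(
        f"{gene} neutral",
        tab.loc[neutral_ids, "os_days"].to_numpy(),
        tab.loc[neutral_ids, "os_event"].to_numpy(),
    )
    indicator = pd.Series(np.nan, index=pd.Index(shared))
    indicator.loc[carrier_ids] = 1.0
    indicator.loc[neutral_ids] = 0.0
    return carrier, neutral, indicator


def associate_cnv_clinical(
    drivers: pd.DataFrame,
    cnv: CopyNumberCallMatrix,
    target_expr: pd.DataFrame,
    clinical: ClinicalTable,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Per CNV-driven gene: log-rank p of carrier-vs-neutral survival, carrier
    hazard ratio, exact Fisher p of copy-number status vs subtype, and a
    univariate Cox fit on the gene's expression."""
    rows = []
    driver_rows = drivers[drivers["is_driver"]] if "is_driver" in drivers else drivers
    for _, d in driver_rows.iterrows():
        gene = d["gene_id"]
        state = 2 if d["direction"] == "amplification" else -2
        if gene not in cnv.calls.index:
            continue
        try:
            carrier, neutral, indicator = strata_for_gene(cnv, clinical, gene, state)
        except ValueError:
            log.info("gene %s: empty stratum, skipped", gene)
            continue
        if carrier.times.size < min_carriers:
            log.info("gene %s has %d carriers (< %d); skipped",
                     gene, carrier.times.size, min_carriers)
            continue
        chi2, lr_p = logrank_test(carrier, neutral)

        # carrier-status Cox HR
        sub = clinical.table.loc[indicator.dropna().index].copy()
        sub["carrier"] = indicator.dropna()
        hr_row = cox_fit(ClinicalTable(sub), ["carrier"], mode="univariate").iloc[0]

        # subtype contingency: rows = status (0, state), cols = subtypes
        subtypes = sorted(clinical.table["subtype"].unique())
        counts = np.array([
            [int(((indicator == s) & (clinical.table.loc[indicator.index, "subtype"] == st)).sum())
             for st in subtypes]
            for s in (0.0, 1.0)
        ])
        fisher_p = fisher_exact_rxc(ContingencyTable(["neutral", "carrier"], subtypes, counts))

        # expression Cox (univariate)
        expr_p = expr_hr = np.nan
        if gene in target_expr.index:
            sub2 = clinical.table.copy()
            expr_vec = target_expr.loc[gene].reindex(sub2.index)
            sub2["expr"] = expr_vec
            sub2 = sub2.dropna(subset=["expr"])
            if sub2["expr"].nunique() > 1:
                fit = cox_fit(ClinicalTable(sub2), ["expr"], mode="univariate").iloc[0]
                expr_hr, expr_p = fit["HR"], fit["p"]

        rows.append(dict(
            gene_id=gene, direction=d["direction"], n_carriers=carrier.times.size,
            n_neutral=neutral.times.size, logrank_chi2=chi2, logrank_p=lr_p,
            carrier_hr=hr_row["HR"], carrier_hr_p=hr_row["p"],
            fisher_subtype_p=fisher_p, expr_cox_hr=expr_hr, expr_cox_p=expr_p,
        ))
    cols = ["gene_id", "direction", "n_carriers", "n_neutral", "logrank_chi2",
            "logrank_p", "carrier_hr", "carrier_hr_p", "fisher_subtype_p",
            "expr_cox_hr", "expr_cox_p"]
    return pd.DataFrame(rows, columns=cols)
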