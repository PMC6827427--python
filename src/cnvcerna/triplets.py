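"""Candidate ceRNA triplet screening within one copy-number status.

A candidate triplet (ceRNA1, ceRNA2, shared miRNA) must show, over the samples
of one status: a significantly positive ceRNA-ceRNA Pearson correlation and
significantly negative miRNA-ceRNA correlations for both partners, with
Benjamini-Hochberg adjustment applied separately to the pair-correlation
family and the miRNA-target family of the screen.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, TargetInteractionSet

log = logging.getLogger(__name__)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r over pairwise-complete observations with the two-sided p-value
    from the t-distribution on n-2 df. Returns (nan, nan) for degenerate input
    (fewer than 3 complete pairs or a constant vector)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        return (np.nan, np.nan)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return (np.nan, np.nan)
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return (r, p)


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries left NaN and
    excluded from the family size)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class CandidateTriplet:
    cerna1_id: str  # canonical: cerna1_id < cerna2_id
    cerna2_id: str
    mirna_id: str
    status: str  # amplification | deletion | normal
    r_pair: float
    q_pair: float
    r_mi1: float
    q_mi1: float
    r_mi2: float
    q_mi2: float
    n_samples_used: int


def shared_mirna_pairs(
    targets: TargetInteractionSet, features: set[str]
) -> dict[tuple[str, str], set[str]]:
    """All canonical target pairs sharing at least one miRNA, restricted to
    features present in the expression data."""
    pairs: dict[tuple[str, str], set[str]] = {}
    for mirna, ts in targets.targets_by_mirna().items():
        present = sorted(ts & features)
        for a, b in itertools.combinations(present, 2):
            pairs.setdefault((a, b), set()).add(mirna)
    return pairs


def find_candidate_triplets(
    target_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    targets: TargetInteractionSet,
    samples: set[str] | list[str],
    status_label: str,
    q_threshold: float = 0.05,
    min_samples: int = 5,
    pair_mirnas: dict[tuple[str, str], set[str]] | None = None,
) -> list[CandidateTriplet]:
    """Screen one status. ``target_expr`` holds mRNA and lncRNA rows together
    (features x samples); ``mirna_expr`` the miRNA rows."""
    cols = [s for s in target_expr.columns if s in set(samples)]
    if len(cols) < min_samples:
        log.info("status %s has %d samples (< %d); no triplets",
                 status_label, len(cols), min_samples)
        return []
    features = set(target_expr.index)
    if pair_mirnas is None:
        pair_mirnas = shared_mirna_pairs(targets, features)
    if not pair_mirnas:
        return []

    T = target_expr[cols]
    M = mirna_expr[cols]
    n = len(cols)

    pair_list = sorted(pair_mirnas)
    pair_stats = {
        pq: pearson(T.loc[pq[0]].to_numpy(), T.loc[pq[1]].to_numpy())
        for pq in pair_list
    }
    mt_keys = sorted({
        (m, t) for pq, ms in pair_mirnas.items() for m in ms for t in pq
        if m in M.index
    })
    mt_stats = {
        (m, t): pearson(M.loc[m].to_numpy(), T.loc[t].to_numpy())
        for m, t in mt_keys
    }

    q_pair = dict(zip(pair_list, bh_adjust([pair_stats[pq][1] for pq in pair_list])))
    q_mt = dict(zip(mt_keys, bh_adjust([mt_stats[k][1] for k in mt_keys])))

    out: list[CandidateTriplet] = []
    for (a, b), mirnas in pair_mirnas.items():
        r_ab, _ = pair_stats[(a, b)]
        if not (np.isfinite(r_ab) and r_ab > 0 and q_pair[(a, b)] < q_threshold):
            continue
        for m in sorted(mirnas):
            if (m, a) not in mt_stats or (m, b) not in mt_stats:
                continue
            r1, _ = mt_stats[(m, a)]
            r2, _ = mt_stats[(m, b)]
            if (
                np.isfinite(r1) and r1 < 0 and q_mt[(m, a)] < q_threshold
                and np.isfinite(r2) and r2 < 0 and q_mt[(m, b)] < q_threshold
            ):
                out.append(CandidateTriplet(
                    a, b, m, status_label,
                    r_pair=r_ab, q_pair=float(q_pair[(a, b)]),
                    r_mi1=r1, q_mi1=float(q_mt[(m, a)]),
                    r_mi2=r2, q_mi2=float(q_mt[(m, b)]),
                    n_samples_used=n,
                ))
    return out


def triplets_to_frame(triplets: list[CandidateTriplet]) -> pd.DataFrame:
    import dataclasses

    cols = [f.name for f in dataclasses.fields(CandidateTriplet)]
    return pd.DataFrame([dataclasses.asdict(t) for t in triplets], columns=cols)
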