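"""The dysregulation statistic dR = |cor_v - cor_n| and its permutation test.

cor_v is the ceRNA-pair Pearson correlation in the aberrant-state samples of
one CNV-driven gene, cor_n the correlation in that gene's copy-neutral
samples. Significance is assessed by shuffling the aberrant/neutral labels
(group sizes preserved) and recomputing dR; the add-one Monte-Carlo p-value
keeps p > 0. A pair whose correlation rises in the aberrant state is
*enhanced*, one whose correlation falls is *weakened*.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .triplets import CandidateTriplet, pearson

log = logging.getLogger(__name__)

ENHANCED, WEAKENED = "enhanced", "weakened"


def delta_r(cor_v: float, cor_n: float) -> tuple[float, str]:
    """|cor_v - cor_n| and the dysregulation direction (ties count as weakened)."""
    delta = abs(cor_v - cor_n)
    if cor_v == cor_n:
        log.debug("tied correlations (%.4f); direction set to weakened", cor_v)
    return float(delta), (ENHANCED if cor_v > cor_n else WEAKENED)


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X with the matching row of Y."""
    n = X.shape[1]
    sx = X.sum(axis=1)
    sy = Y.sum(axis=1)
    sxx = np.einsum("ij,ij->i", X, X)
    syy = np.einsum("ij,ij->i", Y, Y)
    sxy = np.einsum("ij,ij->i", X, Y)
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(den)
    r[den <= 0] = np.nan
    return r


def _seed_for(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-(driver, pair) substream, reproducible under any
    execution order."""
    parts = [seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(parts))


def permutation_test(
    expr1: pd.Series | np.ndarray,
    expr2: pd.Series | np.ndarray,
    aberrant_samples: set[str] | list[str],
    normal_samples: set[str] | list[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 50,
) -> tuple[float, float, float, float]:
    """Label-permutation test of dR for one ceRNA pair.

    Returns (perm_p, delta_obs, cor_v, cor_n). Permutations that produce a
    degenerate (constant) subgroup are redrawn; perm_p uses the add-one rule
    (1 + #{dR_perm >= dR_obs}) / (n_perm + 1) and is therefore never 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ab = sorted(aberrant_samples)
    no = sorted(normal_samples)
    if isinstance(expr1, pd.Series):
        x = expr1.reindex(ab + no).to_numpy(dtype=float)
        y = expr2.reindex(ab + no).to_numpy(dtype=float)
    else:
        x = np.asarray(expr1, dtype=float)
        y = np.asarray(expr2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    na = int(ok[: len(ab)].sum())
    x, y = x[ok], y[ok]
    ntot = x.size

    cor_v, _ = pearson(x[:na], y[:na])
    cor_n, _ = pearson(x[na:], y[na:])
    if not (np.isfinite(cor_v) and np.isfinite(cor_n)):
        raise ValueError("observed correlation undefined (constant or tiny group)")
    d_obs, _ = delta_r(cor_v, cor_n)

    idx = rng.permuted(
        np.broadcast_to(np.arange(ntot), (n_perm, ntot)).copy(), axis=1
    )
    xa, ya = x[idx[:, :na]], y[idx[:, :na]]
    xn, yn = x[idx[:, na:]], y[idx[:, na:]]
    d_perm = np.abs(_rowwise_pearson(xa, ya) - _rowwise_pearson(xn, yn))

    redraws = 0
    bad = ~np.isfinite(d_perm)
    while bad.any() and redraws < max_redraws:
        redraws += 1
        k = int(bad.sum())
        idx = rng.permuted(np.broadcast_to(np.arange(ntot), (k, ntot)).copy(), axis=1)
        d_perm[bad] = np.abs(
            _rowwise_pearson(x[idx[:, :na]], y[idx[:, :na]])
            - _rowwise_pearson(x[idx[:, na:]], y[idx[:, na:]])
        )
        bad = ~np.isfinite(d_perm)
    if bad.any():
        log.warning("%d degenerate permutations remained after %d redraws",
                    int(bad.sum()), max_redraws)
        d_perm = d_perm[~bad]
    # tolerance so permutations reproducing the observed labelling count as
    # ties despite a different floating-point summation order
    perm_p = float((1 + np.sum(d_perm >= d_obs - 1e-9)) / (d_perm.size + 1))
    return perm_p, d_obs, cor_v, cor_n


def fisher_z_test(cor_v: float, cor_n: float, n_v: int, n_n: int) -> tuple[float, float]:
    """Analytic differential-correlation z-test (Fisher transform).

    Cross-check utility only; the pipeline's significance call is the
    label-permutation test.
    """
    if min(n_v, n_n) < 4:
        raise ValueError("need at least 4 samples per group")
    z = (np.arctanh(cor_v) - np.arctanh(cor_n)) / np.sqrt(
        1.0 / (n_v - 3) + 1.0 / (n_n - 3))
    from scipy import stats

    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class DysregulatedPair:
    cerna1_id: str
    cerna2_id: str
    driver_gene_id: str
    driver_state: str  # amplification | deletion
    cor_v: float
    cor_n: float
    delta_r: float
    direction: str  # enhanced | weakened
    perm_p: float
    n_perm: int
    supporting_mirnas: set[str] = field(default_factory=set)


def call_dysregulated_pairs(
    triplets_by_status: dict[str, list[CandidateTriplet]],
    driver_gene_id: str,
    driver_state: str,
    target_expr: pd.DataFrame,
    aberrant_samples: set[str],
    normal_samples: set[str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_samples: int = 5,
) -> tuple[list[DysregulatedPair], pd.DataFrame]:
    """Test every pair that qualified as a candidate in the driver's aberrant
    status and/or its neutral status. A pair seen in only one status still has
    its other-status correlation computed from that status's samples. Returns
    (significant pairs, table of all tested pairs)."""
    pair_mirnas: dict[tuple[str, str], set[str]] = {}
    for status in (driver_state, "normal"):
        for t in triplets_by_status.get(status, []):
            pair_mirnas.setdefault((t.cerna1_id, t.cerna2_id), set()).add(t.mirna_id)
    if len(aberrant_samples) < min_samples or len(normal_samples) < min_samples:
        return [], pd.DataFrame()

    significant: list[DysregulatedPair] = []
    rows = []
    for (a, b), mirnas in sorted(pair_mirnas.items()):
        rng = _seed_for(seed, driver_gene_id, f"{a}|{b}")
        try:
            perm_p, d_obs, cor_v, cor_n = permutation_test(
                target_expr.loc[a], target_expr.loc[b],
                aberrant_samples, normal_samples, n_perm=n_perm, seed=rng,
            )
        except ValueError as exc:
            log.info("pair (%s, %s) skipped for driver %s: %s", a, b, driver_gene_id, exc)
            continue
        _, direction = delta_r(cor_v, cor_n)
        rows.append(dict(
            cerna1_id=a, cerna2_id=b, driver_gene_id=driver_gene_id,
            driver_state=driver_state, cor_v=cor_v, cor_n=cor_n,
            delta_r=d_obs, direction=direction, perm_p=perm_p, n_perm=n_perm,
            supporting_mirnas=",".join(sorted(mirnas)),
            significant=perm_p < alpha,
        ))
        if perm_p < alpha:
            significant.append(DysregulatedPair(
                a, b, driver_gene_id, driver_state, cor_v, cor_n,
                d_obs, direction, perm_p, n_perm, set(mirnas),
            ))
    cols = ["cerna1_id", "cerna2_id", "driver_gene_id", "driver_state", "cor_v",
            "cor_n", "delta_r", "direction", "perm_p", "n_perm",
            "supporting_mirnas", "significant"]
    return significant, pd.DataFrame(rows, columns=cols)
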