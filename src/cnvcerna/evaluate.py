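"""Recovery and calibration measurements on synthetic cohorts.

These helpers run the core analysis stages (drivers -> triplet screens ->
permutation tests) in memory on a generated cohort and score the result
against the generator's planted truth. They are the basis of the package's
self-validation: type-I error of the driver test on null cohorts, uniformity
of the permutation p-values on null pairs, and recall of planted drivers and
dysregulated pairs under the default study conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import drivers as drv
from . import dysregulation as dys
from .simulate import SyntheticCohort
from .triplets import find_candidate_triplets, shared_mirna_pairs


def run_core(
    cohort: SyntheticCohort,
    driver_alpha: float = 0.05,
    corr_q: float = 0.05,
    perm_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_samples: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drivers -> screens -> permutation tests, without touching disk.

    Returns (driver table, tested-pair table with a ``significant`` column).
    """
    mrna = drv.filter_expression(cohort.mrna)
    lnc = drv.filter_expression(cohort.lncrna)
    mirna = drv.filter_expression(cohort.mirna)
    driver_table, cleaned = drv.find_drivers(cohort.cnv, mrna, lnc,
                                             alpha=driver_alpha)
    target_expr = pd.concat([mrna.values, lnc.values])
    pair_mirnas = shared_mirna_pairs(cohort.interactions, set(target_expr.index))
    frames = []
    for _, d in driver_table[driver_table["is_driver"]].iterrows():
        grouping = drv.status_grouping(cleaned, d["gene_id"])
        aberrant = (grouping.amplified_samples if d["direction"] == drv.AMP
                    else grouping.deleted_samples)
        by_status = {
            label: find_candidate_triplets(
                target_expr, mirna.values, cohort.interactions, samples, label,
                q_threshold=corr_q, min_samples=min_samples,
                pair_mirnas=pair_mirnas)
            for label, samples in ((d["direction"], aberrant),
                                   ("normal", grouping.normal_samples))
        }
        _, tested = dys.call_dysregulated_pairs(
            by_status, d["gene_id"], d["direction"], target_expr,
            aberrant, grouping.normal_samples,
            alpha=perm_alpha, n_perm=n_perm, seed=seed, min_samples=min_samples)
        if len(tested):
            frames.append(tested)
    tested_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cerna1_id", "cerna2_id", "driver_gene_id", "driver_state",
                 "cor_v", "cor_n", "delta_r", "direction", "perm_p", "n_perm",
                 "supporting_mirnas", "significant"])
    return driver_table, tested_all


def recovery_metrics(
    cohort: SyntheticCohort, n_perm: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Recall of planted drivers / pairs and direction accuracy of the
    recovered pairs, at the pipeline's standard thresholds."""
    driver_table, tested = run_core(cohort, n_perm=n_perm, seed=seed)
    hits = driver_table[driver_table["is_driver"]]
    found = set(zip(hits["gene_id"], hits["direction"]))
    planted = {(t["gene"], t["direction"]) for t in cohort.truth.planted_drivers}
    driver_recall = len(planted & found) / len(planted) if planted else np.nan

    sig = tested[tested["significant"]] if len(tested) else tested
    recovered = direction_ok = 0
    for t in cohort.truth.planted_pairs:
        a, b = sorted((t["cerna1"], t["cerna2"]))
        rows = sig[(sig["cerna1_id"] == a) & (sig["cerna2_id"] == b)
                   & (sig["driver_gene_id"] == t["driver"])] if len(sig) else []
        if len(rows):
            recovered += 1
            if (rows["direction"] == t["direction"]).any():
                direction_ok += 1
    n_planted = len(cohort.truth.planted_pairs)
    return dict(
        driver_recall=driver_recall,
        pair_recall=recovered / n_planted if n_planted else np.nan,
        direction_accuracy=direction_ok / recovered if recovered else np.nan,
        n_planted_pairs=n_planted,
        n_recovered_pairs=recovered,
        n_significant_pairs=int(sig["significant"].sum()) if len(sig) else 0,
    )


def null_driver_rates(cohort: SyntheticCohort, alpha: float = 0.05) -> dict[str, float]:
    """Type-I error of the rank-sum driver test on a null cohort: the fraction
    of tested (gene, direction) units with p below alpha, and the stricter
    concordance-gated call rate."""
    mrna = drv.filter_expression(cohort.mrna)
    lnc = drv.filter_expression(cohort.lncrna)
    table, _ = drv.find_drivers(cohort.cnv, mrna, lnc, alpha=alpha)
    tested = table[table["ranksum_p"].notna()]
    return dict(
        n_tested=len(tested),
        p_rate=float((tested["ranksum_p"] < alpha).mean()),
        call_rate=float(tested["is_driver"].mean()),
    )


def null_permutation_pvalues(
    cohort: SyntheticCohort,
    max_pairs: int = 2000,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values of dR on the cohort's declared null pairs, using
    the first driver gene's carrier/neutral grouping as the labels."""
    gene = cohort.cnv.gene_ids[0]
    calls = cohort.cnv.calls.loc[gene]
    aberrant = set(calls.index[calls.abs() == 2])
    neutral = set(calls.index[calls == 0])
    expr = pd.concat([cohort.mrna.values, cohort.lncrna.values])
    ps = []
    for pair in cohort.truth.null_pairs[:max_pairs]:
        rng = dys._seed_for(seed, gene, f"{pair['cerna1']}|{pair['cerna2']}")
        p, *_ = dys.permutation_test(
            expr.loc[pair["cerna1"]], expr.loc[pair["cerna2"]],
            aberrant, neutral, n_perm=n_perm, seed=rng)
        ps.append(p)
    return np.asarray(ps)


def mean_recovered_pairs_over_seeds(
    base_config, attenuation: float, seeds: range, n_perm: int = 200
) -> float:
    """Mean number of recovered planted pairs across seeds at one attenuation
    level (used for the effect-size monotonicity property)."""
    from .simulate import generate_cohort

    counts = []
    for seed in seeds:
        cfg = dataclasses.replace(base_config, seed=seed,
                                  dysregulation_attenuation=attenuation)
        m = recovery_metrics(generate_cohort(cfg), n_perm=n_perm, seed=seed)
        counts.append(m["n_recovered_pairs"])
    return float(np.mean(counts))
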