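"""Synthetic glioma-like cohorts with planted CNV-driven ceRNA dysregulation.

The generator realises the structure the analysis assumes, with ground truth:

* a minority of samples carries a high-level copy-number event (+2 or -2) per
  driver gene, and the driver's expression is dose-shifted by the event;
* each miRNA has a latent per-sample activity; its targets receive a negative
  contribution of that activity, so miRNA-target correlations are negative and
  two targets sharing a miRNA are positively correlated (the ceRNA signature);
* for planted *weakened* pairs the miRNA coupling of both partners is
  multiplied by ``dysregulation_attenuation`` in the driver's aberrant samples
  only (and by ``enhancement_factor`` for planted *enhanced* pairs), which is
  exactly the condition-specific decoupling the pipeline is built to detect;
* overall survival is exponential with a log-hazard that may depend on one
  driver's carrier status; histological subtype frequencies may also depend on
  that status so the clinical association stage has signal.

Identical seed => bit-identical output. A ``null`` cohort keeps the whole
correlation structure and the CNV calls but removes every CNV-dependent
effect, so downstream p-values are calibrated against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CopyNumberCallMatrix,
    ExpressionMatrix,
    TargetInteractionSet,
    write_clinical,
    write_cnv_calls,
    write_expression_matrix,
    write_interactions,
)

SUBTYPES = ("Astrocytoma", "Oligoastrocytoma", "Oligodendroglioma")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions used throughout."""

    n_samples: int = 300
    n_mrna: int = 200
    n_lncrna: int = 40
    n_mirna: int = 60
    n_driver_genes: int = 10
    n_weakened_pairs: int = 20
    n_enhanced_pairs: int = 0
    cnv_carrier_fraction: float = 0.15
    cnv_expression_effect: float = 1.5  # log2-units mean shift at state +/-2
    mirna_coupling: float = 0.8
    dysregulation_attenuation: float = 0.2
    enhancement_factor: float = 2.0
    targets_per_mirna: int = 4
    noise_sd: float = 0.3
    survival_log_hr: float = 0.7  # extra log-hazard for carriers of the survival driver
    survival_driver_index: int = 1
    subtype_association: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mrna", "n_lncrna", "n_mirna",
                     "n_driver_genes", "targets_per_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cnv_carrier_fraction < 1:
            raise ValueError("cnv_carrier_fraction must be in (0, 1)")
        if not 0 < self.mirna_coupling < 1:
            raise ValueError("mirna_coupling must be in (0, 1)")
        if not 0 <= self.dysregulation_attenuation <= 1:
            raise ValueError("dysregulation_attenuation must be in [0, 1]")
        if self.enhancement_factor < 1:
            raise ValueError("enhancement_factor must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if round(self.n_samples * self.cnv_carrier_fraction) < 3:
            raise ValueError("carrier count < 3 after rounding; correlations undefined")


@dataclass
class SyntheticTruth:
    """What was planted, for recall/precision scoring downstream."""

    planted_drivers: list[dict]  # {gene, direction}
    planted_pairs: list[dict]  # {cerna1, cerna2, mirna, driver, direction}
    null_pairs: list[dict]  # {cerna1, cerna2, mirna}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["planted_drivers"], d["planted_pairs"], d["null_pairs"])


@dataclass
class SyntheticCohort:
    cnv: CopyNumberCallMatrix
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    interactions: TargetInteractionSet
    clinical: ClinicalTable
    truth: SyntheticTruth
    config: SimulationConfig


def _subtype_probs(carrier: bool, associated: bool) -> np.ndarray:
    if associated and carrier:
        return np.array([0.65, 0.20, 0.15])
    return np.array([0.30, 0.30, 0.40])


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort (CNV calls, three expression matrices, interactions,
    clinical table) plus the planted truth, deterministically from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    mrna_ids = [f"M{i:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"L{i:04d}" for i in range(cfg.n_lncrna)]
    mi_ids = [f"MI{i:04d}" for i in range(cfg.n_mirna)]
    feat_class = {**{g: "mRNA" for g in mrna_ids}, **{g: "lncRNA" for g in lnc_ids}}

    n_pairs = cfg.n_weakened_pairs + cfg.n_enhanced_pairs
    if cfg.n_driver_genes > cfg.n_mrna:
        raise ValueError("n_driver_genes exceeds n_mrna")
    if n_pairs > cfg.n_mirna:
        raise ValueError("need one dedicated miRNA per planted pair")

    # --- role assignment (deterministic given id ordering) -----------------
    drivers = mrna_ids[: cfg.n_driver_genes]
    driver_dir = {g: ("amplification" if i % 2 == 0 else "deletion")
                  for i, g in enumerate(drivers)}

    pair_mirnas = mi_ids[:n_pairs]
    bg_mirnas = mi_ids[n_pairs:]
    # dedicated planted targets: pairs of features after the drivers; every 4th
    # pair uses a lncRNA partner so lncRNA ceRNAs are exercised
    pool = mrna_ids[cfg.n_driver_genes:]
    lnc_pool = list(lnc_ids)
    planted_targets: list[tuple[str, str]] = []
    pi = 0
    for k in range(n_pairs):
        t1 = pool[pi]; pi += 1
        if k % 4 == 3 and lnc_pool:
            t2 = lnc_pool.pop(0)
        else:
            t2 = pool[pi]; pi += 1
        planted_targets.append((t1, t2))
    if pi > len(pool):
        raise ValueError("not enough mRNAs for planted pair targets")

    used = set(drivers) | {t for p in planted_targets for t in p}
    bg_pool = [g for g in mrna_ids + lnc_ids if g not in used]
    if len(bg_pool) < cfg.targets_per_mirna:
        raise ValueError("background target pool smaller than targets_per_mirna")

    bg_targets: dict[str, list[str]] = {}
    for m in bg_mirnas:
        bg_targets[m] = list(rng.choice(bg_pool, size=cfg.targets_per_mirna, replace=False))

    # --- CNV calls ----------------------------------------------------------
    genes = mrna_ids + lnc_ids
    calls = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    n_carriers = int(round(n * cfg.cnv_carrier_fraction))
    carrier_sets: dict[str, np.ndarray] = {}
    for g in drivers:
        idx = rng.choice(n, size=n_carriers, replace=False)
        carrier_sets[g] = idx
        calls.iloc[calls.index.get_loc(g), idx] = 2 if driver_dir[g] == "amplification" else -2

    non_driver = [g for g in genes if g not in drivers]
    # low-level calls on ~10% of non-driver genes: exercised by the +/-1 recode
    for g in rng.choice(non_driver, size=max(1, len(non_driver) // 10), replace=False):
        idx = rng.choice(n, size=max(3, n // 8), replace=False)
        calls.loc[g, calls.columns[idx]] = rng.choice([-1, 1])
    # rare high-level calls below the recurrence filter on ~2% of genes
    rare = rng.choice([g for g in non_driver if (calls.loc[g] == 0).all()],
                      size=max(1, len(non_driver) // 50), replace=False)
    for g in rare:
        idx = rng.choice(n, size=max(1, n // 25), replace=False)
        calls.loc[g, calls.columns[idx]] = rng.choice([-2, 2])
    # mixed-state decoys: majority +2 with a tiny -2 minority (binomial cleanup
    # zeroes the minority) and a balanced +2/-2 gene (binomial removes the gene)
    mixed_pool = [g for g in non_driver if (calls.loc[g] == 0).all()]
    if len(mixed_pool) >= 2:
        g_min, g_bal = mixed_pool[0], mixed_pool[1]
        idx = rng.permutation(n)
        k = max(4, int(round(0.12 * n)))
        calls.loc[g_min, calls.columns[idx[:k]]] = 2
        calls.loc[g_min, calls.columns[idx[k:k + 2]]] = -2
        kb = max(4, int(round(0.08 * n)))
        calls.loc[g_bal, calls.columns[idx[:kb]]] = 2
        calls.loc[g_bal, calls.columns[idx[kb:2 * kb]]] = -2

    # --- expression ---------------------------------------------------------
    activity = rng.normal(size=(cfg.n_mirna, n))  # latent miRNA activities
    act = pd.DataFrame(activity, index=mi_ids, columns=samples)

    def baseline(ids: list[str]) -> np.ndarray:
        return rng.normal(6.0, 0.5, size=len(ids))[:, None]

    expr = pd.DataFrame(
        baseline(genes) + rng.normal(0, cfg.noise_sd, size=(len(genes), n)),
        index=genes, columns=samples,
    )
    for g in drivers:
        state = calls.loc[g].to_numpy()
        expr.loc[g] += cfg.cnv_expression_effect * state / 2.0

    planted_pairs: list[dict] = []
    for k, ((t1, t2), m) in enumerate(zip(planted_targets, pair_mirnas)):
        direction = "weakened" if k < cfg.n_weakened_pairs else "enhanced"
        driver = drivers[k % len(drivers)]
        factor = (cfg.dysregulation_attenuation if direction == "weakened"
                  else cfg.enhancement_factor)
        coupling = np.full(n, cfg.mirna_coupling)
        coupling[carrier_sets[driver]] = cfg.mirna_coupling * factor
        for t in (t1, t2):
            expr.loc[t] -= coupling * act.loc[m].to_numpy()
        planted_pairs.append(
            dict(cerna1=t1, cerna2=t2, mirna=m, driver=driver, direction=direction)
        )

    null_pairs: list[dict] = []
    for m, targets in bg_targets.items():
        for t in targets:
            expr.loc[t] -= cfg.mirna_coupling * act.loc[m].to_numpy()
        for i in range(len(targets)):
            for j in range(i + 1, len(targets)):
                a, b = sorted((targets[i], targets[j]))
                null_pairs.append(dict(cerna1=a, cerna2=b, mirna=m))

    mirna_expr = pd.DataFrame(
        baseline(mi_ids) + activity + rng.normal(0, cfg.noise_sd, size=(cfg.n_mirna, n)),
        index=mi_ids, columns=samples,
    )

    expr = expr.clip(lower=0.0)
    mirna_expr = mirna_expr.clip(lower=0.0)
    assert (expr.std(axis=1) > 0).all() and (mirna_expr.std(axis=1) > 0).all(), \
        "zero-variance expression row emitted"

    # --- interactions -------------------------------------------------------
    rows = [(m, t, feat_class[t])
            for p, m in zip(planted_targets, pair_mirnas) for t in p]
    rows += [(m, t, feat_class[t]) for m, ts in bg_targets.items() for t in ts]
    interactions = TargetInteractionSet(
        pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])
    )

    # --- clinical -----------------------------------------------------------
    surv_driver = drivers[cfg.survival_driver_index % len(drivers)]
    carrier = np.zeros(n, dtype=bool)
    carrier[carrier_sets[surv_driver]] = True
    lam = np.log(2) / 800.0 * np.exp(cfg.survival_log_hr * carrier)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(100.0, 2500.0, size=n)
    os_days = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    subtype = np.array([
        SUBTYPES[rng.choice(3, p=_subtype_probs(bool(c), cfg.subtype_association))]
        for c in carrier
    ])
    clinical = ClinicalTable(pd.DataFrame(
        {"os_days": np.round(os_days, 1), "os_event": os_event, "subtype": subtype},
        index=pd.Index(samples, name="sample_id"),
    ))

    effects_on = (cfg.cnv_expression_effect != 0)
    truth = SyntheticTruth(
        planted_drivers=[{"gene": g, "direction": driver_dir[g]} for g in drivers]
        if effects_on else [],
        planted_pairs=[p for p in planted_pairs
                       if (p["direction"] == "weakened" and cfg.dysregulation_attenuation < 1)
                       or (p["direction"] == "enhanced" and cfg.enhancement_factor > 1)],
        null_pairs=null_pairs + [
            {"cerna1": min(p["cerna1"], p["cerna2"]),
             "cerna2": max(p["cerna1"], p["cerna2"]), "mirna": p["mirna"]}
            for p in planted_pairs
            if not ((p["direction"] == "weakened" and cfg.dysregulation_attenuation < 1)
                    or (p["direction"] == "enhanced" and cfg.enhancement_factor > 1))
        ],
    )

    return SyntheticCohort(
        cnv=CopyNumberCallMatrix(calls),
        mrna=ExpressionMatrix(expr.loc[mrna_ids].copy(), "mRNA"),
        lncrna=ExpressionMatrix(expr.loc[lnc_ids].copy(), "lncRNA"),
        mirna=ExpressionMatrix(mirna_expr, "miRNA"),
        interactions=interactions,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Same cohort machinery with every CNV-dependent effect neutralised:
    expression ignores copy number, coupling is status-independent, survival
    and subtype are independent of carrier status."""
    neutral = dataclasses.replace(
        config,
        cnv_expression_effect=0.0,
        dysregulation_attenuation=1.0,
        enhancement_factor=1.0,
        survival_log_hr=0.0,
        subtype_association=False,
    )
    return generate_cohort(neutral)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all five pipeline input files plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cnv": outdir / "cnv_calls.tsv",
        "mrna": outdir / "expr_mrna.tsv",
        "lncrna": outdir / "expr_lncrna.tsv",
        "mirna": outdir / "expr_mirna.tsv",
        "interactions": outdir / "interactions.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_cnv_calls(cohort.cnv, paths["cnv"])
    write_expression_matrix(cohort.mrna, paths["mrna"])
    write_expression_matrix(cohort.lncrna, paths["lncrna"])
    write_expression_matrix(cohort.mirna, paths["mirna"])
    write_interactions(cohort.interactions, paths["interactions"])
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth.to_json(paths["truth"])
    return paths
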