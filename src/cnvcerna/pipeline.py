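"""End-to-end orchestration: drivers -> triplets -> dysregulation -> network /
communities -> enrichment -> clinical, from one config and one seed."""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clinical as clin
from . import drivers as drv
from . import dysregulation as dys
from . import enrichment as enr
from . import network as net
from .io import (
    read_clinical,
    read_cnv_calls,
    read_expression_matrix,
    read_gmt,
    read_interactions,
    write_json,
)
from .triplets import find_candidate_triplets, shared_mirna_pairs, triplets_to_frame

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Input paths and every threshold of the analysis."""

    cnv_path: str | Path
    expr_mrna_path: str | Path
    expr_lncrna_path: str | Path
    expr_mirna_path: str | Path
    interactions_path: str | Path
    clinical_path: str | Path | None = None
    gmt_path: str | Path | None = None
    out_dir: str | Path = "results"
    driver_alpha: float = 0.05
    corr_q: float = 0.05
    perm_alpha: float = 0.05
    n_perm: int = 1000
    min_cnv_fraction: float = 0.10
    min_expr_fraction: float = 0.30
    max_missing_fraction: float = 0.10
    binomial_alpha: float = 0.05
    min_samples_per_status: int = 5
    run_clinical: bool = True
    run_enrichment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("driver_alpha", "corr_q", "perm_alpha", "min_cnv_fraction",
                     "min_expr_fraction", "max_missing_fraction", "binomial_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str = ""
    n_samples: int = 0
    n_drivers: int = 0
    n_candidate_triplets: int = 0
    n_dysregulated_pairs: int = 0
    pair_counts: list[dict] = field(default_factory=list)  # per (driver state): enhanced/weakened

    def check_consistency(self) -> None:
        total = sum(c["enhanced"] + c["weakened"] for c in self.pair_counts)
        if total != self.n_dysregulated_pairs:
            raise AssertionError("manifest pair counts inconsistent")


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_all(config: PipelineConfig) -> RunManifest:
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in dataclasses.asdict(cfg).items()},
        version=__version__,
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    # ---- load & prefilter -------------------------------------------------
    try:
        cnv = read_cnv_calls(cfg.cnv_path)
        mrna = drv.filter_expression(
            read_expression_matrix(cfg.expr_mrna_path, "mRNA"),
            cfg.min_expr_fraction, cfg.max_missing_fraction)
        lnc = drv.filter_expression(
            read_expression_matrix(cfg.expr_lncrna_path, "lncRNA"),
            cfg.min_expr_fraction, cfg.max_missing_fraction)
        mirna = drv.filter_expression(
            read_expression_matrix(cfg.expr_mirna_path, "miRNA"),
            cfg.min_expr_fraction, cfg.max_missing_fraction)
        interactions = read_interactions(cfg.interactions_path)
        sample_sets = {tuple(sorted(m.sample_ids))
                       for m in (mrna, lnc, mirna)} | {tuple(sorted(cnv.sample_ids))}
        if len(sample_sets) != 1:
            raise ValueError("inconsistent sample ids across input matrices")
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc
    manifest.n_samples = len(mrna.sample_ids)

    # ---- drivers ----------------------------------------------------------
    try:
        driver_table, cleaned = drv.find_drivers(
            cnv, mrna, lnc, alpha=cfg.driver_alpha,
            min_fraction=cfg.min_cnv_fraction, binomial_alpha=cfg.binomial_alpha)
        driver_table.to_csv(out / "drivers.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("drivers", exc) from exc
    hits = driver_table[driver_table["is_driver"]]
    manifest.n_drivers = len(hits)
    log.info("drivers: %d/%d tested units significant", len(hits), len(driver_table))

    # ---- triplets & dysregulation -----------------------------------------
    target_expr = pd.concat([mrna.values, lnc.values])
    feature_class = {**{g: "mRNA" for g in mrna.feature_ids},
                     **{g: "lncRNA" for g in lnc.feature_ids}}
    pair_mirnas = shared_mirna_pairs(interactions, set(target_expr.index))
    all_triplets, all_pairs, tested_frames = [], [], []
    try:
        for _, d in hits.iterrows():
            grouping = drv.status_grouping(cleaned, d["gene_id"])
            aberrant = (grouping.amplified_samples if d["direction"] == drv.AMP
                        else grouping.deleted_samples)
            statuses = {d["direction"]: aberrant, "normal": grouping.normal_samples}
            by_status = {}
            for label, samples in statuses.items():
                trip = find_candidate_triplets(
                    target_expr, mirna.values, interactions, samples, label,
                    q_threshold=cfg.corr_q, min_samples=cfg.min_samples_per_status,
                    pair_mirnas=pair_mirnas)
                by_status[label] = trip
                for t in trip:
                    all_triplets.append(dataclasses.asdict(t) | {"driver_gene_id": d["gene_id"]})
            sig, tested = dys.call_dysregulated_pairs(
                by_status, d["gene_id"], d["direction"], target_expr,
                aberrant, grouping.normal_samples,
                alpha=cfg.perm_alpha, n_perm=cfg.n_perm, seed=cfg.seed,
                min_samples=cfg.min_samples_per_status)
            all_pairs.extend(sig)
            if len(tested):
                tested_frames.append(tested)
    except Exception as exc:  # noqa: BLE001
        raise StageError("dysregulation", exc) from exc

    pd.DataFrame(all_triplets).to_csv(out / "triplets.tsv", sep="\t", index=False)
    tested_all = (pd.concat(tested_frames, ignore_index=True)
                  if tested_frames else pd.DataFrame())
    tested_all.to_csv(out / "pairs_tested.tsv", sep="\t", index=False)
    sig_frame = tested_all[tested_all["significant"]] if len(tested_all) else tested_all
    sig_frame.to_csv(out / "pairs.tsv", sep="\t", index=False)
    manifest.n_candidate_triplets = len(all_triplets)
    manifest.n_dysregulated_pairs = len(all_pairs)
    if len(sig_frame):
        counts = (sig_frame.groupby(["driver_state", "direction"]).size()
                  .unstack(fill_value=0))
        for state in counts.index:
            manifest.pair_counts.append(dict(
                driver_state=state,
                enhanced=int(counts.loc[state].get("enhanced", 0)),
                weakened=int(counts.loc[state].get("weakened", 0)),
            ))
    manifest.check_consistency()

    # ---- network & communities --------------------------------------------
    partition = None
    if all_pairs:
        try:
            graph = net.build_network(all_pairs, feature_class)
            partition = net.detect_communities(graph, seed=cfg.seed)
            net.export_graphml(graph, out / "network.graphml")
            net.export_sif(graph, out / "edges.sif.tsv")
            pd.DataFrame(
                sorted(partition.assignment.items()),
                columns=["node", "community"],
            ).to_csv(out / "communities.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("network", exc) from exc

    # ---- enrichment --------------------------------------------------------
    if cfg.run_enrichment and cfg.gmt_path and all_pairs:
        try:
            gmt = read_gmt(cfg.gmt_path)
            universe = set(target_expr.index)
            network_genes = set(graph.nodes)
            enr.enrich_collection(network_genes, gmt, universe).to_csv(
                out / "enrichment_network.tsv", sep="\t", index=False)
            if partition is not None:
                biggest = net.largest_community(partition)
                enr.enrich_collection(biggest, gmt, universe).to_csv(
                    out / "enrichment_largest_community.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc

    # ---- clinical ----------------------------------------------------------
    if cfg.run_clinical and cfg.clinical_path:
        try:
            clinical = read_clinical(cfg.clinical_path)
            assoc = clin.associate_cnv_clinical(hits, cleaned, target_expr, clinical)
            assoc.to_csv(out / "clinical.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("clinical", exc) from exc

    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    write_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest
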