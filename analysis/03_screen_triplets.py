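"""Screen candidate ceRNA triplets per driver and copy-number status.

For each CNV-driven gene, samples are split into its aberrant status and its
copy-neutral status; within each, every pair of expressed RNAs sharing a
miRNA is screened for the ceRNA signature (positive pair correlation,
negative miRNA correlations, BH q < 0.05 per family).
"""

import dataclasses

import pandas as pd

from common import RESULTS_DIR, require_cohort

from cnvcerna import drivers as drv
from cnvcerna.io import read_cnv_calls, read_expression_matrix, read_interactions
from cnvcerna.triplets import find_candidate_triplets, shared_mirna_pairs


def main() -> None:
    paths = require_cohort()
    table = pd.read_csv(RESULTS_DIR / "drivers.tsv", sep="\t")
    cnv = drv.clean_calls(read_cnv_calls(paths["cnv"]))
    mrna = drv.filter_expression(read_expression_matrix(paths["mrna"], "mRNA"))
    lnc = drv.filter_expression(read_expression_matrix(paths["lncrna"], "lncRNA"))
    mirna = drv.filter_expression(read_expression_matrix(paths["mirna"], "miRNA"))
    ix = read_interactions(paths["interactions"])
    target_expr = pd.concat([mrna.values, lnc.values])
    pair_mirnas = shared_mirna_pairs(ix, set(target_expr.index))

    rows = []
    for _, d in table[table["is_driver"]].iterrows():
        grouping = drv.status_grouping(cnv, d["gene_id"])
        aberrant = (grouping.amplified_samples if d["direction"] == drv.AMP
                    else grouping.deleted_samples)
        for label, samples in ((d["direction"], aberrant),
                               ("normal", grouping.normal_samples)):
            for t in find_candidate_triplets(target_expr, mirna.values, ix,
                                             samples, label,
                                             pair_mirnas=pair_mirnas):
                rows.append(dataclasses.asdict(t)
                            | {"driver_gene_id": d["gene_id"]})
    out = RESULTS_DIR / "triplets.tsv"
    frame = pd.DataFrame(rows)
    frame.to_csv(out, sep="\t", index=False)
    by_status = frame.groupby("status").size().to_dict() if len(frame) else {}
    print(f"{len(frame)} candidate triplets across "
          f"{frame['driver_gene_id'].nunique() if len(frame) else 0} drivers")
    print(f"per status: {by_status}")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
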