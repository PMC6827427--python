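"""Permutation-test the dysregulation statistic dR per candidate pair.

dR = |cor_v - cor_n| compares each ceRNA pair's correlation between a
driver's aberrant and neutral samples; 1000 label permutations give the
null. The script prints the enhanced/weakened tally per driver state (the
cohort-level summary table of the pipeline) and the planted-pair recall.
"""

import pandas as pd

from common import RESULTS_DIR, SEED, require_cohort

from cnvcerna import drivers as drv
from cnvcerna.dysregulation import call_dysregulated_pairs
from cnvcerna.io import read_cnv_calls, read_expression_matrix
from cnvcerna.simulate import SyntheticTruth
from cnvcerna.triplets import CandidateTriplet

TRIPLET_FIELDS = ("cerna1_id", "cerna2_id", "mirna_id", "status", "r_pair",
                  "q_pair", "r_mi1", "q_mi1", "r_mi2", "q_mi2",
                  "n_samples_used")


def main() -> None:
    paths = require_cohort()
    trip = pd.read_csv(RESULTS_DIR / "triplets.tsv", sep="\t")
    table = pd.read_csv(RESULTS_DIR / "drivers.tsv", sep="\t")
    cnv = drv.clean_calls(read_cnv_calls(paths["cnv"]))
    mrna = drv.filter_expression(read_expression_matrix(paths["mrna"], "mRNA"))
    lnc = drv.filter_expression(read_expression_matrix(paths["lncrna"], "lncRNA"))
    target_expr = pd.concat([mrna.values, lnc.values])

    frames = []
    for _, d in table[table["is_driver"]].iterrows():
        sub = trip[trip["driver_gene_id"] == d["gene_id"]]
        by_status = {
            status: [CandidateTriplet(**{k: r[k] for k in TRIPLET_FIELDS})
                     for _, r in grp.iterrows()]
            for status, grp in sub.groupby("status")
        }
        grouping = drv.status_grouping(cnv, d["gene_id"])
        aberrant = (grouping.amplified_samples if d["direction"] == drv.AMP
                    else grouping.deleted_samples)
        _, tested = call_dysregulated_pairs(
            by_status, d["gene_id"], d["direction"], target_expr,
            aberrant, grouping.normal_samples, n_perm=1000, seed=SEED)
        if len(tested):
            frames.append(tested)
    tested = pd.concat(frames, ignore_index=True)
    tested.to_csv(RESULTS_DIR / "pairs_tested.tsv", sep="\t", index=False)
    sig = tested[tested["significant"]]
    sig.to_csv(RESULTS_DIR / "pairs.tsv", sep="\t", index=False)

    tally = sig.groupby(["driver_state", "direction"]).size().unstack(fill_value=0)
    print(f"{len(sig)} significant dysregulated pairs of {len(tested)} tested")
    print("per driver state:")
    print(tally.to_string())

    truth = SyntheticTruth.from_json(paths["truth"])
    rec = ok = 0
    for t in truth.planted_pairs:
        a, b = sorted((t["cerna1"], t["cerna2"]))
        rows = sig[(sig["cerna1_id"] == a) & (sig["cerna2_id"] == b)
                   & (sig["driver_gene_id"] == t["driver"])]
        if len(rows):
            rec += 1
            ok += (rows["direction"] == t["direction"]).any()
    print(f"planted-pair recall: {rec}/{len(truth.planted_pairs)}; "
          f"direction correct for {ok}/{rec} recovered")
    print(f"tables -> {RESULTS_DIR / 'pairs.tsv'}")


if __name__ == "__main__":
    main()
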