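"""Assemble the dysregulated ceRNA network and detect communities.

Significant pairs become undirected edges (drivers annotated on nodes and
edges); communities come from seeded multilevel modularity optimisation.
"""

import pandas as pd

from common import RESULTS_DIR, SEED

from cnvcerna.dysregulation import DysregulatedPair
from cnvcerna.network import (
    build_network,
    detect_communities,
    export_graphml,
    export_sif,
    largest_community,
)


def main() -> None:
    df = pd.read_csv(RESULTS_DIR / "pairs.tsv", sep="\t")
    pairs = [
        DysregulatedPair(
            r["cerna1_id"], r["cerna2_id"], r["driver_gene_id"],
            r["driver_state"], r["cor_v"], r["cor_n"], r["delta_r"],
            r["direction"], r["perm_p"], int(r["n_perm"]),
            set(str(r["supporting_mirnas"]).split(",")))
        for _, r in df.iterrows()
    ]
    g = build_network(pairs)
    part = detect_communities(g, seed=SEED)
    export_graphml(g, RESULTS_DIR / "network.graphml")
    export_sif(g, RESULTS_DIR / "edges.sif.tsv")
    pd.DataFrame(sorted(part.assignment.items()),
                 columns=["node", "community"]).to_csv(
        RESULTS_DIR / "communities.tsv", sep="\t", index=False)
    biggest = largest_community(part)
    n_comm = len(set(part.assignment.values()))
    n_drivers = sum(1 for _, a in g.nodes(data=True) if a["is_cnv_driver"])
    print(f"network: {g.number_of_nodes()} nodes "
          f"({n_drivers} CNV drivers), {g.number_of_edges()} edges")
    print(f"communities: {n_comm}, modularity Q = {part.modularity_q:.3f}")
    print(f"largest community: {len(biggest)} nodes")
    (RESULTS_DIR / "largest_community.txt").write_text(
        "\n".join(sorted(biggest)) + "\n")


if __name__ == "__main__":
    main()
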