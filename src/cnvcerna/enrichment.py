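"""Hypergeometric over-representation of network/community genes in gene sets.

With a universe of N genes (the expression profiles after prefiltering, mRNA
and lncRNA only), a query of n genes and a set covering M universe genes of
which m overlap the query, the enrichment p is the inclusive upper tail
P(X >= m) of Hypergeometric(N, M, n), computed exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .triplets import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    N: int
    n: int
    M: int
    m: int
    p: float
    q: float = float("nan")


def hypergeom_enrich(query: set[str], geneset: set[str], universe: set[str],
                     set_name: str = "") -> EnrichmentResult:
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        log.info("%d query gene(s) outside universe dropped", len(outside))
    q = query & universe
    s = geneset & universe
    m = len(q & s)
    N, M, n = len(universe), len(s), len(q)
    p = float(stats.hypergeom.sf(m - 1, N, M, n))  # P(X >= m)
    return EnrichmentResult(set_name, N, n, M, m, min(p, 1.0))


def enrich_collection(query: set[str], collection: GeneSetCollection,
                      universe: set[str]) -> pd.DataFrame:
    """Per-set hypergeometric tests, BH-adjusted across the collection,
    sorted by p (ties by set name for determinism)."""
    if not collection.sets:
        return pd.DataFrame(columns=["set_name", "N", "n", "M", "m", "p", "q"])
    results = [
        hypergeom_enrich(query, members, universe, set_name=name)
        for name, members in sorted(collection.sets.items())
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set_name"], ignore_index=True)
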