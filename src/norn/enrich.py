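"""Hypergeometric gene-set over-representation analysis (ORA).

For an input gene list (typically DEGs) and a collection of named gene
sets, each set is tested with the upper-tail hypergeometric probability
P(X >= k) of drawing k or more set members in n input genes from a
universe of N genes containing K set members, followed by
Benjamini-Hochberg correction across sets. The gene ratio k/n and the
overlap count are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from norn.spots import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a universe.

    Members outside the universe are dropped (logged); sets left empty are
    removed. The universe defaults to the union of all set members but in
    analysis practice should be the genes actually tested for differential
    expression.
    """

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        if not self.universe:
            raise ValueError("empty universe")
        clean = {}
        for name, members in self.sets.items():
            members = set(members)
            dropped = members - self.universe
            if dropped:
                logger.info("set %r: %d members outside the universe dropped", name, len(dropped))
            members &= self.universe
            if members:
                clean[name] = members
            else:
                logger.info("set %r empty after harmonization; removed", name)
        if not clean:
            raise ValueError("no non-empty gene sets after harmonization")
        self.sets = clean


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members per tab-separated
    line) into a collection; the universe defaults to the union of sets."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def ora(input_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of each gene set in the input list.

    Input genes outside the universe are dropped with a logged count. Per
    set: overlap k ("count"), set size K, input size n, universe N, the
    upper-tail hypergeometric p = P(X >= k), BH-adjusted q across all
    tested sets, gene ratio k/n, and the overlapping genes. Sorted by
    adjusted p (ties: larger overlap first, then name).
    """
    genes = set(input_genes)
    if not genes:
        raise ValueError("empty input gene list")
    outside = genes - collection.universe
    if outside:
        logger.info("%d input genes outside the universe dropped", len(outside))
    genes &= collection.universe
    if not genes:
        raise ValueError("no input genes remain inside the universe")

    N = len(collection.universe)
    n = len(genes)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = genes & members
        k = len(overlap)
        # P(X >= k) under sampling n of N with K successes
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": name,
                "count": k,
                "set_size": K,
                "input_size": n,
                "universe_size": N,
                "gene_ratio": k / n,
                "p": p,
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table = table.sort_values(
        ["q", "p", "count", "term"], ascending=[True, True, False, True], kind="stable"
    ).reset_index(drop=True)
    return table[
        ["term", "count", "set_size", "input_size", "universe_size", "gene_ratio", "p", "q", "genes"]
    ]


def top_terms(results: pd.DataFrame, limit: int = 20) -> pd.DataFrame:
    """First ``limit`` rows of a sorted enrichment table (the 20 most
    significantly enriched pathways, by default); ties in adjusted p break
    by larger overlap then term name."""
    if limit < 0:
        raise ValueError("limit must be >= 0")
    ordered = results.sort_values(
        ["q", "count", "term"], ascending=[True, False, True], kind="stable"
    )
    return ordered.head(limit).reset_index(drop=True)
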