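"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list (e.g. protein-coding genes spatially associated with DE
lncRNAs), each gene set is tested with the upper-tail hypergeometric
probability P[X >= k] of drawing k set members in a query of size n from
a universe of N genes containing K set members; BH correction is applied
across the collection.  Enrichment only (no depletion), matching the usual
GO/KEGG over-representation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise EnrichmentError("empty universe")
        # restrict set members to the universe up front
        self.sets = {
            name: sorted(set(members) & self.universe)
            for name, members in self.sets.items()
        }


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> members...).

    When no universe is given, the union of all set members is used.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            name = parts[0]
            if name in sets:
                raise EnrichmentError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in parts[2:] if m]
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def hypergeom_upper_tail(k, N, K, n):
    """P[X >= k] for X ~ Hypergeometric(N, K, n); accepts scalars or arrays."""
    import numpy as np

    k = np.asarray(k)
    p = np.where(k <= 0, 1.0, hypergeom.sf(k - 1, N, K, n))
    return float(p) if p.ndim == 0 else p


def ora(query: set[str] | list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of a query list against every set in the collection.

    Query ids outside the universe are dropped (their count is in the
    ``n_dropped`` frame attribute).  Results are sorted by q then by
    descending overlap.
    """
    query_set = set(query)
    dropped = query_set - collection.universe
    query_in = query_set & collection.universe
    if not query_in:
        raise EnrichmentError("query has no members inside the universe")
    N = len(collection.universe)
    n = len(query_in)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = sorted(query_in.intersection(members))
        k = len(overlap)
        rows.append(
            dict(
                set_name=name,
                k=k,
                n_query=n,
                K=K,
                N=N,
                p=hypergeom_upper_tail(k, N, K, n),
                member_ids=",".join(overlap),
            )
        )
    df = pd.DataFrame(
        rows, columns=["set_name", "k", "n_query", "K", "N", "p", "member_ids"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df = df[["set_name", "k", "n_query", "K", "N", "p", "q", "member_ids"]]
    df = df.sort_values(["q", "k"], ascending=[True, False]).reset_index(drop=True)
    df.attrs["n_dropped"] = len(dropped)
    return df
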