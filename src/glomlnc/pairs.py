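"""Co-location of DE lncRNAs with DE protein-coding genes.

Joins the spatial classification to per-stratum differential-expression
tables, producing one record per (DE lncRNA, DE partner gene) combination,
then tabulates the four regulation patterns per relation — the machinery
behind regulation-pattern tables of cis-candidate lncRNA studies — plus
the proximal (<5 kb) lincRNA sub-analysis and Venn membership of DE
features across age strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassifiedLncRNA

PATTERNS = (
    "gene_up_lnc_up",
    "gene_up_lnc_down",
    "gene_down_lnc_down",
    "gene_down_lnc_up",
)

RELATIONS = ("sense", "antisense", "neighbor")

_CLASS_TO_RELATION = {
    "intragenic_sense": "sense",
    "intragenic_antisense": "antisense",
    "linc_neighbor": "neighbor",
}


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class PairRecord:
    lnc_id: str
    gene_id: str
    relation: str
    stratum: str
    lnc_direction: str
    gene_direction: str
    pattern: str
    gap_bp: int | None
    same_strand: bool | None
    relative_position: str | None


def _pattern(gene_direction: str, lnc_direction: str) -> str:
    return f"gene_{gene_direction}_lnc_{lnc_direction}"


def build_pairs(
    classified: Sequence[ClassifiedLncRNA],
    de_lnc: pd.DataFrame,
    de_genes: pd.DataFrame,
    stratum: str,
) -> list[PairRecord]:
    """One PairRecord per DE lncRNA x DE partner gene in a stratum.

    ``de_lnc``/``de_genes`` are DE tables with feature_id, direction,
    significant columns (one stratum each).  Intragenic lncRNAs pair with
    every overlapping DE gene, lincRNA neighbors with their in-window
    nearest DE partner(s); orphans never pair.
    """
    for name, tbl in (("de_lnc", de_lnc), ("de_genes", de_genes)):
        missing = {"feature_id", "direction", "significant"} - set(tbl.columns)
        if missing:
            raise PairingError(f"{name} table missing columns {sorted(missing)}")
    sig_lnc = de_lnc.loc[de_lnc["significant"].astype(bool)].set_index("feature_id")
    sig_gene = de_genes.loc[de_genes["significant"].astype(bool)].set_index("feature_id")
    records: list[PairRecord] = []
    for rec in classified:
        relation = _CLASS_TO_RELATION.get(rec.spatial_class)
        if relation is None or rec.lnc_id not in sig_lnc.index:
            continue
        lnc_dir = str(sig_lnc.loc[rec.lnc_id, "direction"])
        for gid in rec.partner_gene_ids:
            if gid not in sig_gene.index:
                continue
            gene_dir = str(sig_gene.loc[gid, "direction"])
            records.append(
                PairRecord(
                    lnc_id=rec.lnc_id,
                    gene_id=gid,
                    relation=relation,
                    stratum=stratum,
                    lnc_direction=lnc_dir,
                    gene_direction=gene_dir,
                    pattern=_pattern(gene_dir, lnc_dir),
                    gap_bp=rec.gap_bp,
                    same_strand=rec.same_strand_as_partner,
                    relative_position=rec.relative_position,
                )
            )
    return records


def pairs_to_frame(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(p) for p in pairs],
        columns=[
            "lnc_id", "gene_id", "relation", "stratum", "lnc_direction",
            "gene_direction", "pattern", "gap_bp", "same_strand",
            "relative_position",
        ],
    )


def concordance_table(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    """Long-format counts per (relation, stratum, pattern), plus margins.

    Besides the pair count, the distinct-gene margin ``n_genes`` is
    reported per cell (several lncRNAs may share one host gene).
    """
    df = pairs_to_frame(pairs)
    cells = []
    strata = sorted(df["stratum"].unique()) if not df.empty else []
    for relation in RELATIONS:
        for stratum in strata:
            sub = df[(df["relation"] == relation) & (df["stratum"] == stratum)]
            for pattern in PATTERNS:
                cell = sub[sub["pattern"] == pattern]
                cells.append(
                    dict(
                        relation=relation,
                        stratum=stratum,
                        pattern=pattern,
                        count=len(cell),
                        n_genes=cell["gene_id"].nunique(),
                    )
                )
            cells.append(
                dict(
                    relation=relation,
                    stratum=stratum,
                    pattern="total",
                    count=len(sub),
                    n_genes=sub["gene_id"].nunique(),
                )
            )
    return pd.DataFrame(
        cells, columns=["relation", "stratum", "pattern", "count", "n_genes"]
    )


def proximal_analysis(
    pairs: Iterable[PairRecord],
    threshold_bp: int = 5_000,
) -> dict[str, int]:
    """Summary of neighbor pairs with gap strictly below ``threshold_bp``.

    Returns counts: total proximal pairs, pairs where lincRNA and gene
    share the direction, pairs with the lincRNA downstream of its
    partner, and same-strand pairs.
    """
    prox = [
        p
        for p in pairs
        if p.relation == "neighbor"
        and p.gap_bp is not None
        and p.gap_bp < threshold_bp
    ]
    return {
        "n_proximal": len(prox),
        "n_same_pattern": sum(
            1 for p in prox if p.lnc_direction == p.gene_direction
        ),
        "n_downstream": sum(
            1 for p in prox if p.relative_position == "downstream"
        ),
        "n_same_strand": sum(1 for p in prox if p.same_strand),
    }


def venn_membership(
    de_tables: Mapping[str, pd.DataFrame],
    feature_subset: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Stratum-membership sets of significant features and Venn region counts.

    ``de_tables`` maps stratum label -> DE table.  Returns (per-feature
    frame with a ``strata`` frozenset column, region counts keyed by
    frozenset of stratum labels).  Region counts sum to the union size.
    """
    if len(de_tables) < 2:
        raise PairingError("venn membership needs >=2 strata")
    membership: dict[str, set[str]] = {}
    for stratum, tbl in de_tables.items():
        sig = set(tbl.loc[tbl["significant"], "feature_id"])
        if feature_subset is not None:
            sig &= feature_subset
        for fid in sig:
            membership.setdefault(fid, set()).add(stratum)
    rows = [
        dict(feature_id=fid, strata=frozenset(strata))
        for fid, strata in sorted(membership.items())
    ]
    frame = pd.DataFrame(rows, columns=["feature_id", "strata"])
    regions: dict[frozenset, int] = {}
    labels = list(de_tables)
    for r in range(1, len(labels) + 1):
        for combo in combinations(sorted(labels), r):
            regions[frozenset(combo)] = 0
    for row in rows:
        regions[row["strata"]] += 1
    return frame, regions


def dedupe_pairs_across_strata(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    """Cross-stratum-deduplicated pair list (first stratum kept per pair)."""
    df = pairs_to_frame(pairs)
    if df.empty:
        return df
    return df.drop_duplicates(subset=["lnc_id", "gene_id"], keep="first").reset_index(
        drop=True
    )
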