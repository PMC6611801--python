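"""Strand-aware positional classification of lncRNAs.

Each lncRNA receives exactly one of four classes relative to the
protein-coding gene annotation:

* ``intragenic_sense``     — overlaps a gene's transcriptional unit by at
  least one base on the same strand (introns count; intronic sense
  lncRNAs are the dominant class in glomerular data);
* ``intragenic_antisense`` — overlaps on the opposite strand only;
* ``linc_neighbor``        — no overlap, but the nearest gene lies within
  the cis window (default gap < 50 kb);
* ``linc_orphan``          — no gene within the window.

When a lncRNA overlaps genes on both strands, sense wins for the
single-label class; all overlapping genes remain listed as partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    AnnotationSet,
    GeneIndex,
    LncRNAModel,
    build_interval_index,
)

WINDOW_BP = 50_000
PROXIMAL_BP = 5_000

CLASSES = (
    "intragenic_sense",
    "intragenic_antisense",
    "linc_neighbor",
    "linc_orphan",
)


@dataclass(frozen=True)
class ClassifiedLncRNA:
    lnc_id: str
    spatial_class: str
    partner_gene_ids: tuple[str, ...] = ()
    gap_bp: int | None = None
    relative_position: str | None = None  # upstream | downstream (linc_neighbor)
    same_strand_as_partner: bool | None = None
    proximal_flag: bool | None = None


def classify_lncrna(
    lnc: LncRNAModel,
    index: GeneIndex,
    window_bp: int = WINDOW_BP,
    proximal_bp: int = PROXIMAL_BP,
) -> ClassifiedLncRNA:
    """Classify one lncRNA against an index of protein-coding genes."""
    overlapping = index.overlapping(lnc.interval)
    if overlapping:
        sense = [g for g in overlapping if g.interval.strand == lnc.interval.strand]
        cls = "intragenic_sense" if sense else "intragenic_antisense"
        return ClassifiedLncRNA(
            lnc_id=lnc.lnc_id,
            spatial_class=cls,
            partner_gene_ids=tuple(g.gene_id for g in overlapping),
            gap_bp=0,
            proximal_flag=True,
        )
    nearest, gap = index.nearest(lnc.interval)
    if gap is None or gap >= window_bp:
        return ClassifiedLncRNA(lnc_id=lnc.lnc_id, spatial_class="linc_orphan")
    # orientation relative to the (first) partner gene's own strand:
    # a lincRNA past the gene's TES is downstream, before its TSS upstream
    partner = nearest[0]
    giv, liv = partner.interval, lnc.interval
    right_of_gene = liv.start >= giv.end
    if giv.strand == "+":
        rel = "downstream" if right_of_gene else "upstream"
    else:
        rel = "upstream" if right_of_gene else "downstream"
    return ClassifiedLncRNA(
        lnc_id=lnc.lnc_id,
        spatial_class="linc_neighbor",
        partner_gene_ids=tuple(g.gene_id for g in nearest),
        gap_bp=gap,
        relative_position=rel,
        same_strand_as_partner=partner.interval.strand == liv.strand,
        proximal_flag=gap < proximal_bp,
    )


def classify_all(
    ann: AnnotationSet,
    window_bp: int = WINDOW_BP,
    proximal_bp: int = PROXIMAL_BP,
) -> list[ClassifiedLncRNA]:
    """Classify every lncRNA; the classes partition the lncRNA set."""
    index = build_interval_index(ann)
    return [
        classify_lncrna(l, index, window_bp=window_bp, proximal_bp=proximal_bp)
        for l in ann.lncrnas
    ]


def class_counts(classified: Iterable[ClassifiedLncRNA]) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for rec in classified:
        counts[rec.spatial_class] += 1
    return counts


def classification_to_frame(classified: Sequence[ClassifiedLncRNA]) -> pd.DataFrame:
    rows = [
        {
            "lnc_id": r.lnc_id,
            "spatial_class": r.spatial_class,
            "partner_gene_ids": ",".join(r.partner_gene_ids),
            "gap_bp": r.gap_bp,
            "relative_position": r.relative_position,
            "same_strand_as_partner": r.same_strand_as_partner,
            "proximal_flag": r.proximal_flag,
        }
        for r in classified
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_id", "spatial_class", "partner_gene_ids", "gap_bp",
            "relative_position", "same_strand_as_partner", "proximal_flag",
        ],
    )


def host_gene_rollup(
    classified: Iterable[ClassifiedLncRNA],
    de_lnc_ids: set[str],
) -> pd.DataFrame:
    """Per host gene, counts of distinct DE intragenic lncRNAs.

    Only genes hosting at least one DE intragenic lncRNA appear; sorted by
    total count descending.  Columns: gene_id, n_de_lnc, n_sense,
    n_antisense, multi (hosts more than one).
    """
    per_gene: dict[str, dict[str, set[str]]] = {}
    for rec in classified:
        if rec.spatial_class not in ("intragenic_sense", "intragenic_antisense"):
            continue
        if rec.lnc_id not in de_lnc_ids:
            continue
        key = "sense" if rec.spatial_class == "intragenic_sense" else "antisense"
        for gid in rec.partner_gene_ids:
            slot = per_gene.setdefault(gid, {"sense": set(), "antisense": set()})
            slot[key].add(rec.lnc_id)
    rows = []
    for gid, slot in per_gene.items():
        n_sense = len(slot["sense"])
        n_anti = len(slot["antisense"])
        total = len(slot["sense"] | slot["antisense"])
        rows.append((gid, total, n_sense, n_anti, total > 1))
    df = pd.DataFrame(
        rows, columns=["gene_id", "n_de_lnc", "n_sense", "n_antisense", "multi"]
    )
    return df.sort_values(
        ["n_de_lnc", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
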