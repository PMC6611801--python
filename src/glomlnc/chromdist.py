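"""Per-chromosome density of differentially expressed features.

For a feature category (coding genes, all lncRNAs, or the intragenic /
intergenic lncRNA subsets) this computes, per named chromosome, the
percentage of encoded features that are differentially expressed, plus
the cross-chromosome mean and sample SD of those percentages.  Unplaced
scaffolds are excluded.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .annotation import AnnotationSet, is_named_chromosome
from .classify import ClassifiedLncRNA

CATEGORIES = ("coding", "lncRNA_all", "lncRNA_intragenic", "lncRNA_intergenic")


class ChromStatsError(ValueError):
    pass


def _category_features(
    ann: AnnotationSet,
    category: str,
    classified: Sequence[ClassifiedLncRNA] | None,
) -> list[tuple[str, str]]:
    """(feature_id, chrom) list for the requested category."""
    if category == "coding":
        return [(g.gene_id, g.interval.chrom) for g in ann.genes]
    if category == "lncRNA_all":
        return [(l.lnc_id, l.interval.chrom) for l in ann.lncrnas]
    if category in ("lncRNA_intragenic", "lncRNA_intergenic"):
        if classified is None:
            raise ChromStatsError(f"category {category} needs a classification")
        intragenic = {
            r.lnc_id
            for r in classified
            if r.spatial_class in ("intragenic_sense", "intragenic_antisense")
        }
        chrom_of = {l.lnc_id: l.interval.chrom for l in ann.lncrnas}
        if category == "lncRNA_intragenic":
            return [(i, chrom_of[i]) for i in sorted(intragenic)]
        return [
            (l.lnc_id, l.interval.chrom)
            for l in ann.lncrnas
            if l.lnc_id not in intragenic
        ]
    raise ChromStatsError(f"unknown category {category!r}; pick from {CATEGORIES}")


def chrom_stats(
    ann: AnnotationSet,
    de_ids: set[str],
    category: str,
    classified: Sequence[ClassifiedLncRNA] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome DE percentages and their (mean, sample SD).

    Returns a frame with chrom, n_encoded, n_de, pct (NaN-flagged when a
    chromosome encodes no feature of the category) and the mean/SD over
    chromosomes with n_encoded > 0.
    """
    feats = _category_features(ann, category, classified)
    if not feats:
        raise ChromStatsError(f"no features in category {category!r}")
    cat_ids = {fid for fid, _ in feats}
    stray = de_ids - cat_ids
    de_in_cat = de_ids & cat_ids
    if stray and not de_in_cat:
        raise ChromStatsError("de_ids share no members with the category")

    chroms = sorted(
        {c for _, c in feats if is_named_chromosome(c)}
        | {
            f.interval.chrom
            for f in ann.features()
            if is_named_chromosome(f.interval.chrom)
        }
    )
    rows = []
    for chrom in chroms:
        ids_here = [fid for fid, c in feats if c == chrom]
        n_enc = len(ids_here)
        n_de = sum(1 for fid in ids_here if fid in de_in_cat)
        pct = 100.0 * n_de / n_enc if n_enc else float("nan")
        rows.append(dict(chrom=chrom, n_encoded=n_enc, n_de=n_de, pct=pct))
    df = pd.DataFrame(rows, columns=["chrom", "n_encoded", "n_de", "pct"])
    valid = df.loc[df["n_encoded"] > 0, "pct"]
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1)) if len(valid) > 1 else float("nan")
    return df, mean, sd
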