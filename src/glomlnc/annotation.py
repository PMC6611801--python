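"""Gene annotation containers, readers, and interval queries.

All coordinates are held internally as 0-based half-open intervals
(BED convention); GTF input/output converts at the boundary.  A gene's
"transcriptional unit" is the union span of its transcript rows, from the
TSS-most to the TES-most coordinate, introns included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"

#: biotype tokens treated as lncRNA when reading external annotation;
#: rRNA/snRNA/piRNA and other small-RNA classes are deliberately absent so a
#: biotype filter of {protein_coding, lncRNA} drops them.
LNCRNA_SYNONYMS = frozenset(
    {"lncRNA", "lincRNA", "antisense", "lnc_RNA", "processed_transcript"}
)

#: chromosome names considered "placed"; everything else (scaffolds,
#: patches) is kept for classification but dropped from per-chromosome
#: statistics.
_NAMED_CHROM = re.compile(r"^(chr)?([0-9]{1,2}|[XYM]|MT)$")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("empty chromosome name")
        if self.start < 0:
            raise AnnotationError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise AnnotationError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene's transcriptional unit."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    biotype: str = PROTEIN_CODING


@dataclass(frozen=True)
class LncRNAModel:
    """A lncRNA gene locus; aliases carry alternate IDs (NONMMUT/ENSMUST...)."""

    lnc_id: str
    interval: GenomicInterval
    aliases: tuple[str, ...] = ()
    biotype: str = LNCRNA


@dataclass
class AnnotationSet:
    """Validated collection of coding genes and lncRNAs."""

    genes: list[GeneModel] = field(default_factory=list)
    lncrnas: list[LncRNAModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        gene_ids = [g.gene_id for g in self.genes]
        if len(gene_ids) != len(set(gene_ids)):
            dup = sorted({i for i in gene_ids if gene_ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene_id(s): {dup[:5]}")
        lnc_ids = [l.lnc_id for l in self.lncrnas]
        if len(lnc_ids) != len(set(lnc_ids)):
            dup = sorted({i for i in lnc_ids if lnc_ids.count(i) > 1})
            raise AnnotationError(f"duplicate lnc_id(s): {dup[:5]}")
        gene_id_set = set(gene_ids)
        for l in self.lncrnas:
            clash = gene_id_set.intersection(l.aliases)
            if clash:
                raise AnnotationError(
                    f"lncRNA {l.lnc_id} alias collides with gene_id: {sorted(clash)}"
                )
        if self.chrom_sizes is not None:
            for feat in self.features():
                iv = feat.interval
                if iv.chrom not in self.chrom_sizes:
                    raise AnnotationError(
                        f"{_feat_id(feat)}: chromosome {iv.chrom} missing from chrom_sizes"
                    )
                if iv.end > self.chrom_sizes[iv.chrom]:
                    raise AnnotationError(
                        f"{_feat_id(feat)}: end {iv.end} exceeds length of {iv.chrom}"
                    )

    def features(self) -> Iterable[GeneModel | LncRNAModel]:
        yield from self.genes
        yield from self.lncrnas

    @property
    def named_chromosomes(self) -> list[str]:
        chroms = {f.interval.chrom for f in self.features()}
        return sorted(c for c in chroms if is_named_chromosome(c))


def _feat_id(feat: GeneModel | LncRNAModel) -> str:
    return feat.gene_id if isinstance(feat, GeneModel) else feat.lnc_id


def is_named_chromosome(chrom: str) -> bool:
    return bool(_NAMED_CHROM.match(chrom))


# ---------------------------------------------------------------------------
# readers / writers


def read_gtf(
    path: str | Path,
    biotype_filter: set[str] | None = None,
) -> AnnotationSet:
    """Read gene-level annotation from a GTF file.

    Transcript/exon rows of a gene are collapsed to the union span per
    gene_id.  GTF's 1-based closed intervals become 0-based half-open.
    Records whose biotype is outside ``biotype_filter`` (default:
    protein_coding plus the lncRNA synonyms) are dropped — this is how
    rRNA/snRNA/piRNA records are excluded.
    """
    import pyranges as pr

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_gtf(path)
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return AnnotationSet()
    if "gene_id" not in df.columns:
        raise AnnotationError(f"{path}: GTF lacks gene_id attributes")
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = PROTEIN_CODING
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]

    if biotype_filter is None:
        biotype_filter = {PROTEIN_CODING} | set(LNCRNA_SYNONYMS)

    genes: list[GeneModel] = []
    lncrnas: list[LncRNAModel] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        chroms = grp["Chromosome"].unique()
        strands = grp["Strand"].unique()
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene_id {gene_id}: conflicting chrom/strand across rows"
            )
        biotype = str(grp["gene_biotype"].dropna().iloc[0])
        if biotype not in biotype_filter and not (
            LNCRNA in biotype_filter and biotype in LNCRNA_SYNONYMS
        ):
            continue
        iv = GenomicInterval(
            chrom=str(chroms[0]),
            start=int(grp["Start"].min()),
            end=int(grp["End"].max()),
            strand=str(strands[0]),
        )
        names = grp["gene_name"].dropna()
        symbol = str(names.iloc[0]) if len(names) else str(gene_id)
        if biotype == PROTEIN_CODING:
            genes.append(GeneModel(gene_id=str(gene_id), symbol=symbol, interval=iv))
        else:
            lncrnas.append(LncRNAModel(lnc_id=str(gene_id), interval=iv))
    return AnnotationSet(genes=genes, lncrnas=lncrnas)


def _prevalidate_gtf(path: Path) -> None:
    """Cheap structural check so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer start/end"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid 1-based interval {start}-{end}"
                )


_TSV_COLUMNS = ["id", "symbol", "chrom", "start0", "end0", "strand", "biotype"]


def read_annotation_tsv(path: str | Path) -> AnnotationSet:
    """Read the flat TSV annotation dialect (0-based half-open columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneModel] = []
    lncrnas: list[LncRNAModel] = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(
            chrom=row.chrom, start=int(row.start0), end=int(row.end0), strand=row.strand
        )
        if row.biotype == PROTEIN_CODING:
            genes.append(GeneModel(gene_id=row.id, symbol=str(row.symbol), interval=iv))
        elif row.biotype in LNCRNA_SYNONYMS:
            aliases: tuple[str, ...] = ()
            if "aliases" in df.columns and isinstance(getattr(row, "aliases", None), str):
                aliases = tuple(a for a in row.aliases.split(",") if a)
            lncrnas.append(LncRNAModel(lnc_id=row.id, interval=iv, aliases=aliases))
        else:
            raise AnnotationError(f"{path}: unknown biotype {row.biotype!r} for {row.id}")
    return AnnotationSet(genes=genes, lncrnas=lncrnas)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def annotation_to_frame(ann: AnnotationSet) -> pd.DataFrame:
    rows = []
    for g in ann.genes:
        rows.append(
            (g.gene_id, g.symbol, g.interval.chrom, g.interval.start, g.interval.end,
             g.interval.strand, g.biotype, "")
        )
    for l in ann.lncrnas:
        rows.append(
            (l.lnc_id, l.lnc_id, l.interval.chrom, l.interval.start, l.interval.end,
             l.interval.strand, l.biotype, ",".join(l.aliases))
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS + ["aliases"])


def write_annotation_tsv(ann: AnnotationSet, path: str | Path) -> None:
    annotation_to_frame(ann).to_csv(path, sep="\t", index=False)


def write_bed6(features: Sequence[GeneModel | LncRNAModel], path: str | Path) -> None:
    """Export a feature subset as BED6 (name=id, score=0)."""
    with open(path, "w") as fh:
        for feat in features:
            iv = feat.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_feat_id(feat)}\t0\t{iv.strand}\n"
            )


def write_gtf(ann: AnnotationSet, path: str | Path, source: str = "glomlnc") -> None:
    """Write gene-level GTF rows (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for feat in ann.features():
            iv = feat.interval
            if isinstance(feat, GeneModel):
                attrs = (
                    f'gene_id "{feat.gene_id}"; gene_name "{feat.symbol}"; '
                    f'gene_biotype "{feat.biotype}";'
                )
            else:
                attrs = f'gene_id "{feat.lnc_id}"; gene_biotype "{feat.biotype}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# interval queries


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> tuple[int, bool]:
    """Bases strictly between two same-chromosome intervals.

    Returns ``(distance, overlapping)``.  Overlap by >=1 base gives (0, True);
    adjacency under half-open coordinates gives (0, False).
    """
    if a.chrom != b.chrom:
        raise AnnotationError(
            f"gap_distance on different chromosomes: {a.chrom} vs {b.chrom}"
        )
    if a.start < b.end and b.start < a.end:
        return 0, True
    if a.end <= b.start:
        return b.start - a.end, False
    return a.start - b.end, False


class GeneIndex:
    """Per-chromosome interval index over protein-coding genes.

    Overlap queries go through an interval tree; nearest-by-gap queries use
    the tree plus an expanding window.  Results are defined to match a
    brute-force scan over all genes.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        # sorted (end, gene) / (start, gene) lists for O(log n) nearest lookups
        self._by_end: dict[str, list[tuple[int, GeneModel]]] = {}
        self._by_start: dict[str, list[tuple[int, GeneModel]]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, glist in self._by_chrom.items():
            glist.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
            self._trees[chrom] = IntervalTree.from_tuples(
                (g.interval.start, g.interval.end, g) for g in glist
            )
            self._by_end[chrom] = sorted(
                ((g.interval.end, g) for g in glist), key=lambda t: t[0]
            )
            self._by_start[chrom] = sorted(
                ((g.interval.start, g) for g in glist), key=lambda t: t[0]
            )

    def overlapping(self, query: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
        return hits

    def nearest(self, query: GenomicInterval) -> tuple[list[GeneModel], int | None]:
        """Nearest non-overlapping gene(s) by gap; ties return all tied genes.

        Returns ``([], None)`` on a chromosome with no genes.  Overlapping
        genes are excluded — callers handle overlap via :meth:`overlapping`.
        """
        from bisect import bisect_left, bisect_right

        glist = self._by_chrom.get(query.chrom)
        if not glist:
            return [], None
        # Non-overlapping genes lie entirely left (end <= query.start) or
        # entirely right (start >= query.end) of the query.
        by_end = self._by_end[query.chrom]
        by_start = self._by_start[query.chrom]
        ends = [t[0] for t in by_end]
        starts = [t[0] for t in by_start]
        candidates: list[tuple[int, int]] = []  # (gap, side)
        i = bisect_right(ends, query.start)
        if i > 0:
            candidates.append((query.start - ends[i - 1], 0))
        j = bisect_left(starts, query.end)
        if j < len(starts):
            candidates.append((starts[j] - query.end, 1))
        if not candidates:
            return [], None
        best_gap = min(gap for gap, _ in candidates)
        best: list[GeneModel] = []
        if i > 0 and query.start - ends[i - 1] == best_gap:
            e_best = ends[i - 1]
            k = bisect_left(ends, e_best)
            best.extend(g for e, g in by_end[k:i])
        if j < len(starts) and starts[j] - query.end == best_gap:
            s_best = starts[j]
            k = bisect_right(starts, s_best)
            best.extend(g for s, g in by_start[j:k])
        best.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
        return best, best_gap


def build_interval_index(ann: AnnotationSet) -> GeneIndex:
    """Index the protein-coding genes of an annotation set."""
    return GeneIndex(ann.genes)
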