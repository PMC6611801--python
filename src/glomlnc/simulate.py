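"""Synthetic annotation, expression, and qPCR fixtures with planted truth.

The generator emulates the design of a glomerular microarray study in a
leptin-deficient diabetic mouse model: two genotypes (diabetic case vs
wild-type control) sampled at several ages, a genome of protein-coding
genes with lncRNAs planted in each spatial class, log2 expression with
planted fold changes around the 2-fold significance gate, and Ct tables
with a stable reference gene.

Every quantity is drawn from one seeded NumPy generator stream, so a fixed
seed yields byte-identical outputs.

Layout strategy: features are grouped into "blocks" (a host gene with its
intragenic lncRNA, a gene/lincRNA neighbor pair, a lone gene, or a lone
orphan lincRNA).  Blocks are laid out left to right per chromosome with
inter-block spacing larger than the cis window, so every planted lncRNA
satisfies its class by construction and no accidental relationships arise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    LncRNAModel,
    write_annotation_tsv,
)

PATTERNS = (
    "gene_up_lnc_up",
    "gene_up_lnc_down",
    "gene_down_lnc_down",
    "gene_down_lnc_up",
)

CASE_GROUP = "ob"
CONTROL_GROUP = "wt"
REFERENCE_GENE = "Ppib"  # cyclophilin B


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlannedPair:
    """One planted DE lncRNA x DE gene co-location with its regulation pattern."""

    relation: str  # sense | antisense | neighbor
    pattern: str  # one of PATTERNS
    proximal: bool = False  # neighbor only: gap < 5 kb
    downstream: bool = True  # neighbor only: lincRNA 3' of the partner gene
    same_strand: bool = True  # neighbor only

    def __post_init__(self) -> None:
        if self.relation not in ("sense", "antisense", "neighbor"):
            raise SimulationError(f"unknown relation {self.relation!r}")
        if self.pattern not in PATTERNS:
            raise SimulationError(f"unknown pattern {self.pattern!r}")


def default_concordance_plan() -> tuple[PlannedPair, ...]:
    """Planted co-location pairs for the focal age group.

    Mirrors the structure of the study's co-localization findings: sense
    pairs mostly concordant-up, a few antisense pairs with mixed patterns,
    and 13 proximal lincRNA pairs of which 12 share the partner's
    direction, 12 lie downstream, and 11 sit on the same strand.
    """
    plan: list[PlannedPair] = []
    plan += [PlannedPair("sense", "gene_up_lnc_up")] * 3
    plan += [PlannedPair("sense", "gene_up_lnc_down")]
    plan += [PlannedPair("sense", "gene_down_lnc_down")]
    plan += [PlannedPair("antisense", "gene_up_lnc_up")]
    plan += [PlannedPair("antisense", "gene_up_lnc_down")]
    plan += [PlannedPair("antisense", "gene_down_lnc_down")]
    # 13 proximal lincRNA pairs: 12 concordant / 12 downstream / 11 same-strand
    prox_specs = []
    for i in range(13):
        pattern = "gene_up_lnc_up" if i < 6 else (
            "gene_down_lnc_down" if i < 12 else "gene_up_lnc_down"
        )
        prox_specs.append(
            PlannedPair(
                "neighbor",
                pattern,
                proximal=True,
                downstream=i != 12,
                same_strand=i < 11,
            )
        )
    plan += prox_specs
    # distal (5-50 kb) neighbor pairs with mixed patterns
    plan += [
        PlannedPair("neighbor", "gene_up_lnc_up", proximal=False),
        PlannedPair("neighbor", "gene_up_lnc_down", proximal=False),
        PlannedPair("neighbor", "gene_down_lnc_down", proximal=False),
        PlannedPair("neighbor", "gene_down_lnc_up", proximal=False),
    ]
    return tuple(plan)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the array experiment: 4 replicates per genotype
    (the study used n = 3-4), planted |log2 FC| of log2(2.5) so true
    effects sit above the 2-fold gate, and three age strata with the
    full planted structure expressed in the oldest group.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 8_000_000
    n_coding: int = 60
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {
            "intragenic_sense": 10,
            "intragenic_antisense": 6,
            "linc_neighbor": 20,
            "linc_orphan": 10,
        }
    )
    neighbor_gap_range: tuple[int, int] = (5_000, 50_000)
    proximal_gap_range: tuple[int, int] = (200, 5_000)
    window_bp: int = 50_000
    n_replicates: int = 4
    log2_sigma: float = 0.1
    de_log2fc: float = math.log2(2.5)
    de_fraction: float = 0.1
    strata: tuple[str, ...] = ("8w", "16w", "24w")
    focal_stratum: str = "24w"
    stratum_retention: dict[str, float] = field(
        default_factory=lambda: {"8w": 0.1, "16w": 0.3, "24w": 1.0}
    )
    concordance_plan: tuple[PlannedPair, ...] = field(
        default_factory=default_concordance_plan
    )
    n_ct_animals: int = 6
    ct_sigma: float = 0.15

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.planted_counts.values()):
            raise SimulationError("planted counts must be non-negative")
        if self.de_log2fc <= 0:
            raise SimulationError("de_log2fc must be positive")
        if self.n_replicates < 2:
            raise SimulationError("need >=2 replicates per group")
        if self.focal_stratum not in self.strata:
            raise SimulationError("focal_stratum must be one of strata")
        for rel, key in (
            ("sense", "intragenic_sense"),
            ("antisense", "intragenic_antisense"),
            ("neighbor", "linc_neighbor"),
        ):
            n_planned = sum(1 for p in self.concordance_plan if p.relation == rel)
            if n_planned > self.planted_counts.get(key, 0):
                raise SimulationError(
                    f"concordance_plan needs {n_planned} {key} lncRNAs but "
                    f"planted_counts provides {self.planted_counts.get(key, 0)}"
                )
        n_partnered = sum(
            self.planted_counts.get(k, 0)
            for k in ("intragenic_sense", "intragenic_antisense", "linc_neighbor")
        )
        if n_partnered > self.n_coding:
            raise SimulationError(
                "n_coding must cover one partner gene per partnered lncRNA"
            )


@dataclass
class GroundTruth:
    """Planted structure, consistent with the emitted data by construction."""

    classes: pd.DataFrame  # lnc_id, true_class, partner_gene_id, gap_bp, ...
    de: pd.DataFrame  # stratum, feature_id, is_de, direction
    pairs: pd.DataFrame  # stratum, lnc_id, gene_id, relation, pattern, proximal

    def de_ids(self, stratum: str) -> set[str]:
        sub = self.de[(self.de["stratum"] == stratum) & self.de["is_de"]]
        return set(sub["feature_id"])


# ---------------------------------------------------------------------------
# annotation generation


@dataclass
class _Block:
    kind: str  # sense | antisense | neighbor | orphan | gene
    pair: PlannedPair | None = None  # planned DE pair attached to this block
    lnc_index: int = -1
    gene_index: int = -1


def generate_annotation(cfg: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Emit an annotation whose lncRNAs satisfy their planted classes."""
    rng = np.random.default_rng(cfg.seed)

    counts = cfg.planted_counts
    blocks: list[_Block] = []
    plan_by_rel: dict[str, list[PlannedPair]] = {"sense": [], "antisense": [], "neighbor": []}
    for p in cfg.concordance_plan:
        plan_by_rel[p.relation].append(p)

    def make_blocks(kind: str, total: int, planned: list[PlannedPair]) -> None:
        for i in range(total):
            blocks.append(_Block(kind=kind, pair=planned[i] if i < len(planned) else None))

    make_blocks("sense", counts.get("intragenic_sense", 0), plan_by_rel["sense"])
    make_blocks("antisense", counts.get("intragenic_antisense", 0), plan_by_rel["antisense"])
    make_blocks("neighbor", counts.get("linc_neighbor", 0), plan_by_rel["neighbor"])
    make_blocks("orphan", counts.get("linc_orphan", 0), [])
    n_extra_genes = cfg.n_coding - sum(
        1 for b in blocks if b.kind in ("sense", "antisense", "neighbor")
    )
    for _ in range(n_extra_genes):
        blocks.append(_Block(kind="gene"))

    rng.shuffle(blocks)  # mix classes across chromosomes

    genes: list[GeneModel] = []
    lncrnas: list[LncRNAModel] = []
    truth_rows: list[dict] = []
    # spacing larger than the cis window isolates the blocks
    margin = cfg.window_bp + 10_000
    cursors = {f"chr{i + 1}": margin for i in range(cfg.n_chroms)}
    chrom_names = list(cursors)

    gi = li = 0
    for bi, block in enumerate(blocks):
        chrom = chrom_names[bi % cfg.n_chroms]
        spacing = int(rng.integers(margin, margin + 50_000))
        start = cursors[chrom] + spacing

        gene_len = int(rng.integers(5_000, 40_000))
        lnc_len = int(rng.integers(500, 4_000))
        gene_strand = "+" if rng.random() < 0.5 else "-"

        gene = lnc = None
        truth: dict | None = None
        if block.kind in ("sense", "antisense"):
            gene = _gene(gi, chrom, start, start + gene_len, gene_strand)
            inner = int(rng.integers(0, gene_len - lnc_len))
            lnc_strand = gene_strand if block.kind == "sense" else _flip(gene_strand)
            lnc = _lnc(li, chrom, start + inner, start + inner + lnc_len, lnc_strand)
            truth = dict(
                lnc_id=lnc.lnc_id,
                true_class=f"intragenic_{block.kind}",
                partner_gene_id=gene.gene_id,
                gap_bp=0,
                relative_position=None,
                same_strand=block.kind == "sense",
                proximal=True,
            )
            end = start + gene_len
        elif block.kind == "neighbor":
            pair = block.pair
            if pair is not None and pair.proximal:
                lo, hi = cfg.proximal_gap_range
            else:
                lo, hi = cfg.neighbor_gap_range
            gap = int(rng.integers(lo, hi))
            downstream = (
                pair.downstream if pair is not None else bool(rng.random() < 0.5)
            )
            same_strand = (
                pair.same_strand if pair is not None else bool(rng.random() < 0.5)
            )
            lnc_strand = gene_strand if same_strand else _flip(gene_strand)
            # "downstream" means 3' of the gene in the gene's frame
            lnc_right = downstream if gene_strand == "+" else not downstream
            if lnc_right:
                gene = _gene(gi, chrom, start, start + gene_len, gene_strand)
                ls = start + gene_len + gap
                lnc = _lnc(li, chrom, ls, ls + lnc_len, lnc_strand)
                end = ls + lnc_len
            else:
                lnc = _lnc(li, chrom, start, start + lnc_len, lnc_strand)
                gs = start + lnc_len + gap
                gene = _gene(gi, chrom, gs, gs + gene_len, gene_strand)
                end = gs + gene_len
            truth = dict(
                lnc_id=lnc.lnc_id,
                true_class="linc_neighbor",
                partner_gene_id=gene.gene_id,
                gap_bp=gap,
                relative_position="downstream" if downstream else "upstream",
                same_strand=same_strand,
                proximal=gap < cfg.proximal_gap_range[1],
            )
        elif block.kind == "orphan":
            lnc_strand = "+" if rng.random() < 0.5 else "-"
            lnc = _lnc(li, chrom, start, start + lnc_len, lnc_strand)
            truth = dict(
                lnc_id=lnc.lnc_id,
                true_class="linc_orphan",
                partner_gene_id=None,
                gap_bp=None,
                relative_position=None,
                same_strand=None,
                proximal=None,
            )
            end = start + lnc_len
        else:  # lone coding gene
            gene = _gene(gi, chrom, start, start + gene_len, gene_strand)
            end = start + gene_len

        if end + margin > cfg.chrom_length:
            raise SimulationError(
                f"ran out of room on {chrom}; increase chrom_length "
                f"(needed > {end + margin})"
            )
        cursors[chrom] = end
        if gene is not None:
            genes.append(gene)
            block.gene_index = gi
            gi += 1
        if lnc is not None:
            lncrnas.append(lnc)
            block.lnc_index = li
            li += 1
        if truth is not None:
            truth_rows.append(truth)

    ann = AnnotationSet(
        genes=genes,
        lncrnas=lncrnas,
        chrom_sizes={c: cfg.chrom_length for c in chrom_names},
    )
    classes = pd.DataFrame(
        truth_rows,
        columns=[
            "lnc_id", "true_class", "partner_gene_id", "gap_bp",
            "relative_position", "same_strand", "proximal",
        ],
    )
    de, pairs = _plant_de(cfg, blocks, genes, lncrnas, rng)
    return ann, GroundTruth(classes=classes, de=de, pairs=pairs)


def _gene(i: int, chrom: str, start: int, end: int, strand: str) -> GeneModel:
    return GeneModel(
        gene_id=f"gene{i:04d}",
        symbol=f"Gene{i:04d}",
        interval=GenomicInterval(chrom, start, end, strand),
    )


def _lnc(i: int, chrom: str, start: int, end: int, strand: str) -> LncRNAModel:
    return LncRNAModel(
        lnc_id=f"lnc{i:04d}",
        interval=GenomicInterval(chrom, start, end, strand),
        aliases=(f"NONMMUT{i:06d}",),
    )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _plant_de(
    cfg: SimulationConfig,
    blocks: list[_Block],
    genes: list[GeneModel],
    lncrnas: list[LncRNAModel],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign per-stratum DE flags and directions.

    Planned pairs are DE (with their pattern's directions) in the focal
    stratum.  Ambient DE is restricted to features that cannot form
    co-location pairs — orphan lincRNAs, partner-less coding genes, and
    planted lncRNAs without a planned pattern (their host/partner gene
    stays non-DE) — so the pair table of the focal stratum equals the
    concordance plan exactly, by construction.
    """
    focal = cfg.focal_stratum
    de_dir: dict[str, str] = {}  # feature_id -> direction in focal stratum
    pair_rows: list[dict] = []
    paired_gene_ids: set[str] = set()
    for block in blocks:
        if block.pair is None:
            continue
        pair = block.pair
        lnc_id = lncrnas[block.lnc_index].lnc_id
        gene_id = genes[block.gene_index].gene_id
        gene_dir = "up" if pair.pattern.startswith("gene_up") else "down"
        lnc_dir = "up" if pair.pattern.endswith("lnc_up") else "down"
        de_dir[gene_id] = gene_dir
        de_dir[lnc_id] = lnc_dir
        paired_gene_ids.add(gene_id)
        pair_rows.append(
            dict(
                stratum=focal,
                lnc_id=lnc_id,
                gene_id=gene_id,
                relation=pair.relation,
                pattern=pair.pattern,
                proximal=pair.proximal,
            )
        )

    # ambient DE among pair-incapable features only
    eligible: list[str] = []
    for block in blocks:
        if block.kind == "orphan":
            eligible.append(lncrnas[block.lnc_index].lnc_id)
        elif block.kind == "gene":
            eligible.append(genes[block.gene_index].gene_id)
        elif block.pair is None:
            # planted lncRNA without a planned pattern; partner stays non-DE
            eligible.append(lncrnas[block.lnc_index].lnc_id)
    for fid in eligible:
        if rng.random() < cfg.de_fraction:
            de_dir[fid] = "up" if rng.random() < 0.5 else "down"

    all_ids = [g.gene_id for g in genes] + [l.lnc_id for l in lncrnas]
    de_rows: list[dict] = []
    # earlier strata express a retained subset of the focal DE set
    retained: dict[str, set[str]] = {}
    for stratum in cfg.strata:
        keep = cfg.stratum_retention.get(stratum, 1.0)
        if stratum == focal:
            retained[stratum] = set(de_dir)
        else:
            retained[stratum] = {fid for fid in de_dir if rng.random() < keep}
    for stratum in cfg.strata:
        for fid in all_ids:
            is_de = fid in retained[stratum]
            de_rows.append(
                dict(
                    stratum=stratum,
                    feature_id=fid,
                    is_de=is_de,
                    direction=de_dir.get(fid) if is_de else None,
                )
            )
    de = pd.DataFrame(de_rows, columns=["stratum", "feature_id", "is_de", "direction"])
    pairs = pd.DataFrame(
        pair_rows,
        columns=["stratum", "lnc_id", "gene_id", "relation", "pattern", "proximal"],
    )
    return de, pairs


# ---------------------------------------------------------------------------
# expression generation


def generate_expression(
    cfg: SimulationConfig,
    ann: AnnotationSet,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix (features x samples) and sample sheet.

    Per feature: baseline + group shift (+/- de_log2fc for DE features in
    the stratum, split half up/half down around the baseline) + Gaussian
    noise with SD log2_sigma.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    feature_ids = [g.gene_id for g in ann.genes] + [l.lnc_id for l in ann.lncrnas]
    baseline = pd.Series(
        rng.uniform(6.0, 12.0, size=len(feature_ids)), index=feature_ids
    )
    columns: list[str] = []
    sheet_rows: list[dict] = []
    data: dict[str, np.ndarray] = {}
    for stratum in cfg.strata:
        de_sub = truth.de[truth.de["stratum"] == stratum].set_index("feature_id")
        shift = np.zeros(len(feature_ids))
        for k, fid in enumerate(feature_ids):
            row = de_sub.loc[fid]
            if bool(row["is_de"]):
                sign = 1.0 if row["direction"] == "up" else -1.0
                shift[k] = sign * cfg.de_log2fc
        for group in (CONTROL_GROUP, CASE_GROUP):
            for r in range(cfg.n_replicates):
                name = f"{stratum}_{group}_{r + 1}"
                mu = baseline.to_numpy() + (shift if group == CASE_GROUP else 0.0)
                data[name] = mu + rng.normal(0.0, cfg.log2_sigma, size=len(feature_ids))
                columns.append(name)
                sheet_rows.append(dict(sample=name, group=group, stratum=stratum))
    matrix = pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"))
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "group", "stratum"])
    return matrix, sheet


def simulate_matrix(
    n_features: int,
    n_per_group: int,
    de_fraction: float,
    de_log2fc: float,
    sigma: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Flat two-group matrix for calibration/power studies.

    Returns (matrix, sample sheet with stratum "sim", boolean truth vector
    of planted DE).  Planted features are shifted up or down alternately.
    """
    rng = np.random.default_rng(seed)
    n_de = int(round(de_fraction * n_features))
    is_de = np.zeros(n_features, dtype=bool)
    is_de[:n_de] = True
    signs = np.where(np.arange(n_features) % 2 == 0, 1.0, -1.0)
    shift = np.where(is_de, signs * de_log2fc, 0.0)
    baseline = rng.uniform(6.0, 12.0, size=n_features)
    cols = {}
    sheet_rows = []
    for group in (CONTROL_GROUP, CASE_GROUP):
        for r in range(n_per_group):
            name = f"{group}_{r + 1}"
            mu = baseline + (shift if group == CASE_GROUP else 0.0)
            cols[name] = mu + rng.normal(0.0, sigma, size=n_features)
            sheet_rows.append(dict(sample=name, group=group, stratum="sim"))
    idx = pd.Index([f"f{i:05d}" for i in range(n_features)], name="feature_id")
    return (
        pd.DataFrame(cols, index=idx),
        pd.DataFrame(sheet_rows, columns=["sample", "group", "stratum"]),
        is_de,
    )


# ---------------------------------------------------------------------------
# Ct generation


def generate_ct_table(
    cfg: SimulationConfig,
    truth: GroundTruth,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Technical-triplicate Ct table for a panel of planted pair members.

    Ct = per-gene baseline - log2(relative abundance) + noise; the
    reference gene (cyclophilin B) has zero group shift.  Columns:
    sample, group, stratum, gene, replicate, ct.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if genes is None:
        panel: list[str] = []
        for row in truth.pairs.itertuples(index=False):
            for fid in (row.gene_id, row.lnc_id):
                if fid not in panel:
                    panel.append(fid)
            if len(panel) >= 8:
                break
        genes = panel
    genes = list(genes)
    all_genes = genes + [REFERENCE_GENE]
    baseline = {g: float(rng.uniform(18.0, 28.0)) for g in all_genes}
    de = truth.de.set_index(["stratum", "feature_id"])

    rows: list[dict] = []
    for stratum in cfg.strata:
        for group in (CONTROL_GROUP, CASE_GROUP):
            for a in range(cfg.n_ct_animals):
                sample = f"{stratum}_{group}_a{a + 1}"
                # animal-level technical offset shared by all wells
                animal_eff = float(rng.normal(0.0, cfg.ct_sigma))
                for gene in all_genes:
                    shift = 0.0
                    if gene != REFERENCE_GENE and group == CASE_GROUP:
                        try:
                            row = de.loc[(stratum, gene)]
                            if bool(row["is_de"]):
                                sign = 1.0 if row["direction"] == "up" else -1.0
                                # higher abundance -> fewer cycles
                                shift = -sign * cfg.de_log2fc
                        except KeyError:
                            pass
                    mu = baseline[gene] + shift + animal_eff
                    for rep in range(3):
                        rows.append(
                            dict(
                                sample=sample,
                                group=group,
                                stratum=stratum,
                                gene=gene,
                                replicate=rep + 1,
                                ct=mu + float(rng.normal(0.0, cfg.ct_sigma / 2.0)),
                            )
                        )
    return pd.DataFrame(
        rows, columns=["sample", "group", "stratum", "gene", "replicate", "ct"]
    )


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    cfg: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate and write the full fixture set; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = generate_annotation(cfg)
    matrix, sheet = generate_expression(cfg, ann, truth)
    ct = generate_ct_table(cfg, truth)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "matrix": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "ct": outdir / "ct.tsv",
        "truth_classes": outdir / "truth_classes.tsv",
        "truth_de": outdir / "truth_de.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
    }
    write_annotation_tsv(ann, paths["annotation"])
    matrix.to_csv(paths["matrix"], sep="\t")
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    ct.to_csv(paths["ct"], sep="\t", index=False)
    truth.classes.to_csv(paths["truth_classes"], sep="\t", index=False)
    truth.de.to_csv(paths["truth_de"], sep="\t", index=False)
    truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
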