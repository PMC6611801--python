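"""Positional classification: definitional cases, oracle equivalence,
partition/monotonicity/strand-flip properties, and host-gene rollup."""

import numpy as np
import pytest

from glomlnc.annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    LncRNAModel,
    build_interval_index,
    gap_distance,
)
from glomlnc.classify import (
    CLASSES,
    ClassifiedLncRNA,
    class_counts,
    classify_all,
    classify_lncrna,
    host_gene_rollup,
)
from .conftest import make_gene, make_lnc, random_annotation


def brute_force_classify(ann: AnnotationSet, window_bp=50_000):
    """All-pairs scan applying the same overlap/strand/window rules."""
    out = {}
    for lnc in ann.lncrnas:
        overlapping = [
            g for g in ann.genes
            if g.interval.chrom == lnc.interval.chrom
            and lnc.interval.overlaps(g.interval)
        ]
        if overlapping:
            sense = any(
                g.interval.strand == lnc.interval.strand for g in overlapping
            )
            cls = "intragenic_sense" if sense else "intragenic_antisense"
            out[lnc.lnc_id] = (cls, sorted(g.gene_id for g in overlapping), 0)
            continue
        gaps = [
            (gap_distance(lnc.interval, g.interval)[0], g.gene_id)
            for g in ann.genes
            if g.interval.chrom == lnc.interval.chrom
        ]
        if not gaps or min(g for g, _ in gaps) >= window_bp:
            out[lnc.lnc_id] = ("linc_orphan", [], None)
        else:
            best = min(g for g, _ in gaps)
            out[lnc.lnc_id] = (
                "linc_neighbor",
                sorted(gid for g, gid in gaps if g == best),
                best,
            )
    return out


class TestClassifyOne:
    @pytest.fixture
    def plus_gene_index(self):
        gene = make_gene("geneA", "chr1", 1000, 5000, "+")
        return build_interval_index(AnnotationSet(genes=[gene]))

    def test_sense_overlap(self, plus_gene_index):
        rec = classify_lncrna(make_lnc("l", "chr1", 2000, 3000, "+"), plus_gene_index)
        assert rec.spatial_class == "intragenic_sense"
        assert rec.partner_gene_ids == ("geneA",)
        assert rec.gap_bp == 0

    def test_antisense_overlap(self, plus_gene_index):
        rec = classify_lncrna(make_lnc("l", "chr1", 2000, 3000, "-"), plus_gene_index)
        assert rec.spatial_class == "intragenic_antisense"

    def test_neighbor_with_orientation(self, plus_gene_index):
        rec = classify_lncrna(make_lnc("l", "chr1", 6000, 7000, "+"), plus_gene_index)
        assert rec.spatial_class == "linc_neighbor"
        assert rec.gap_bp == 1000
        assert rec.relative_position == "downstream"  # 3' of a + gene
        assert rec.same_strand_as_partner is True
        assert rec.proximal_flag is True

    def test_upstream_of_minus_gene(self):
        gene = make_gene("geneB", "chr1", 10_000, 20_000, "-")
        idx = build_interval_index(AnnotationSet(genes=[gene]))
        # right of a minus-strand gene is its 5' side
        rec = classify_lncrna(make_lnc("l", "chr1", 25_000, 26_000, "+"), idx)
        assert rec.relative_position == "upstream"
        assert rec.same_strand_as_partner is False

    def test_window_boundary_is_strict(self, plus_gene_index):
        at_window = classify_lncrna(
            make_lnc("l", "chr1", 55_000, 56_000, "+"), plus_gene_index
        )
        assert at_window.spatial_class == "linc_orphan"  # gap exactly 50,000
        inside = classify_lncrna(
            make_lnc("l", "chr1", 54_999, 56_000, "+"), plus_gene_index
        )
        assert inside.spatial_class == "linc_neighbor"

    def test_empty_chromosome_gives_orphan(self, plus_gene_index):
        rec = classify_lncrna(make_lnc("l", "chr9", 0, 1000, "+"), plus_gene_index)
        assert rec.spatial_class == "linc_orphan"
        assert rec.partner_gene_ids == ()

    def test_sense_priority_over_antisense(self):
        genes = [
            make_gene("gplus", "chr1", 1000, 5000, "+"),
            make_gene("gminus", "chr1", 2000, 6000, "-"),
        ]
        idx = build_interval_index(AnnotationSet(genes=genes))
        rec = classify_lncrna(make_lnc("l", "chr1", 2500, 3000, "+"), idx)
        assert rec.spatial_class == "intragenic_sense"
        assert set(rec.partner_gene_ids) == {"gplus", "gminus"}


class TestClassifyAll:
    def test_planted_counts_recovered(self, default_cohort):
        cfg, ann, truth = default_cohort
        counts = class_counts(classify_all(ann))
        assert counts == cfg.planted_counts

    def test_empty_lncrna_set(self):
        ann = AnnotationSet(genes=[make_gene("g", "chr1", 0, 1000)])
        assert classify_all(ann) == []

    def test_partition_property(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ann = random_annotation(rng, n_genes=40, n_lnc=60)
            counts = class_counts(classify_all(ann))
            assert sum(counts.values()) == len(ann.lncrnas)

    def test_equals_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            ann = random_annotation(rng, n_genes=50, n_lnc=80, n_chroms=3)
            expected = brute_force_classify(ann)
            for rec in classify_all(ann):
                cls, partners, gap = expected[rec.lnc_id]
                assert rec.spatial_class == cls
                assert sorted(rec.partner_gene_ids) == partners
                assert rec.gap_bp == gap

    def test_window_monotonicity(self):
        """Growing the window never turns a neighbor into an orphan."""
        rng = np.random.default_rng(23)
        ann = random_annotation(rng, n_genes=30, n_lnc=50)
        small = {r.lnc_id: r.spatial_class for r in classify_all(ann, window_bp=10_000)}
        large = {r.lnc_id: r.spatial_class for r in classify_all(ann, window_bp=80_000)}
        for lid, cls in small.items():
            if cls == "linc_neighbor":
                assert large[lid] == "linc_neighbor"

    def test_strand_flip_swaps_only_sense_antisense(self):
        rng = np.random.default_rng(24)
        ann = random_annotation(rng, n_genes=30, n_lnc=50)
        flipped = AnnotationSet(
            genes=[
                GeneModel(
                    g.gene_id, g.symbol,
                    GenomicInterval(
                        g.interval.chrom, g.interval.start, g.interval.end,
                        "-" if g.interval.strand == "+" else "+",
                    ),
                )
                for g in ann.genes
            ],
            lncrnas=[
                LncRNAModel(
                    l.lnc_id,
                    GenomicInterval(
                        l.interval.chrom, l.interval.start, l.interval.end,
                        "-" if l.interval.strand == "+" else "+",
                    ),
                )
                for l in ann.lncrnas
            ],
        )
        orig = {r.lnc_id: r.spatial_class for r in classify_all(ann)}
        flip = {r.lnc_id: r.spatial_class for r in classify_all(flipped)}
        for lid in orig:
            a, b = orig[lid], flip[lid]
            if a.startswith("linc"):
                assert b == a  # intergenic status is strand-free
            else:
                assert b == a  # both strands flipped: sense stays sense


class TestHostGeneRollup:
    def _hosted(self, n_sense, n_anti):
        recs = []
        for i in range(n_sense):
            recs.append(
                ClassifiedLncRNA(f"s{i}", "intragenic_sense", ("host",), 0)
            )
        for i in range(n_anti):
            recs.append(
                ClassifiedLncRNA(f"a{i}", "intragenic_antisense", ("host",), 0)
            )
        return recs

    def test_counts_and_split(self):
        recs = self._hosted(3, 1)
        de = {"s0", "s1", "s2", "a0"}
        df = host_gene_rollup(recs, de)
        row = df.iloc[0]
        assert (row["gene_id"], row["n_de_lnc"], row["n_sense"], row["n_antisense"]) == (
            "host", 4, 3, 1
        )
        assert bool(row["multi"]) is True

    def test_gene_without_de_lnc_absent(self):
        recs = self._hosted(2, 0)
        df = host_gene_rollup(recs, set())
        assert df.empty

    def test_heavy_host_tops_rollup(self):
        recs = self._hosted(12, 0) + [
            ClassifiedLncRNA("x0", "intragenic_sense", ("other",), 0)
        ]
        de = {f"s{i}" for i in range(12)} | {"x0"}
        df = host_gene_rollup(recs, de)
        assert df.iloc[0]["gene_id"] == "host"
        assert df.iloc[0]["n_de_lnc"] == 12
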