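"""Pairing of DE lncRNAs with DE genes, pattern tabulation, proximal
sub-analysis, and Venn membership across strata."""

import numpy as np
import pandas as pd
import pytest

from glomlnc.classify import ClassifiedLncRNA, classify_all
from glomlnc.diffexpr import call_de
from glomlnc.pairs import (
    PATTERNS,
    PairingError,
    PairRecord,
    build_pairs,
    concordance_table,
    dedupe_pairs_across_strata,
    pairs_to_frame,
    proximal_analysis,
    venn_membership,
)
from glomlnc.simulate import (
    CASE_GROUP,
    CONTROL_GROUP,
    generate_annotation,
    generate_expression,
)


def de_table(rows):
    """rows: (feature_id, direction, significant)"""
    return pd.DataFrame(rows, columns=["feature_id", "direction", "significant"])


SENSE_REC = ClassifiedLncRNA("lncA", "intragenic_sense", ("geneA",), 0)


class TestBuildPairs:
    def test_both_up_gives_concordant_pattern(self):
        pairs = build_pairs(
            [SENSE_REC],
            de_table([("lncA", "up", True)]),
            de_table([("geneA", "up", True)]),
            "24w",
        )
        assert len(pairs) == 1
        assert pairs[0].pattern == "gene_up_lnc_up"
        assert pairs[0].relation == "sense"

    def test_non_de_gene_makes_no_pair(self):
        pairs = build_pairs(
            [SENSE_REC],
            de_table([("lncA", "up", True)]),
            de_table([("geneA", "up", False)]),
            "24w",
        )
        assert pairs == []

    def test_orphan_never_pairs(self):
        rec = ClassifiedLncRNA("lncB", "linc_orphan")
        pairs = build_pairs(
            [rec], de_table([("lncB", "up", True)]), de_table([]), "24w"
        )
        assert pairs == []

    def test_multi_host_gene_yields_multiple_pairs(self):
        recs = [
            ClassifiedLncRNA("lnc1", "intragenic_sense", ("geneA",), 0),
            ClassifiedLncRNA("lnc2", "intragenic_antisense", ("geneA",), 0),
        ]
        pairs = build_pairs(
            recs,
            de_table([("lnc1", "up", True), ("lnc2", "down", True)]),
            de_table([("geneA", "up", True)]),
            "24w",
        )
        assert {p.relation for p in pairs} == {"sense", "antisense"}

    def test_planted_plan_recovered_exactly(self, default_cohort):
        cfg, ann, truth = default_cohort
        matrix, sheet = generate_expression(cfg, ann, truth)
        focal = cfg.focal_stratum
        de = call_de(matrix, sheet, focal, CASE_GROUP, CONTROL_GROUP)
        lnc_ids = {l.lnc_id for l in ann.lncrnas}
        classified = classify_all(ann)
        pairs = build_pairs(
            classified,
            de[de["feature_id"].isin(lnc_ids)],
            de[~de["feature_id"].isin(lnc_ids)],
            focal,
        )
        got = {(p.lnc_id, p.gene_id, p.pattern) for p in pairs}
        planted = truth.pairs[truth.pairs["stratum"] == focal]
        want = {(r.lnc_id, r.gene_id, r.pattern) for r in planted.itertuples()}
        assert got == want


class TestConcordanceTable:
    def test_single_cell_count(self):
        pairs = [
            PairRecord("l", f"g{i}", "sense", "24w", "up", "up",
                       "gene_up_lnc_up", 0, True, None)
            for i in range(3)
        ]
        tbl = concordance_table(pairs)
        cell = tbl[
            (tbl["relation"] == "sense") & (tbl["pattern"] == "gene_up_lnc_up")
        ]
        assert int(cell["count"].iloc[0]) == 3
        total = tbl[(tbl["relation"] == "sense") & (tbl["pattern"] == "total")]
        assert int(total["count"].iloc[0]) == 3

    def test_empty_pairs_all_zero(self):
        tbl = concordance_table([])
        assert tbl.empty or (tbl["count"] == 0).all()

    def test_equals_brute_force_tally(self):
        rng = np.random.default_rng(41)
        pairs = []
        for i in range(200):
            rel = ("sense", "antisense", "neighbor")[rng.integers(0, 3)]
            pat = PATTERNS[rng.integers(0, 4)]
            gdir = "up" if pat.startswith("gene_up") else "down"
            ldir = "up" if pat.endswith("lnc_up") else "down"
            pairs.append(
                PairRecord(f"l{i}", f"g{rng.integers(0, 50)}", rel,
                           ("8w", "24w")[rng.integers(0, 2)], ldir, gdir, pat,
                           None, None, None)
            )
        tbl = concordance_table(pairs).set_index(["relation", "stratum", "pattern"])
        for rel in ("sense", "antisense", "neighbor"):
            for st in ("8w", "24w"):
                for pat in PATTERNS:
                    brute = sum(
                        1 for p in pairs
                        if p.relation == rel and p.stratum == st and p.pattern == pat
                    )
                    assert tbl.loc[(rel, st, pat), "count"] == brute

    def test_marginal_sums_to_total_pairs(self):
        rng = np.random.default_rng(42)
        pairs = [
            PairRecord(f"l{i}", "g", ("sense", "antisense", "neighbor")[rng.integers(0, 3)],
                       "24w", "up", "up", "gene_up_lnc_up", None, None, None)
            for i in range(57)
        ]
        tbl = concordance_table(pairs)
        totals = tbl[tbl["pattern"] == "total"]["count"].sum()
        assert totals == 57


def neighbor_pair(i, gap, same_dir=True, downstream=True, same_strand=True):
    return PairRecord(
        f"l{i}", f"g{i}", "neighbor", "24w",
        "up" if same_dir else "down", "up",
        "gene_up_lnc_up" if same_dir else "gene_up_lnc_down",
        gap, same_strand, "downstream" if downstream else "upstream",
    )


class TestProximalAnalysis:
    def test_strict_threshold(self):
        pairs = [neighbor_pair(0, 4999), neighbor_pair(1, 5000)]
        summary = proximal_analysis(pairs)
        assert summary["n_proximal"] == 1

    def test_planted_13_of_12_structure(self, default_cohort):
        cfg, ann, truth = default_cohort
        planted = truth.pairs[truth.pairs["proximal"]]
        assert len(planted) == 13
        concordant = sum(
            1 for r in planted.itertuples()
            if r.pattern in ("gene_up_lnc_up", "gene_down_lnc_down")
        )
        assert concordant == 12

    def test_empty_input(self):
        assert proximal_analysis([]) == {
            "n_proximal": 0, "n_same_pattern": 0,
            "n_downstream": 0, "n_same_strand": 0,
        }

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(43)
        pairs = [neighbor_pair(i, int(rng.integers(0, 50_000))) for i in range(100)]
        counts = [
            proximal_analysis(pairs, threshold_bp=t)["n_proximal"]
            for t in (1_000, 5_000, 20_000, 50_001)
        ]
        assert counts == sorted(counts)


def sig_table(ids):
    return pd.DataFrame(
        {"feature_id": list(ids), "direction": "up", "significant": True}
    )


class TestVennMembership:
    def test_region_assignment(self):
        frame, regions = venn_membership(
            {"8w": sig_table(["a", "b"]), "16w": sig_table(["b"]),
             "24w": sig_table(["c"])}
        )
        by_id = frame.set_index("feature_id")["strata"]
        assert by_id["b"] == frozenset({"8w", "16w"})
        assert regions[frozenset({"8w"})] == 1
        assert regions[frozenset({"8w", "16w"})] == 1
        assert regions[frozenset({"24w"})] == 1

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(44)
        tables = {
            s: sig_table({f"f{rng.integers(0, 60)}" for _ in range(30)})
            for s in ("8w", "16w", "24w")
        }
        frame, regions = venn_membership(tables)
        union = set()
        for t in tables.values():
            union |= set(t["feature_id"])
        assert sum(regions.values()) == len(union)

    def test_requires_two_strata(self):
        with pytest.raises(PairingError):
            venn_membership({"24w": sig_table(["a"])})


class TestDedupe:
    def test_cross_stratum_dedup(self):
        pairs = [
            PairRecord("l", "g", "sense", "16w", "up", "up",
                       "gene_up_lnc_up", 0, True, None),
            PairRecord("l", "g", "sense", "24w", "up", "up",
                       "gene_up_lnc_up", 0, True, None),
        ]
        df = dedupe_pairs_across_strata(pairs)
        assert len(df) == 1
        assert len(pairs_to_frame(pairs)) == 2
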