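"""End-to-end orchestration: simulate -> de -> classify -> pair ->
chromstats -> enrich -> qpcr -> compare, with a hashed manifest.

Each stage writes TSV outputs under one output directory.  The manifest
records, per stage, the parameters, output files with SHA-256 hashes,
and row counts, so identical (inputs, config, seed) reruns are provably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chromdist, classify, diffexpr, enrichment, pairs, qpcr, simulate
from .annotation import read_annotation_tsv
from .crossdataset import harmonize, sam_test

log = logging.getLogger("glomlnc")

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_INTERNAL_ERROR = 4


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path = Path("glomlnc_out")
    seed: int = 0
    fc_high: float = 2.0
    fc_low: float = 0.5
    fdr: float = 0.05
    window_bp: int = 50_000
    proximal_bp: int = 5_000
    case: str = simulate.CASE_GROUP
    control: str = simulate.CONTROL_GROUP
    strata: tuple[str, ...] = ("8w", "16w", "24w")
    focal_stratum: str = "24w"
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (self.fc_high > 1 > self.fc_low > 0):
            raise ConfigError(
                f"need fc_high > 1 > fc_low > 0, got {self.fc_high}, {self.fc_low}"
            )
        if not (0 < self.fdr < 1):
            raise ConfigError(f"fdr must lie in (0, 1): {self.fdr}")
        if not (self.window_bp > self.proximal_bp > 0):
            raise ConfigError(
                f"need window_bp > proximal_bp > 0: {self.window_bp}, {self.proximal_bp}"
            )
        if self.focal_stratum not in self.strata:
            raise ConfigError("focal_stratum must be one of strata")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        raw.update(overrides)
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        sim_cfg = simulate.SimulationConfig(
            seed=raw.get("seed", 0), **sim_raw
        )
        return cls(sim=sim_cfg, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict."""
    t0 = time.time()
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed, "parameters": {
        "fc_high": cfg.fc_high, "fc_low": cfg.fc_low, "fdr": cfg.fdr,
        "window_bp": cfg.window_bp, "proximal_bp": cfg.proximal_bp,
    }}

    def record(stage: str, files: dict[str, Path], **extra) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
                **extra,
            }
        )
        log.info("stage %-10s done (%.1fs)", stage, time.time() - t0)

    # 1. simulate
    sim_cfg = cfg.sim
    if sim_cfg.seed != cfg.seed:
        sim_cfg = simulate.SimulationConfig(
            **{**vars(sim_cfg), "seed": cfg.seed}
        )
    paths = simulate.write_fixture_bundle(sim_cfg, outdir / "fixtures")
    ann = read_annotation_tsv(paths["annotation"])
    truth = simulate.GroundTruth(
        classes=pd.read_csv(paths["truth_classes"], sep="\t"),
        de=pd.read_csv(paths["truth_de"], sep="\t"),
        pairs=pd.read_csv(paths["truth_pairs"], sep="\t"),
    )
    matrix = pd.read_csv(paths["matrix"], sep="\t", index_col=0)
    sheet = pd.read_csv(paths["samples"], sep="\t")
    ct = pd.read_csv(paths["ct"], sep="\t")
    record("simulate", paths, n_genes=len(ann.genes), n_lncrnas=len(ann.lncrnas))

    # 2. differential expression per stratum
    lnc_ids = {l.lnc_id for l in ann.lncrnas}
    de_tables: dict[str, pd.DataFrame] = {}
    de_files: dict[str, Path] = {}
    for stratum in cfg.strata:
        de = diffexpr.call_de(matrix, sheet, stratum, cfg.case, cfg.control)
        de_tables[stratum] = de
        de_files[stratum] = _write(de, outdir / f"de_{stratum}.tsv")
    record("de", de_files, strata=list(cfg.strata))

    # 3. classification
    classified = classify.classify_all(
        ann, window_bp=cfg.window_bp, proximal_bp=cfg.proximal_bp
    )
    cls_frame = classify.classification_to_frame(classified)
    cls_path = _write(cls_frame, outdir / "classification.tsv")
    counts = classify.class_counts(classified)
    record("classify", {"classification": cls_path}, class_counts=counts)

    # 4. pairs + concordance + proximal + venn
    all_pairs: list[pairs.PairRecord] = []
    for stratum in cfg.strata:
        de = de_tables[stratum]
        de_lnc = de[de["feature_id"].isin(lnc_ids)]
        de_gene = de[~de["feature_id"].isin(lnc_ids)]
        all_pairs.extend(pairs.build_pairs(classified, de_lnc, de_gene, stratum))
    pair_frame = pairs.pairs_to_frame(all_pairs)
    conc = pairs.concordance_table(all_pairs)
    prox = pairs.proximal_analysis(
        [p for p in all_pairs if p.stratum == cfg.focal_stratum],
        threshold_bp=cfg.proximal_bp,
    )
    venn_frame, venn_regions = pairs.venn_membership(
        {s: de_tables[s] for s in cfg.strata}, feature_subset=lnc_ids
    )
    venn_rows = pd.DataFrame(
        [
            {"region": "+".join(sorted(k)), "count": v}
            for k, v in sorted(venn_regions.items(), key=lambda kv: sorted(kv[0]))
        ]
    )
    pair_files = {
        "pairs": _write(pair_frame, outdir / "pairs.tsv"),
        "concordance": _write(conc, outdir / "concordance.tsv"),
        "proximal": _write(
            pd.DataFrame([prox]), outdir / "proximal_summary.tsv"
        ),
        "venn": _write(venn_rows, outdir / "venn.tsv"),
    }
    record("pair", pair_files, proximal=prox)

    # 5. chromosome distribution (focal stratum)
    focal_de = set(
        de_tables[cfg.focal_stratum].loc[
            de_tables[cfg.focal_stratum]["significant"], "feature_id"
        ]
    )
    chrom_files = {}
    chrom_summary = {}
    for category in chromdist.CATEGORIES:
        ids = focal_de & {
            fid for fid, _ in chromdist._category_features(ann, category, classified)
        }
        stats_df, mean, sd = chromdist.chrom_stats(ann, ids, category, classified)
        chrom_files[category] = _write(stats_df, outdir / f"chromstats_{category}.tsv")
        chrom_summary[category] = {"mean_pct": mean, "sd_pct": sd}
    record("chromstats", chrom_files, summary=chrom_summary)

    # 6. enrichment: genes partnered with DE lncRNAs vs synthetic gene sets
    de_lnc_ids = focal_de & lnc_ids
    query = sorted(
        {
            gid
            for rec in classified
            if rec.lnc_id in de_lnc_ids
            for gid in rec.partner_gene_ids
        }
    )
    universe = {g.gene_id for g in ann.genes}
    collection = _synthetic_gene_sets(ann, query, universe, cfg.seed)
    gmt_path = outdir / "genesets.gmt"
    enrichment.write_gmt(collection, gmt_path)
    if query:
        enr = enrichment.ora(query, collection)
    else:
        enr = pd.DataFrame()
    enr_path = _write(enr, outdir / "enrichment.tsv")
    record("enrich", {"gmt": gmt_path, "enrichment": enr_path}, n_query=len(query))

    # 7. qPCR validation panel
    panel = sorted(set(ct["gene"]) - {simulate.REFERENCE_GENE})
    qp = qpcr.ddct_table(
        ct, panel, cfg.case, cfg.control,
        reference_gene=simulate.REFERENCE_GENE, stratum=cfg.focal_stratum,
    )
    qp_path = _write(qp, outdir / "qpcr.tsv")
    record("qpcr", {"qpcr": qp_path}, n_genes=len(panel))

    # 8. cross-dataset comparison: SAM on the focal stratum plus a
    #    harmonized join of the per-stratum DE tables as pseudo-studies
    focal_sheet = sheet[sheet["stratum"] == cfg.focal_stratum]
    groups = focal_sheet.set_index("sample")["group"]
    sam = sam_test(
        matrix[focal_sheet["sample"].tolist()],
        groups,
        case=cfg.case,
        control=cfg.control,
        n_perm=200,
        seed=cfg.seed,
    )
    studies = {
        s: de_tables[s].rename(columns={"feature_id": "gene_id"})[
            ["gene_id", "fc", "significant"]
        ]
        for s in cfg.strata
    }
    conc_matrix = harmonize(studies, join="outer")
    cmp_files = {
        "sam": _write(sam, outdir / "sam.tsv"),
        "concordance_matrix": _write(conc_matrix, outdir / "cross_dataset.tsv"),
    }
    record("compare", cmp_files, n_harmonized=len(conc_matrix))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.1fs -> %s", time.time() - t0, outdir)
    return manifest


def _synthetic_gene_sets(
    ann, query: list[str], universe: set[str], seed: int
) -> enrichment.GeneSetCollection:
    """Gene sets for the synthetic cohort: one set built around the query
    (enriched by construction) plus random background sets."""
    import numpy as np

    rng = np.random.default_rng(seed + 3)
    uni = sorted(universe)
    sets: dict[str, list[str]] = {}
    core = list(query[: max(3, len(query) // 2)])
    pad = [g for g in uni if g not in core]
    rng.shuffle(pad)
    sets["cis_candidate_hosts"] = sorted(core + pad[: max(2, len(core) // 3)])
    for i in range(6):
        size = int(rng.integers(5, max(6, len(uni) // 3)))
        sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(uni, size=min(size, len(uni)), replace=False).tolist()
        )
    return enrichment.GeneSetCollection(sets=sets, universe=universe)


def check_against_truth(
    manifest: dict,
    cfg: PipelineConfig,
) -> dict:
    """Compare pipeline outputs in cfg.outdir against the planted truth.

    Returns a dict of booleans/counters used by the end-to-end tests and
    the reproducibility script.
    """
    outdir = cfg.outdir
    truth_classes = pd.read_csv(outdir / "fixtures" / "truth_classes.tsv", sep="\t")
    truth_pairs = pd.read_csv(outdir / "fixtures" / "truth_pairs.tsv", sep="\t")
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t")
    merged = truth_classes.merge(cls, on="lnc_id")
    class_match = bool((merged["true_class"] == merged["spatial_class"]).all())

    pair_frame = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    focal_pairs = pair_frame[pair_frame["stratum"] == cfg.focal_stratum]
    planted = truth_pairs[truth_pairs["stratum"] == cfg.focal_stratum]
    got = {(r.lnc_id, r.gene_id, r.pattern) for r in focal_pairs.itertuples()}
    want = {(r.lnc_id, r.gene_id, r.pattern) for r in planted.itertuples()}
    prox = pd.read_csv(outdir / "proximal_summary.tsv", sep="\t").iloc[0]
    return {
        "class_counts_match": class_match,
        "pairs_match_plan": got == want,
        "n_pairs_recovered": len(got & want),
        "n_pairs_planted": len(want),
        "n_pairs_extra": len(got - want),
        "proximal_total": int(prox["n_proximal"]),
        "proximal_concordant": int(prox["n_same_pattern"]),
        "proximal_downstream": int(prox["n_downstream"]),
        "proximal_same_strand": int(prox["n_same_strand"]),
    }
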