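"""End-to-end orchestration: simulate/load -> tile -> DMR -> cluster ->
annotate -> enrich -> DE -> integrate, with a reproducible run directory.

A run is driven by a :class:`PipelineConfig` (YAML on disk).  Inputs are
either a sample sheet pointing at cytosine reports plus a GTF and a counts
matrix, or a synthetic-data block that generates them.  Every stage writes
its tables before the next stage starts, so a failure retains partial
outputs; the manifest records the seed, parameters and SHA-256 checksums
of every output (no timestamps, so repeated seeded runs are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import dmr as dmr_mod
from . import expression as expr_mod
from . import io as io_mod
from . import tiling
from .core import CELL_TYPES
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

ADJACENT_COMPARISONS = (("EC", "HEC"), ("HEC", "HSPC"))


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed of one pipeline run.

    Threshold defaults are the study's printed values: 500 bp tiles, DMR
    difference 0.2 at adjusted p 0.05, promoter TSS +/- 1 kb, DEG |log2FC|
    >= 1, correlation threshold -0.3.
    """

    outdir: str = "tilemeth_run"
    sample_sheet: str | None = None
    annotation: str | None = None
    counts: str | None = None
    chrom_sizes: str | None = None  # optional; otherwise inferred from the data
    simulate: dict | None = None
    tile_size: int = 500
    diff_threshold: float = 0.2
    alpha: float = 0.05
    min_shared_cpg: int = 3
    corr_threshold: float = -0.3
    min_meth_range: float = 0.2
    deg_alpha: float = 0.05
    lfc_threshold: float = 1.0
    promoter_up: int = 1000
    promoter_down: int = 1000
    cluster_backend: str = "rule"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.deg_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.diff_threshold <= 0 or self.diff_threshold >= 1:
            raise ValueError("diff_threshold must lie in (0, 1)")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.simulate is None:
            for name in ("sample_sheet", "annotation", "counts"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config must set {name} (or a simulate block)")
                if not os.path.exists(p):
                    raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "inputs"
    t0 = time.time()
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
            ds = simulate_dataset(sim_cfg, outdir=out / "data")
            samples, meta = ds.samples, ds.sample_meta
            chrom_sizes = ds.genome.chrom_sizes
            genes = ds.genome.genes
            counts = ds.counts
        else:
            sheet = io_mod.read_sample_sheet(config.sample_sheet)
            samples = io_mod.load_samples(sheet)
            meta = sheet.drop(columns="file")
            genes = ann.read_gtf(config.annotation)
            if config.chrom_sizes is not None:
                chrom_sizes = io_mod.read_chrom_sizes(config.chrom_sizes)
            else:
                chrom_sizes = _chrom_sizes_from(samples, genes)
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "tile"
        tiles = tiling.make_tiles(chrom_sizes, config.tile_size)
        cohort = tiling.MethylomeCohort.from_samples(samples)
        tm = tiling.TileMatrix.from_cohort(cohort, tiles, config.tile_size)
        tm.to_wide_tsv(out / "tile_levels.tsv")
        levels = tm.levels()
        glob = pd.DataFrame(
            {
                "sample_id": tm.sample_ids,
                "global_level": [
                    tiling.global_methylation(levels[s]) for s in tm.sample_ids
                ],
            }
        ).merge(meta, on="sample_id")
        glob.to_csv(out / "global_levels.tsv", sep="\t", index=False, float_format="%.6g")
        cats = pd.DataFrame(
            [
                {"sample_id": s.sample_id, **tiling.cpg_category_fractions(s.records)}
                for s in samples
            ]
        )
        cats.to_csv(out / "cpg_categories.tsv", sep="\t", index=False, float_format="%.6g")
        logger.info("stage tile done (%.1fs)", time.time() - t0)

        stage = "dmr"
        comparisons: dict[str, tuple[list[str], list[str]]] = {}
        sib = meta["genotype"] == "sibling"
        for a, b in ADJACENT_COMPARISONS:
            comparisons[f"sibling_{a}_vs_{b}"] = (
                cohort.select(sib & (meta["cell_type"] == a)),
                cohort.select(sib & (meta["cell_type"] == b)),
            )
        if (meta["genotype"] == "mutant").any():
            for ct in CELL_TYPES:
                comparisons[f"{ct}_sibling_vs_mutant"] = (
                    cohort.select(sib & (meta["cell_type"] == ct)),
                    cohort.select(~sib & (meta["cell_type"] == ct)),
                )
        all_calls: dict[str, pd.DataFrame] = {}
        tested_ids: set[str] = set()
        summaries = []
        for name, (ga, gb) in comparisons.items():
            tested = dmr_mod.call_dmrs(
                tm, ga, gb,
                min_shared_cpg=config.min_shared_cpg,
                diff_threshold=config.diff_threshold,
                alpha=config.alpha,
                return_tested=True,
            )
            calls = tested[tested["called"]].drop(columns="called").reset_index(drop=True)
            all_calls[name] = calls
            if name.startswith("sibling_"):
                tested_ids.update(tested["tile_id"])
            calls.to_csv(out / f"dmr_{name}.tsv", sep="\t", index=False, float_format="%.6g")
            bed = calls.copy()
            bed["score"] = -np.log10(np.maximum(bed["p_adj"], 1e-300))
            bed["strand"] = "."
            io_mod.write_bed(
                bed[["chrom", "start0", "end0", "tile_id", "score", "strand",
                     "mean_a", "mean_b", "diff", "direction"]],
                out / f"dmr_{name}.bed",
            )
            summaries.append({"comparison": name, "n_dmr": len(calls),
                              **dmr_mod.dmr_direction_summary(calls)})
        pd.DataFrame(summaries).to_csv(
            out / "dmr_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        logger.info("stage dmr done (%.1fs)", time.time() - t0)

        stage = "cluster"
        union_ids = sorted(
            set().union(*(all_calls[f"sibling_{a}_vs_{b}"]["tile_id"]
                          for a, b in ADJACENT_COMPARISONS))
        )
        profiles = _sibling_profiles(tm, meta, union_ids)
        clustered = dmr_mod.assign_six_clusters(
            profiles, backend=config.cluster_backend, random_state=config.seed
        )
        clustered.to_csv(out / "dmr_clusters.tsv", sep="\t", float_format="%.6g")
        logger.info("stage cluster done (%.1fs)", time.time() - t0)

        stage = "annotate"
        features = ann.build_feature_sets(
            genes, chrom_sizes, up=config.promoter_up, down=config.promoter_down
        )
        union_regions = tm.tiles[tm.tiles["tile_id"].isin(union_ids)].reset_index(drop=True)
        annotated = ann.annotate_dmrs(union_regions, features)
        annotated.to_csv(out / "dmr_features.tsv", sep="\t", index=False)
        ann.feature_distribution(annotated).rename("percent").rename_axis("feature").to_csv(
            out / "dmr_feature_distribution.tsv", sep="\t", float_format="%.6g"
        )
        universe = tm.tiles[tm.tiles["tile_id"].isin(tested_ids)].reset_index(drop=True)
        enrichment = ann.region_set_enrichment(union_regions, features, universe)
        enrichment.to_csv(out / "dmr_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        logger.info("stage annotate done (%.1fs)", time.time() - t0)

        stage = "deg"
        normalized = expr_mod.normalize_counts(counts)
        sib_ids = [s for s in counts.columns if s in set(meta.loc[sib, "sample_id"])]
        mut_ids = [s for s in counts.columns if s not in set(sib_ids)]
        degs = expr_mod.call_degs(
            normalized, sib_ids, mut_ids,
            deg_alpha=config.deg_alpha, lfc_threshold=config.lfc_threshold,
        )
        degs.to_csv(out / "degs.tsv", sep="\t", index=False, float_format="%.6g")
        logger.info("stage deg done (%.1fs)", time.time() - t0)

        stage = "integrate"
        prom = expr_mod.promoter_methylation_matrix(
            cohort, genes, up=config.promoter_up, down=config.promoter_down,
            chrom_sizes=chrom_sizes,
        )
        passing = degs[degs["passes"]]
        integration = expr_mod.integrate(
            passing, prom, normalized, meta,
            corr_threshold=config.corr_threshold,
            min_meth_range=config.min_meth_range,
        )
        integration.to_csv(out / "integration.tsv", sep="\t", index=False, float_format="%.6g")
        stage_sets = expr_mod.stage_transition_filter(
            list(passing["gene_id"]), prom, normalized, meta
        )
        stage_rows = [
            {"transition": tr, "gene_id": g}
            for tr, genes_tr in stage_sets.items()
            for g in genes_tr
        ]
        pd.DataFrame(stage_rows, columns=["transition", "gene_id"]).to_csv(
            out / "stage_transition_genes.tsv", sep="\t", index=False
        )
        logger.info("stage integrate done (%.1fs)", time.time() - t0)

        stage = "manifest"
        outputs = sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seed": config.seed,
            "parameters": dataclasses.asdict(config),
            "outputs": {p: _sha256(out / p) for p in outputs},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise
    return out


def _chrom_sizes_from(samples, genes) -> dict[str, int]:
    """Fallback chromosome sizes: the furthest observed coordinate, rounded up."""
    ends: dict[str, int] = {}
    for s in samples:
        for chrom, sub in s.records.groupby("chrom"):
            ends[chrom] = max(ends.get(chrom, 0), int(sub["pos0"].max()) + 2)
    for g in genes:
        ends[g.chrom] = max(ends.get(g.chrom, 0), g.end0)
    return ends


def _sibling_profiles(tm, meta, tile_ids) -> pd.DataFrame:
    """Mean sibling tile level per cell type for the given tiles."""
    levels = tm.levels()
    rows = {}
    for ct in CELL_TYPES:
        ids = meta.loc[
            (meta["genotype"] == "sibling") & (meta["cell_type"] == ct), "sample_id"
        ]
        rows[ct] = levels.loc[tile_ids, list(ids)].mean(axis=1)
    return pd.DataFrame(rows)


def report_summary(run_dir: str | os.PathLike) -> str:
    """Human-readable run summary, re-derived from the run's tables."""
    run = Path(run_dir)
    lines = ["tilemeth run summary", "====================", ""]

    def missing(name: str) -> bool:
        if not (run / name).exists():
            lines.append(f"[missing] {name} — stage did not complete")
            return True
        return False

    if not missing("global_levels.tsv"):
        glob = pd.read_csv(run / "global_levels.tsv", sep="\t")
        lines.append("Global methylation level per group (mean over samples):")
        grouped = glob.groupby(["genotype", "cell_type"])["global_level"].mean()
        for (geno, ct), lv in grouped.items():
            lines.append(f"  {geno:8s} {ct:5s} {100 * lv:6.2f}%")
        lines.append("")
    if not missing("dmr_summary.tsv"):
        summ = pd.read_csv(run / "dmr_summary.tsv", sep="\t")
        lines.append("DMR calls per comparison (group_b relative to group_a):")
        for _, r in summ.iterrows():
            if r["n_dmr"]:
                lines.append(
                    f"  {r['comparison']:28s} {int(r['n_dmr']):6d} DMRs  "
                    f"hyper {r['pct_hyper']:5.1f}%  hypo {r['pct_hypo']:5.1f}%"
                )
            else:
                lines.append(
                    f"  {r['comparison']:28s} {0:6d} DMRs  (percentages undefined)"
                )
        lines.append("")
    if not missing("dmr_clusters.tsv"):
        clusters = pd.read_csv(run / "dmr_clusters.tsv", sep="\t", index_col=0)
        if len(clusters):
            lines.append("Six-pattern cluster sizes (adjacent-stage DMR union):")
            for label, n in clusters["cluster"].value_counts().sort_index().items():
                lines.append(f"  {label}: {n}")
        else:
            lines.append("Six-pattern clusters: no DMRs to cluster")
        lines.append("")
    if not missing("dmr_feature_distribution.tsv"):
        dist = pd.read_csv(run / "dmr_feature_distribution.tsv", sep="\t")
        lines.append("DMR feature distribution (%):")
        for _, r in dist.iterrows():
            lines.append(f"  {r['feature']:10s} {r['percent']:5.1f}")
        lines.append("")
    if not missing("degs.tsv"):
        degs = pd.read_csv(run / "degs.tsv", sep="\t")
        up = int(((degs["passes"]) & (degs["log2fc"] > 0)).sum())
        down = int(((degs["passes"]) & (degs["log2fc"] < 0)).sum())
        lines.append(f"DEGs (mutant vs sibling): {up} up, {down} down")
    if not missing("integration.tsv"):
        integ = pd.read_csv(run / "integration.tsv", sep="\t")
        lines.append(
            f"Integration: {int(integ['selected'].sum())} of {len(integ)} DEGs "
            "negatively methylation-coupled in siblings only"
        )
    if not missing("stage_transition_genes.tsv"):
        st = pd.read_csv(run / "stage_transition_genes.tsv", sep="\t")
        for tr, n in st.groupby("transition").size().items():
            lines.append(f"Stage filter {tr}: {n} genes")
    return "\n".join(lines) + "\n"
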