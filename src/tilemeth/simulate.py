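"""Ground-truth-annotated synthetic WGBS + RNA-seq data generator.

The generator emulates a 3-cell-type (EC, HEC, HSPC) x 2-genotype
(sibling, mutant) x n-replicate design with:

* a globally high-methylation genome (tile-level beta baseline, mean ~0.8);
* cell-type-specific differentially methylated regions planted in the six
  canonical patterns of the cluster taxonomy (gradual gain C1, HSPC-hyper
  C2, HEC-hypo C3, HEC-hyper C4, EC-hypo C5, HSPC-hypo C6), anchored at
  coupled genes' promoters;
* a mutant genotype whose methylation is shifted down genome-wide and whose
  planted regions collapse to a low flat level (methylation dynamics
  abolished), giving the mutant many more hypo- than hyper-DMRs;
* gene expression negatively coupled to latent promoter methylation in
  sibling samples only; mutant samples and uncoupled genes are flat.

Counts are binomial reads at Poisson coverage per CpG, negative-binomial
per gene for expression.  Everything derives from one seeded generator, so
a fixed seed reproduces the dataset byte for byte; the ground truth (tile
patterns, true latent levels, coupled genes) is recorded alongside.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gtf
from .core import CELL_TYPES, GENOTYPES, MethylomeSample
from .io import (
    write_chrom_sizes,
    write_cytosine_report,
    write_sample_sheet,
)
from .tiling import make_tiles, site_tile_index

PATTERNS = ("C1", "C2", "C3", "C4", "C5", "C6")
#: (EC, HEC, HSPC) shape of each pattern on a 0..1 scale.
PATTERN_SHAPES: dict[str, tuple[float, float, float]] = {
    "C1": (0.0, 0.5, 1.0),
    "C2": (0.0, 0.0, 1.0),
    "C3": (1.0, 0.0, 1.0),
    "C4": (0.0, 1.0, 0.0),
    "C5": (0.0, 1.0, 1.0),
    "C6": (1.0, 1.0, 0.0),
}

GROUPS = [f"{g}:{c}" for g in GENOTYPES for c in CELL_TYPES]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults are the reference synthetic scale: 2 chromosomes x 1 Mb with
    ~100 bp CpG spacing (~4,000 tiles), 18 samples, 2,000 genes of which
    200 are methylation-coupled, 30x coverage.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    cpg_spacing_mean_bp: int = 100
    coverage_mean: float = 30.0
    baseline_meth_mean: float = 0.8
    baseline_meth_concentration: float = 15.0
    cpg_jitter_concentration: float = 100.0
    replicate_noise_sd: float = 0.03
    n_planted_dmrs_per_pattern: int = 34
    dmr_delta: float = 0.4
    mutant_hypomethylation_shift: float = 0.15
    n_genes: int = 2000
    n_coupled_genes: int = 200
    coupling_slope: float = -3.0
    expression_baseline_log2_low: float = 5.0
    expression_baseline_log2_high: float = 12.0
    nb_dispersion: float = 0.05
    replicates_per_group: int = 3
    tile_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome counts and lengths must be positive")
        if self.chrom_length_bp < 10 * self.tile_size:
            raise ValueError(
                f"chrom_length_bp must be at least 10 tiles "
                f"({10 * self.tile_size} bp)"
            )
        if self.cpg_spacing_mean_bp <= 0:
            raise ValueError("cpg_spacing_mean_bp must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        for name in ("baseline_meth_mean", "mutant_hypomethylation_shift"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.dmr_delta < 1:
            raise ValueError("dmr_delta must lie in (0, 1)")
        if self.baseline_meth_concentration <= 0 or self.cpg_jitter_concentration <= 0:
            raise ValueError("beta concentrations must be positive")
        if self.n_coupled_genes > self.n_genes:
            raise ValueError("n_coupled_genes cannot exceed n_genes")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class SimulatedGenome:
    chrom_sizes: dict[str, int]
    cpg_sites: pd.DataFrame  # chrom, pos0
    genes: list[GeneModel]
    tiles: pd.DataFrame


@dataclass
class GroundTruth:
    """What was planted: per-tile patterns, latent levels, coupled genes."""

    planted_tiles: pd.DataFrame  # tile_row, tile_id, pattern, delta, region_id
    true_tile_levels: pd.DataFrame  # n_tiles x GROUPS latent levels
    genes: pd.DataFrame  # gene_id, coupled, pattern, baseline_log2, slope
    true_global: dict[str, float] = field(default_factory=dict)

    def true_dmr_mask(self, group_a: str, group_b: str, threshold: float = 0.2) -> np.ndarray:
        """Tiles whose true latent levels differ by more than ``threshold``."""
        diff = self.true_tile_levels[group_b] - self.true_tile_levels[group_a]
        return np.abs(diff.to_numpy()) > threshold

    def stage_coupled_genes(self, ct_from: str, ct_to: str) -> list[str]:
        """Coupled genes with true promoter methylation gain at a transition."""
        shapes = self.genes["pattern"].map(
            lambda p: PATTERN_SHAPES.get(p, (0.0, 0.0, 0.0))
        )
        i_from, i_to = CELL_TYPES.index(ct_from), CELL_TYPES.index(ct_to)
        gain = shapes.map(lambda s: s[i_to] > s[i_from])
        sel = self.genes["coupled"] & gain
        return list(self.genes.loc[sel, "gene_id"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SimulatedGenome
    samples: list[MethylomeSample]
    sample_meta: pd.DataFrame
    counts: pd.DataFrame  # genes x samples
    truth: GroundTruth
    replicate_latent: np.ndarray = field(repr=False)  # n_tiles x n_samples


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> SimulatedGenome:
    """Chromosomes, CpG map (geometric spacing) and two-exon gene models."""
    sizes = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chromosomes)
    }
    frames = []
    for chrom, size in sizes.items():
        # geometric inter-CpG gaps with the configured mean spacing
        n_draw = int(2.5 * size / config.cpg_spacing_mean_bp) + 10
        gaps = rng.geometric(1.0 / config.cpg_spacing_mean_bp, size=n_draw)
        pos = np.cumsum(gaps) - 1
        pos = pos[pos < size - 1]
        frames.append(pd.DataFrame({"chrom": chrom, "pos0": pos.astype(np.int64)}))
    cpg_sites = pd.concat(frames, ignore_index=True)

    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gidx = 0
    margin = 2500
    for (chrom, size), n_here in zip(sizes.items(), per_chrom):
        if n_here == 0:
            continue
        pitch = (size - 2 * margin) / n_here
        if pitch < 100:
            raise ValueError("too many genes for the chromosome length")
        for k in range(n_here):
            anchor = int(margin + k * pitch)
            length = int(rng.integers(400, min(801, max(401, int(pitch)))))
            strand = "+" if rng.random() < 0.5 else "-"
            start0, end0 = anchor, min(anchor + length, size - margin)
            exon1 = (start0, start0 + max(100, length // 3))
            exon2 = (min(end0 - 100, exon1[1] + 50), end0)
            exons = [exon1, exon2] if exon2[0] > exon1[1] else [(start0, end0)]
            genes.append(
                GeneModel(
                    gene_id=f"g{gidx + 1:05d}",
                    chrom=chrom,
                    strand=strand,
                    start0=start0,
                    end0=end0,
                    exons=exons,
                )
            )
            gidx += 1
    tiles = make_tiles(sizes, config.tile_size)
    return SimulatedGenome(chrom_sizes=sizes, cpg_sites=cpg_sites, genes=genes, tiles=tiles)


def _promoter_tile_rows(gene: GeneModel, genome: SimulatedGenome, config: SimulationConfig) -> list[int]:
    from .annotation import promoter_region

    s, e = promoter_region(gene, chrom_size=genome.chrom_sizes[gene.chrom])
    layout_offset = 0
    for chrom, size in genome.chrom_sizes.items():
        n = -(-size // config.tile_size)
        if chrom == gene.chrom:
            first = s // config.tile_size
            last = (e - 1) // config.tile_size
            return [layout_offset + t for t in range(first, last + 1)]
        layout_offset += n
    raise ValueError(f"gene {gene.gene_id} on unknown chromosome")


def _plan_planted(
    genome: SimulatedGenome, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose coupled genes and planted tile regions; returns (gene table, planted table)."""
    n_regions = 6 * config.n_planted_dmrs_per_pattern
    if config.n_coupled_genes > n_regions:
        raise ValueError(
            "n_coupled_genes exceeds the number of planted regions "
            "(6 * n_planted_dmrs_per_pattern); coupled genes need a planted promoter"
        )
    pattern_cycle = [PATTERNS[i % 6] for i in range(n_regions)]

    # coupled genes: evenly spaced so promoter tile sets never collide
    stride = max(1, config.n_genes // max(1, config.n_coupled_genes))
    coupled_idx = [i * stride for i in range(config.n_coupled_genes)]

    gene_rows = []
    planted_rows = []
    used_tiles: set[int] = set()
    region_id = 0
    for j, gi in enumerate(coupled_idx):
        gene = genome.genes[gi]
        pattern = pattern_cycle[region_id]
        tile_rows = _promoter_tile_rows(gene, genome, config)
        tile_rows = [t for t in tile_rows if t not in used_tiles]
        used_tiles.update(tile_rows)
        for t in tile_rows:
            planted_rows.append((t, pattern, config.dmr_delta, region_id))
        gene_rows.append((gene.gene_id, True, pattern))
        region_id += 1

    # leftover regions (if any) go to tiles clear of every promoter
    n_left = n_regions - region_id
    if n_left > 0:
        promoter_tiles: set[int] = set()
        for gene in genome.genes:
            promoter_tiles.update(_promoter_tile_rows(gene, genome, config))
        free = [
            t for t in range(len(genome.tiles))
            if t not in promoter_tiles and t not in used_tiles
        ]
        rng.shuffle(free)
        run = 4  # region width in tiles, matching a promoter's footprint
        k = 0
        for _ in range(n_left):
            block = free[k : k + run]
            k += run
            pattern = pattern_cycle[region_id]
            for t in block:
                planted_rows.append((t, pattern, config.dmr_delta, region_id))
            used_tiles.update(block)
            region_id += 1

    coupled_set = {r[0] for r in gene_rows}
    for gene in genome.genes:
        if gene.gene_id not in coupled_set:
            gene_rows.append((gene.gene_id, False, ""))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "coupled", "pattern"])
    genes = genes.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    planted = pd.DataFrame(
        planted_rows, columns=["tile_row", "pattern", "delta", "region_id"]
    ).sort_values("tile_row", kind="mergesort").reset_index(drop=True)
    planted["tile_id"] = genome.tiles["tile_id"].to_numpy()[planted["tile_row"]]
    return genes, planted


def _pattern_levels(pattern: str, config: SimulationConfig) -> np.ndarray:
    """True sibling (EC, HEC, HSPC) levels of a planted pattern."""
    high = min(0.95, config.baseline_meth_mean + 0.05)
    # the gradual pattern spans 1.5x delta so each of its two stage steps
    # (0.75 delta) stays clearly above the DMR difference threshold while
    # its lowest level stays high enough to keep coupled-gene repression
    # clearly past the DEG fold-change threshold
    span = 1.5 * config.dmr_delta if pattern == "C1" else config.dmr_delta
    shape = np.array(PATTERN_SHAPES[pattern])
    return np.clip(high - span * (1.0 - shape), 0.01, 0.99)


def simulate_methylomes(
    genome: SimulatedGenome, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[MethylomeSample], pd.DataFrame, GroundTruth, np.ndarray]:
    """Draw per-CpG counts for every sample; returns samples, meta, truth, latents."""
    n_tiles = len(genome.tiles)
    genes, planted = _plan_planted(genome, config, rng)

    tile_base = rng.beta(
        config.baseline_meth_mean * config.baseline_meth_concentration,
        (1 - config.baseline_meth_mean) * config.baseline_meth_concentration,
        size=n_tiles,
    )

    # true latent level per tile per (genotype, cell type)
    true_levels = pd.DataFrame(
        {f"sibling:{ct}": tile_base.copy() for ct in CELL_TYPES}
        | {
            f"mutant:{ct}": np.clip(tile_base - config.mutant_hypomethylation_shift, 0, 1)
            for ct in CELL_TYPES
        }
    )
    for pattern, sub in planted.groupby("pattern"):
        levels = _pattern_levels(pattern, config)
        rows = sub["tile_row"].to_numpy()
        for ct, lv in zip(CELL_TYPES, levels):
            true_levels.loc[rows, f"sibling:{ct}"] = lv
        # mutant: dynamics abolished; planted regions sit at a low flat level
        mutant_lv = max(0.0, float(levels.min()) - config.mutant_hypomethylation_shift)
        for ct in CELL_TYPES:
            true_levels.loc[rows, f"mutant:{ct}"] = mutant_lv

    site_tile = site_tile_index(genome.cpg_sites, genome.tiles, config.tile_size)
    n_sites = len(genome.cpg_sites)

    samples: list[MethylomeSample] = []
    meta_rows = []
    latents = np.empty((n_tiles, 0))
    latent_cols = []
    for genotype in GENOTYPES:
        for ct in CELL_TYPES:
            group_level = true_levels[f"{genotype}:{ct}"].to_numpy()
            for rep in range(1, config.replicates_per_group + 1):
                sid = f"{genotype}_{ct}_r{rep}"
                rep_level = np.clip(
                    group_level + rng.normal(0, config.replicate_noise_sd, n_tiles),
                    0.0,
                    1.0,
                )
                pi_mean = np.clip(rep_level[site_tile], 1e-6, 1 - 1e-6)
                c = config.cpg_jitter_concentration
                pi = rng.beta(pi_mean * c, (1 - pi_mean) * c)
                total = rng.poisson(config.coverage_mean, n_sites)
                meth = rng.binomial(total, pi)
                records = pd.DataFrame(
                    {
                        "chrom": genome.cpg_sites["chrom"].to_numpy(),
                        "pos0": genome.cpg_sites["pos0"].to_numpy(),
                        "meth": meth,
                        "total": total,
                    }
                )
                samples.append(
                    MethylomeSample(
                        sample_id=sid,
                        cell_type=ct,
                        genotype=genotype,
                        replicate=rep,
                        records=records,
                    )
                )
                meta_rows.append((sid, ct, genotype, rep))
                latents = np.column_stack([latents, rep_level]) if latents.size else rep_level[:, None]
                latent_cols.append(sid)

    meta = pd.DataFrame(meta_rows, columns=["sample_id", "cell_type", "genotype", "replicate"])
    truth = GroundTruth(
        planted_tiles=planted.loc[:, ["tile_row", "tile_id", "pattern", "delta", "region_id"]],
        true_tile_levels=true_levels,
        genes=genes,
        true_global={g: float(true_levels[g].mean()) for g in GROUPS},
    )
    return samples, meta, truth, latents


def simulate_expression(
    genome: SimulatedGenome,
    truth: GroundTruth,
    meta: pd.DataFrame,
    replicate_latent: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial gene counts coupled to latent promoter methylation.

    Coupled genes in sibling samples follow log2 mean = baseline +
    coupling_slope * latent promoter methylation; coupled genes in mutants
    and all uncoupled genes sit at the baseline.
    """
    genes_by_id = {g.gene_id: g for g in genome.genes}
    gene_table = truth.genes.copy()
    baselines = rng.uniform(
        config.expression_baseline_log2_low,
        config.expression_baseline_log2_high,
        size=len(gene_table),
    )
    gene_table["baseline_log2"] = baselines
    gene_table["slope"] = np.where(gene_table["coupled"], config.coupling_slope, 0.0)

    # latent promoter methylation per gene per sample (mean over promoter tiles)
    sample_ids = list(meta["sample_id"])
    sib_mask = (meta["genotype"] == "sibling").to_numpy()
    prom_latent = np.zeros((len(gene_table), len(sample_ids)))
    for i, gid in enumerate(gene_table["gene_id"]):
        rows = _promoter_tile_rows(genes_by_id[gid], genome, config)
        prom_latent[i] = replicate_latent[rows].mean(axis=0)

    slope = gene_table["slope"].to_numpy()[:, None]
    base = gene_table["baseline_log2"].to_numpy()[:, None]
    log2_mu = base + slope * prom_latent * sib_mask[None, :]
    mu = np.exp2(log2_mu)
    if config.nb_dispersion > 1e-8:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    truth.genes = gene_table
    return pd.DataFrame(counts, index=gene_table["gene_id"], columns=sample_ids)


def simulate_dataset(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> SimulatedDataset:
    """Run the full generator; optionally write all artefacts to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    samples, meta, truth, latents = simulate_methylomes(genome, config, rng)
    counts = simulate_expression(genome, truth, meta, latents, config, rng)
    ds = SimulatedDataset(
        config=config,
        genome=genome,
        samples=samples,
        sample_meta=meta,
        counts=counts,
        truth=truth,
        replicate_latent=latents,
    )
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str | os.PathLike) -> None:
    """Write cytosine reports, chrom.sizes, GTF, counts, sample sheet, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(ds.genome.chrom_sizes, outdir / "genome.chrom.sizes")
    write_gtf(ds.genome.genes, outdir / "genes.gtf")
    sheet_rows = []
    for s in ds.samples:
        fname = f"{s.sample_id}.CpG_report.txt"
        write_cytosine_report(s.records, outdir / fname)
        sheet_rows.append((s.sample_id, s.cell_type, s.genotype, s.replicate, fname))
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "cell_type", "genotype", "replicate", "file"]
    )
    write_sample_sheet(sheet, outdir / "samples.tsv")
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t")
    # ground truth sidecars; the data files themselves carry no truth
    ds.truth.planted_tiles.to_csv(outdir / "truth_tiles.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False,
                          float_format="%.6g")
    levels = ds.truth.true_tile_levels.copy()
    levels.insert(0, "tile_id", ds.genome.tiles["tile_id"].to_numpy())
    levels.to_csv(outdir / "truth_tile_levels.tsv", sep="\t", index=False,
                  float_format="%.6g")
    pd.Series(ds.truth.true_global).rename_axis("group").rename("level").to_csv(
        outdir / "truth_global.tsv", sep="\t"
    )
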