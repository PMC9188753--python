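"""Differential expression and promoter-methylation / expression integration.

The DE stage is a deliberately transparent engine — median-of-ratios size
factors, a two-sample t-test on log2(normalised + 1), BH correction — with
the study's selection thresholds (adjusted p below ``deg_alpha`` and
|log2FC| >= 1).  It does not reimplement DESeq2's negative-binomial
shrinkage.

Integration computes, per differentially expressed gene and per genotype,
the Pearson correlation between promoter methylation and log2 expression
across that genotype's samples (3 cell types x replicates).  A gene is
flagged methylation-regulated when the sibling correlation is below -0.3
while the mutant samples show no such correlation.  A correlation is only
considered meaningful when the promoter's methylation spans more than
``min_meth_range`` (default 0.2, the DMR difference threshold) across the
genotype's samples; below that the promoter is effectively static and the
correlation coefficient reflects noise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, promoter_region
from .dmr import bh_adjust
from .tiling import MethylomeCohort

logger = logging.getLogger(__name__)

CORR_THRESHOLD = -0.3
MIN_METH_RANGE = 0.2


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalisation (genes x samples).

    Size factors are the per-sample median of count ratios to the per-gene
    geometric mean, computed over genes expressed in every sample.
    """
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 genes for median-of-ratios normalisation")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    if (mat.sum(axis=0) == 0).any():
        bad = counts.columns[mat.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in every sample; cannot form size factors")
    log_ref = np.log(mat[expressed]).mean(axis=1, keepdims=True)
    ratios = np.log(mat[expressed]) - log_ref
    factors = np.exp(np.median(ratios, axis=0))
    return counts / factors


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the divisors used by normalize_counts)."""
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 genes for median-of-ratios normalisation")
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in every sample; cannot form size factors")
    log_ref = np.log(mat[expressed]).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(mat[expressed]) - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns)


def call_degs(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    deg_alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential expression between two sample groups.

    log2 fold change uses pseudocount-1 group means of normalised counts
    (b over a); p values come from a two-sample t-test on log2(norm + 1)
    and are BH-adjusted over all genes.  ``passes`` requires adjusted
    p < ``deg_alpha`` and |log2FC| >= ``lfc_threshold``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = normalized.loc[:, group_a].to_numpy(dtype=float)
    b = normalized.loc[:, group_b].to_numpy(dtype=float)
    log_a = np.log2(a + 1)
    log_b = np.log2(b + 1)
    log2fc = np.log2(b.mean(axis=1) + 1) - np.log2(a.mean(axis=1) + 1)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger scipy precision warnings; the
        # zero-variance fix-up below handles those rows explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    same = degenerate & np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
    p[same] = 1.0
    p[degenerate & ~same] = 0.0
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene_id": normalized.index,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "log2fc": log2fc,
            "p_raw": p,
            "p_adj": p_adj,
        }
    )
    out["passes"] = (out["p_adj"] < deg_alpha) & (out["log2fc"].abs() >= lfc_threshold)
    return out


def promoter_methylation_matrix(
    cohort: MethylomeCohort,
    genes: list[GeneModel],
    up: int = 1000,
    down: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled promoter methylation level per gene (rows) and sample (cols).

    NaN where a promoter contains no covered CpG in that sample.
    """
    sites = cohort.sites
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos0"].to_numpy()
    n_samples = cohort.meth.shape[1]
    out = np.full((len(genes), n_samples), np.nan)
    blocks: dict[str, tuple[int, int]] = {}
    start = 0
    for chrom, size in zip(*np.unique(chroms, return_counts=True)):
        # np.unique sorts; sites are sorted by (chrom, pos0) so blocks align
        blocks[chrom] = (start, start + size)
        start += size
    for chrom, (lo, hi) in blocks.items():
        block_pos = pos[lo:hi]
        cmeth = np.vstack([np.zeros((1, n_samples)), np.cumsum(cohort.meth[lo:hi], axis=0)])
        ctot = np.vstack([np.zeros((1, n_samples)), np.cumsum(cohort.total[lo:hi], axis=0)])
        for i, g in enumerate(genes):
            if g.chrom != chrom:
                continue
            size = chrom_sizes.get(chrom) if chrom_sizes else None
            s, e = promoter_region(g, up, down, chrom_size=size)
            a = np.searchsorted(block_pos, s, side="left")
            b = np.searchsorted(block_pos, e, side="left")
            meth = cmeth[b] - cmeth[a]
            total = ctot[b] - ctot[a]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[i] = np.where(total > 0, meth / total, np.nan)
    return pd.DataFrame(out, index=[g.gene_id for g in genes], columns=cohort.sample_ids)


def promoter_methylation_per_gene(
    records: pd.DataFrame,
    genes: list[GeneModel],
    up: int = 1000,
    down: int = 1000,
) -> pd.Series:
    """Single-sample pooled promoter level per gene (NaN if no covered CpG)."""
    levels = {}
    by_chrom = {c: sub for c, sub in records.groupby("chrom")}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            levels[g.gene_id] = np.nan
            continue
        s, e = promoter_region(g, up, down)
        inside = sub[(sub["pos0"] >= s) & (sub["pos0"] < e)]
        total = inside["total"].sum()
        levels[g.gene_id] = inside["meth"].sum() / total if total > 0 else np.nan
    return pd.Series(levels, name="promoter_level")


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def integrate(
    degs: pd.DataFrame,
    promoter_levels: pd.DataFrame,
    normalized: pd.DataFrame,
    sample_meta: pd.DataFrame,
    corr_threshold: float = CORR_THRESHOLD,
    min_meth_range: float = MIN_METH_RANGE,
) -> pd.DataFrame:
    """Per-DEG promoter-methylation/expression correlations per genotype.

    ``promoter_levels`` and ``normalized`` are gene-by-sample tables;
    ``sample_meta`` maps sample_id to genotype/cell_type.  Expression enters
    the correlation as log2(normalised + 1).  A gene is ``selected`` when
    the sibling correlation is below ``corr_threshold`` (with a meaningful
    methylation range) and the mutant samples show no such correlation.
    Genes with fewer than 3 usable samples in a genotype are excluded.
    """
    gene_ids = [g for g in degs["gene_id"] if g in promoter_levels.index]
    by_geno = {
        geno: list(sample_meta.loc[sample_meta["genotype"] == geno, "sample_id"])
        for geno in ("sibling", "mutant")
    }
    rows = []
    n_excluded = 0
    for gene in gene_ids:
        stats_row: dict = {"gene_id": gene}
        usable = True
        for geno, ids in by_geno.items():
            ids = [s for s in ids if s in promoter_levels.columns and s in normalized.columns]
            meth = promoter_levels.loc[gene, ids].to_numpy(dtype=float)
            expr = np.log2(normalized.loc[gene, ids].to_numpy(dtype=float) + 1)
            ok = np.isfinite(meth) & np.isfinite(expr)
            if ok.sum() < 3:
                usable = False
                break
            meth, expr = meth[ok], expr[ok]
            rng = float(meth.max() - meth.min())
            r = pearson_correlation(meth, expr) if (meth.std() > 0 and expr.std() > 0) else float("nan")
            stats_row[f"corr_{geno}"] = r
            stats_row[f"meth_range_{geno}"] = rng
        if not usable:
            n_excluded += 1
            continue
        neg_sib = (
            stats_row["meth_range_sibling"] > min_meth_range
            and np.isfinite(stats_row["corr_sibling"])
            and stats_row["corr_sibling"] < corr_threshold
        )
        neg_mut = (
            stats_row["meth_range_mutant"] > min_meth_range
            and np.isfinite(stats_row["corr_mutant"])
            and stats_row["corr_mutant"] < corr_threshold
        )
        stats_row["selected"] = bool(neg_sib and not neg_mut)
        rows.append(stats_row)
    if n_excluded:
        logger.info("integration excluded %d genes with <3 usable samples", n_excluded)
    cols = ["gene_id", "corr_sibling", "corr_mutant",
            "meth_range_sibling", "meth_range_mutant", "selected"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).loc[:, cols]


def stage_transition_filter(
    gene_ids: list[str],
    promoter_levels: pd.DataFrame,
    normalized: pd.DataFrame,
    sample_meta: pd.DataFrame,
    transitions: tuple[tuple[str, str], ...] = (("EC", "HEC"), ("HEC", "HSPC")),
    min_meth_increase: float = 0.1,
    min_expr_log2_decrease: float = 0.5,
) -> dict[str, list[str]]:
    """Genes silenced alongside promoter methylation gain at each transition.

    A gene passes a transition when, in siblings, mean promoter methylation
    rises by more than ``min_meth_increase`` while mean log2 expression
    falls by more than ``min_expr_log2_decrease`` — and the mutant samples
    do not show the same joint change.  The margins (half the DMR
    difference threshold, half the DEG fold-change threshold) keep
    sign-flips of pure noise from passing.
    """
    log_expr = np.log2(normalized + 1)

    def group_means(table: pd.DataFrame, geno: str, ct: str) -> pd.Series:
        ids = sample_meta.loc[
            (sample_meta["genotype"] == geno) & (sample_meta["cell_type"] == ct),
            "sample_id",
        ]
        ids = [s for s in ids if s in table.columns]
        return table.loc[:, ids].mean(axis=1)

    out: dict[str, list[str]] = {}
    for ct_from, ct_to in transitions:
        name = f"{ct_from}->{ct_to}"
        passed = []
        means = {
            (geno, ct): (
                group_means(promoter_levels, geno, ct),
                group_means(log_expr, geno, ct),
            )
            for geno in ("sibling", "mutant")
            for ct in (ct_from, ct_to)
        }
        for gene in gene_ids:
            if gene not in promoter_levels.index or gene not in normalized.index:
                continue
            vals = {}
            skip = False
            for geno in ("sibling", "mutant"):
                m_from, e_from = means[(geno, ct_from)]
                m_to, e_to = means[(geno, ct_to)]
                dm = m_to.get(gene, np.nan) - m_from.get(gene, np.nan)
                de = e_to.get(gene, np.nan) - e_from.get(gene, np.nan)
                if not (np.isfinite(dm) and np.isfinite(de)):
                    skip = True
                    break
                vals[geno] = (
                    dm > min_meth_increase and de < -min_expr_log2_decrease
                )
            if skip:
                continue
            if vals["sibling"] and not vals["mutant"]:
                passed.append(gene)
        out[name] = passed
    return out
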