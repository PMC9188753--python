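"""Gene models, promoter/gene-body features, DMR annotation and enrichment.

Definitions: the promoter is the strand-aware window from 1 kb upstream to
1 kb downstream of the TSS; the gene body runs from TSS to the
transcription end site.  A DMR is annotated to a single feature by the
fixed precedence promoter > exon > intron > intergenic.  Region-set
enrichment is the one-sided Fisher exact test on the 2x2 overlap table of
a query region set against a feature set, inside a universe of testable
tiles, with BH correction across feature sets.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dmr import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_PRECEDENCE = ("promoter", "exon", "intron")


@dataclass
class GeneModel:
    """A gene-level model built from the outermost transcript span."""

    gene_id: str
    chrom: str
    strand: str
    start0: int  # plus-strand span start (half-open)
    end0: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.end0 <= self.start0:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons:
            if s < self.start0 or e > self.end0:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss0(self) -> int:
        """0-based first transcribed base (strand-aware)."""
        return self.start0 if self.strand == "+" else self.end0 - 1

    @property
    def tes0(self) -> int:
        return self.end0 - 1 if self.strand == "+" else self.start0


def promoter_region(
    gene: GeneModel,
    up: int = 1000,
    down: int = 1000,
    chrom_size: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter window (TSS - up, TSS + down), clipped to bounds."""
    if gene.strand == "+":
        start, end = gene.tss0 - up, gene.tss0 + down
    else:
        start, end = gene.tss0 - down, gene.tss0 + up
    if start < 0:
        logger.debug("promoter of %s clipped at chromosome start", gene.gene_id)
        start = 0
    if chrom_size is not None and end > chrom_size:
        logger.debug("promoter of %s clipped at chromosome end", gene.gene_id)
        end = chrom_size
    return start, end


def genes_table(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start0": [g.start0 for g in genes],
            "end0": [g.end0 for g in genes],
            "tss0": [g.tss0 for g in genes],
        }
    )


def read_gtf(path: str | os.PathLike, gene_key: str = "gene_id") -> list[GeneModel]:
    """Read gene models from GTF/GFF3 (gene/transcript/exon features).

    Gene spans are the outermost transcript span; exons are unioned across
    transcripts.  ``gene_key`` names the attribute carrying the gene id
    (``gene_id`` for GTF, typically ``ID`` for GFF3 gene rows).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get(gene_key, [g.id])[0]
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=g.seqid,
                strand=g.strand,
                start0=g.start - 1,
                end0=g.end,
                exons=merge_intervals(exons),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start0, g.gene_id))
    return genes


def write_gtf(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GTF with gene/transcript/exon rows."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for ftype, (s, e) in [("gene", (g.start0, g.end0)),
                                  ("transcript", (g.start0, g.end0))]:
                fh.write(
                    f"{g.chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_feature_sets(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    up: int = 1000,
    down: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Promoter / exon / intron / gene_body feature sets from gene models.

    Each set is a DataFrame (chrom, start0, end0) with per-chromosome
    overlaps merged.  Intergenic is implicit: a region overlapping no set.
    """
    if not genes:
        raise ValueError("empty gene set")
    per: dict[str, dict[str, list[tuple[int, int]]]] = {
        "promoter": {}, "exon": {}, "intron": {}, "gene_body": {}
    }
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        per["promoter"].setdefault(g.chrom, []).append(
            promoter_region(g, up, down, chrom_size=size)
        )
        per["gene_body"].setdefault(g.chrom, []).append((g.start0, g.end0))
        exons = merge_intervals(g.exons) or [(g.start0, g.end0)]
        per["exon"].setdefault(g.chrom, []).extend(exons)
        prev = g.start0
        for s, e in exons:
            if s > prev:
                per["intron"].setdefault(g.chrom, []).append((prev, s))
            prev = max(prev, e)
        if g.end0 > prev:
            per["intron"].setdefault(g.chrom, []).append((prev, g.end0))
    out = {}
    for name, by_chrom in per.items():
        rows = []
        for chrom in sorted(by_chrom):
            for s, e in merge_intervals(by_chrom[chrom]):
                rows.append((chrom, s, e))
        out[name] = pd.DataFrame(rows, columns=["chrom", "start0", "end0"])
    return out


def _feature_trees(features: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in features.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start0"], sub["end0"])
        )
    return trees


def overlaps_feature(regions: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean: does each region overlap >= 1 bp of the feature set."""
    trees = _feature_trees(features)
    hits = np.zeros(len(regions), dtype=bool)
    for i, (chrom, s, e) in enumerate(
        zip(regions["chrom"], regions["start0"], regions["end0"])
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(s, e):
            hits[i] = True
    return hits


def annotate_dmrs(
    calls: pd.DataFrame,
    feature_sets: dict[str, pd.DataFrame],
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Single feature label per DMR by precedence, plus the label distribution.

    Returns the calls table with a ``feature`` column; regions overlapping
    none of the precedence features are labelled ``intergenic``.
    """
    if not feature_sets:
        raise ValueError("empty feature universe")
    labels = np.array(["intergenic"] * len(calls), dtype=object)
    unassigned = np.ones(len(calls), dtype=bool)
    for name in precedence:
        if name not in feature_sets:
            continue
        hit = overlaps_feature(calls, feature_sets[name]) & unassigned
        labels[hit] = name
        unassigned &= ~hit
    out = calls.copy()
    out["feature"] = labels
    return out


def feature_distribution(annotated: pd.DataFrame) -> pd.Series:
    """Percentage of DMRs per feature label (sums to 100)."""
    counts = annotated["feature"].value_counts()
    return 100.0 * counts / counts.sum()


def region_set_enrichment(
    query: pd.DataFrame,
    feature_sets: dict[str, pd.DataFrame],
    universe: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a query region set within a universe.

    ``query`` and ``universe`` are region tables carrying tile_id; query
    must be a subset of the universe.  For each feature set the 2x2 table
    (query vs rest) x (overlaps vs not) is tested one-sided for enrichment;
    q values are BH-adjusted across feature sets.
    """
    if len(universe) < len(query):
        raise ValueError("universe smaller than query")
    if not set(query["tile_id"]) <= set(universe["tile_id"]):
        raise ValueError("query regions must belong to the universe")
    in_query = universe["tile_id"].isin(set(query["tile_id"])).to_numpy()
    rows = []
    for name, feat in feature_sets.items():
        hit = overlaps_feature(universe, feat)
        a = int((in_query & hit).sum())
        b = int((in_query & ~hit).sum())
        c = int((~in_query & hit).sum())
        d = int((~in_query & ~hit).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["feature", "query_hit", "query_miss", "bg_hit", "bg_miss",
                 "odds_ratio", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
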