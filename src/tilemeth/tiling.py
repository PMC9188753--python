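"""Consecutive fixed-width tiling of the genome and tile methylation levels.

The analysis unit is the 500 bp tile: each chromosome is partitioned into
consecutive, non-overlapping 500 bp windows (the final window may be
shorter), a tile's methylation level in a sample is the pooled count ratio
sum(meth) / sum(total) over the CpGs falling in the tile, and a sample's
genome-wide level is the unweighted mean of its non-missing tile levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethylomeSample

DEFAULT_TILE_SIZE = 500


def make_tiles(chrom_sizes: dict[str, int], tile_size: int = DEFAULT_TILE_SIZE) -> pd.DataFrame:
    """Partition chromosomes into consecutive tiles of ``tile_size`` bp.

    Returns a DataFrame with columns tile_id, chrom, start0, end0; the last
    tile of each chromosome is truncated at the chromosome end.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        starts = np.arange(0, size, tile_size, dtype=np.int64)
        ends = np.minimum(starts + tile_size, size)
        for s, e in zip(starts, ends):
            rows.append((f"{chrom}:{s}-{e}", chrom, s, e))
    tiles = pd.DataFrame(rows, columns=["tile_id", "chrom", "start0", "end0"])
    return tiles


def _chrom_layout(tiles: pd.DataFrame, tile_size: int) -> dict[str, tuple[int, int]]:
    """Map chrom -> (first tile row, number of tiles); requires make_tiles layout."""
    layout: dict[str, tuple[int, int]] = {}
    for chrom, sub in tiles.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        if not np.array_equal(rows, np.arange(rows[0], rows[0] + len(rows))):
            raise ValueError("tiles table must keep each chromosome contiguous")
        layout[chrom] = (int(rows[0]), len(rows))
    return layout


def site_tile_index(
    sites: pd.DataFrame, tiles: pd.DataFrame, tile_size: int = DEFAULT_TILE_SIZE
) -> np.ndarray:
    """Global tile row index for every site (columns chrom, pos0)."""
    layout = _chrom_layout(tiles, tile_size)
    idx = np.empty(len(sites), dtype=np.int64)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos0"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in layout:
            raise ValueError(f"CpG on chromosome {chrom!r} absent from the tile set")
        offset, n = layout[chrom]
        mask = chroms == chrom
        local = pos[mask] // tile_size
        if (local >= n).any():
            raise ValueError(f"CpG beyond the end of chromosome {chrom!r}")
        idx[mask] = offset + local
    return idx


@dataclass
class MethylomeCohort:
    """Per-CpG counts of many samples aligned on a common site set.

    ``meth`` and ``total`` are (n_sites, n_samples) integer arrays; a sample
    missing a site carries total 0 there.
    """

    sites: pd.DataFrame
    meth: np.ndarray = field(repr=False)
    total: np.ndarray = field(repr=False)
    meta: pd.DataFrame

    @classmethod
    def from_samples(cls, samples: list[MethylomeSample]) -> "MethylomeCohort":
        if not samples:
            raise ValueError("no samples")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        keyed = [s.records.set_index(["chrom", "pos0"]) for s in samples]
        index = keyed[0].index
        for k in keyed[1:]:
            index = index.union(k.index)
        index = index.sortlevel([0, 1])[0]
        n = len(index)
        meth = np.zeros((n, len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, k in enumerate(keyed):
            sub = k.reindex(index, fill_value=0)
            meth[:, j] = sub["meth"].to_numpy()
            total[:, j] = sub["total"].to_numpy()
        sites = index.to_frame(index=False)
        meta = pd.DataFrame(
            {
                "sample_id": ids,
                "cell_type": [s.cell_type for s in samples],
                "genotype": [s.genotype for s in samples],
                "replicate": [s.replicate for s in samples],
            }
        )
        return cls(sites=sites, meth=meth, total=total, meta=meta)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in cohort: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.int64)

    def select(self, mask: pd.Series | np.ndarray) -> list[str]:
        """Sample ids matching a boolean mask over ``meta`` rows."""
        return list(self.meta.loc[np.asarray(mask, dtype=bool), "sample_id"])


@dataclass
class TileMatrix:
    """Tile-by-sample pooled methylation counts plus CpG bookkeeping."""

    tiles: pd.DataFrame
    cohort: MethylomeCohort = field(repr=False)
    tile_size: int
    pooled_meth: np.ndarray = field(repr=False)
    pooled_total: np.ndarray = field(repr=False)
    n_cpg_covered: np.ndarray = field(repr=False)
    site_tile: np.ndarray = field(repr=False)

    @classmethod
    def from_cohort(
        cls,
        cohort: MethylomeCohort,
        tiles: pd.DataFrame,
        tile_size: int = DEFAULT_TILE_SIZE,
    ) -> "TileMatrix":
        idx = site_tile_index(cohort.sites, tiles, tile_size)
        n_tiles = len(tiles)
        n_samples = cohort.meth.shape[1]
        pooled_meth = np.zeros((n_tiles, n_samples), dtype=np.int64)
        pooled_total = np.zeros_like(pooled_meth)
        n_cov = np.zeros_like(pooled_meth)
        for j in range(n_samples):
            pooled_meth[:, j] = np.bincount(idx, weights=cohort.meth[:, j], minlength=n_tiles)
            pooled_total[:, j] = np.bincount(idx, weights=cohort.total[:, j], minlength=n_tiles)
            n_cov[:, j] = np.bincount(idx, weights=cohort.total[:, j] > 0, minlength=n_tiles)
        return cls(
            tiles=tiles,
            cohort=cohort,
            tile_size=tile_size,
            pooled_meth=pooled_meth,
            pooled_total=pooled_total,
            n_cpg_covered=n_cov,
            site_tile=idx,
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.cohort.sample_ids

    def levels(self) -> pd.DataFrame:
        """Tile-by-sample levels; NaN where a tile has no covered CpG."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(self.pooled_total > 0, self.pooled_meth / self.pooled_total, np.nan)
        return pd.DataFrame(lv, index=self.tiles["tile_id"], columns=self.sample_ids)

    def to_wide_tsv(self, path) -> None:
        out = self.levels().copy()
        out.insert(0, "chrom", self.tiles["chrom"].to_numpy())
        out.insert(1, "start0", self.tiles["start0"].to_numpy())
        out.insert(2, "end0", self.tiles["end0"].to_numpy())
        out.to_csv(path, sep="\t", float_format="%.6g")

    def sample_bedgraph(self, sample_id: str) -> pd.DataFrame:
        j = self.cohort.columns([sample_id])[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(
                self.pooled_total[:, j] > 0,
                self.pooled_meth[:, j] / self.pooled_total[:, j],
                np.nan,
            )
        return pd.DataFrame(
            {
                "chrom": self.tiles["chrom"],
                "start0": self.tiles["start0"],
                "end0": self.tiles["end0"],
                "value": value,
            }
        )


def tile_methylation(
    sample: MethylomeSample, tiles: pd.DataFrame, tile_size: int = DEFAULT_TILE_SIZE
) -> pd.DataFrame:
    """Pooled tile methylation of one sample.

    Returns a DataFrame aligned with ``tiles``: pooled_meth, pooled_total,
    n_cpg_covered and level (NaN where the tile has no covered CpG).
    """
    rec = sample.records
    n_tiles = len(tiles)
    if len(rec) == 0:
        z = np.zeros(n_tiles, dtype=np.int64)
        return pd.DataFrame(
            {
                "tile_id": tiles["tile_id"],
                "pooled_meth": z,
                "pooled_total": z,
                "n_cpg_covered": z,
                "level": np.full(n_tiles, np.nan),
            }
        )
    idx = site_tile_index(rec[["chrom", "pos0"]], tiles, tile_size)
    meth = np.bincount(idx, weights=rec["meth"], minlength=n_tiles).astype(np.int64)
    total = np.bincount(idx, weights=rec["total"], minlength=n_tiles).astype(np.int64)
    ncov = np.bincount(idx, weights=rec["total"] > 0, minlength=n_tiles).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, meth / total, np.nan)
    return pd.DataFrame(
        {
            "tile_id": tiles["tile_id"],
            "pooled_meth": meth,
            "pooled_total": total,
            "n_cpg_covered": ncov,
            "level": level,
        }
    )


def global_methylation(levels: pd.Series | np.ndarray) -> float:
    """Genome-wide level: unweighted mean over non-missing tile levels."""
    arr = np.asarray(levels, dtype=float)
    ok = ~np.isnan(arr)
    if not ok.any():
        raise ValueError("no tile has a methylation level")
    return float(arr[ok].mean())


def cpg_category_fractions(records: pd.DataFrame) -> dict[str, float]:
    """Fractions of covered CpGs with high, intermediate, low and no methylation.

    Boundaries: high > 0.8; intermediate in [0.2, 0.8]; low in (0, 0.2);
    none exactly 0.  The value 0.8 itself falls in "intermediate" (the open
    interval convention leaves it unclaimed; the intermediate bin is closed
    at the top here).
    """
    covered = records[records["total"] > 0]
    if len(covered) == 0:
        raise ValueError("no covered CpG")
    level = covered["meth"].to_numpy() / covered["total"].to_numpy()
    n = len(level)
    frac = {
        "high": float((level > 0.8).sum() / n),
        "low": float(((level > 0) & (level < 0.2)).sum() / n),
        "none": float((level == 0).sum() / n),
    }
    frac["intermediate"] = float(((level >= 0.2) & (level <= 0.8)).sum() / n)
    return {k: frac[k] for k in ("high", "intermediate", "low", "none")}
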