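"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats:

* bismark-style CpG cytosine report: TSV with columns chrom, 1-based
  position, strand, methylated count, unmethylated count, context,
  trinucleotide.  Only rows matching the context filter (default "CG") are
  kept; plus- and minus-strand calls of one dyad are merged onto the
  plus-strand C.
* chrom.sizes: two-column TSV (chrom, length).
* BED3/BED6: 0-based half-open.
* sample sheet: TSV with columns sample_id, cell_type, genotype, replicate,
  file; ``file`` paths are resolved relative to the sheet's directory.
* clone matrix: TSV, rows = clones, columns = CpG positions, values 1/0/NA
  (see :mod:`tilemeth.clones`).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CELL_TYPES, CPG_COLUMNS, GENOTYPES, MethylomeSample, merge_dyads

logger = logging.getLogger(__name__)

_REPORT_COLS = ["chrom", "pos1", "strand", "meth", "unmeth", "context", "tri"]


def read_cytosine_report(path: str | os.PathLike, context: str = "CG") -> pd.DataFrame:
    """Read a bismark-style CpG cytosine report into a records table.

    Returns a DataFrame with columns chrom, pos0, meth, total.  1-based
    input positions become 0-based; minus-strand calls are mapped onto the
    plus-strand C of the dyad (pos0 = pos1 - 2) and merged by summing.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_REPORT_COLS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "tri": str,
            },
        )
    except pd.errors.EmptyDataError:
        logger.warning("cytosine report %s is empty", path)
        return pd.DataFrame(columns=list(CPG_COLUMNS))
    for col in ("pos1", "meth", "unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed {col!r} field at line {line}")
        raw[col] = vals.astype(np.int64)
    bad_strand = ~raw["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed strand at line {line}")
    if (raw["meth"] < 0).any() or (raw["unmeth"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    raw = raw[raw["context"] == context]
    if len(raw) == 0:
        logger.warning("cytosine report %s has no %s rows", path, context)
        return pd.DataFrame(columns=list(CPG_COLUMNS))
    pos0 = raw["pos1"].to_numpy() - 1
    minus = (raw["strand"] == "-").to_numpy()
    pos0 = pos0 - minus.astype(np.int64)  # minus-strand C sits one base 3' of the plus C
    rec = pd.DataFrame(
        {
            "chrom": raw["chrom"].to_numpy(),
            "pos0": pos0,
            "meth": raw["meth"].to_numpy(),
            "total": (raw["meth"] + raw["unmeth"]).to_numpy(),
        }
    )
    if (rec["pos0"] < 0).any():
        raise ValueError(f"{path}: minus-strand call at position 1 has no plus-strand C")
    return merge_dyads(rec)


def write_cytosine_report(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a records table as a plus-strand-only CpG cytosine report."""
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "pos1": records["pos0"] + 1,
            "strand": "+",
            "meth": records["meth"],
            "unmeth": records["total"] - records["meth"],
            "context": "CG",
            "tri": "CGN",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                        dtype={"chrom": str})
    if (sizes["size"] <= 0).any():
        raise ValueError(f"{path}: non-positive chromosome size")
    return dict(zip(sizes["chrom"], sizes["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3+ (0-based half-open) into columns chrom, start0, end0[, name...]."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if bed.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start0", "end0", "name", "score", "strand"]
    bed.columns = names[: bed.shape[1]] + [f"extra{i}" for i in range(bed.shape[1] - 6)]
    if (bed["end0"] <= bed["start0"]).any():
        raise ValueError(f"{path}: BED interval with end <= start")
    return bed


def write_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame with leading chrom/start0/end0 columns as BED."""
    cols = ["chrom", "start0", "end0"]
    extra = [c for c in regions.columns if c not in cols]
    regions.loc[:, cols + extra].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(levels: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write chrom/start0/end0/value rows as bedGraph (missing values dropped)."""
    out = levels.dropna(subset=["value"])
    out.loc[:, ["chrom", "start0", "end0", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


_SHEET_COLS = ["sample_id", "cell_type", "genotype", "replicate", "file"]


def read_sample_sheet(path: str | os.PathLike, check_files: bool = True) -> pd.DataFrame:
    """Read and validate the sample sheet.

    Fails fast: unknown cell types/genotypes, duplicate sample ids and
    missing data files are all reported at load time.
    """
    path = Path(path)
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SHEET_COLS) - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    sheet = sheet.loc[:, _SHEET_COLS].copy()
    for i, row in sheet.iterrows():
        if row["cell_type"] not in CELL_TYPES:
            raise ValueError(
                f"{path}: row {i + 1} ({row['sample_id']}): unknown cell_type "
                f"{row['cell_type']!r}"
            )
        if row["genotype"] not in GENOTYPES:
            raise ValueError(
                f"{path}: row {i + 1} ({row['sample_id']}): unknown genotype "
                f"{row['genotype']!r}"
            )
    dup = sheet["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate sample_id {sheet['sample_id'][dup].iloc[0]!r}"
        )
    sheet["replicate"] = sheet["replicate"].astype(int)
    sheet["file"] = [
        str((path.parent / f).resolve()) if not os.path.isabs(f) else f
        for f in sheet["file"]
    ]
    if check_files:
        for f in sheet["file"]:
            if not os.path.exists(f):
                raise FileNotFoundError(f"{path}: listed data file not found: {f}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.loc[:, _SHEET_COLS].to_csv(path, sep="\t", index=False)


def load_samples(sheet: pd.DataFrame) -> list[MethylomeSample]:
    """Load every sample listed in a validated sample sheet."""
    samples = []
    for _, row in sheet.iterrows():
        records = read_cytosine_report(row["file"])
        samples.append(
            MethylomeSample(
                sample_id=row["sample_id"],
                cell_type=row["cell_type"],
                genotype=row["genotype"],
                replicate=int(row["replicate"]),
                records=records,
            )
        )
    return samples
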