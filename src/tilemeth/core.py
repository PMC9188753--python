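"""Core data model for per-CpG bisulfite methylation calls.

Conventions used throughout the package:

* Coordinates are 0-based half-open internally.  1-based coordinates exist
  only at the cytosine-report boundary; BED files on disk are 0-based
  half-open as the format requires.
* A "CpG" is the dyad, keyed by the position of the C on the plus strand.
  Plus- and minus-strand calls of one dyad are merged by summing counts.
* A methylation level is always methylated reads / total reads, pooled over
  whatever unit (CpG, tile, promoter) is being summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("EC", "HEC", "HSPC")
GENOTYPES = ("sibling", "mutant")

#: Column order of the per-CpG records table.
CPG_COLUMNS = ("chrom", "pos0", "meth", "total")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a per-CpG records table.

    Requires columns chrom, pos0, meth, total; enforces 0 <= meth <= total,
    pos0 >= 0 and unique sorted (chrom, pos0).  Returns a sorted copy.
    """
    missing = set(CPG_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    rec = records.loc[:, list(CPG_COLUMNS)].copy()
    if len(rec) == 0:
        return rec.reset_index(drop=True)
    if (rec["pos0"] < 0).any():
        raise ValueError("negative CpG position")
    if (rec["meth"] < 0).any() or (rec["total"] < rec["meth"]).any():
        raise ValueError("require 0 <= meth <= total for every CpG")
    rec = rec.sort_values(["chrom", "pos0"], kind="mergesort").reset_index(drop=True)
    dup = rec.duplicated(["chrom", "pos0"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate CpG record at {rec.at[i, 'chrom']}:{rec.at[i, 'pos0']}"
        )
    return rec


@dataclass
class MethylomeSample:
    """One sample's CpG methylation calls plus design metadata.

    ``records`` is a DataFrame with columns chrom, pos0, meth, total, sorted
    and unique on (chrom, pos0).  Zero-coverage CpGs (total == 0) may be
    present; they contribute nothing to pooled statistics.
    """

    sample_id: str
    cell_type: str
    genotype: str
    replicate: int
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        self.records = validate_records(self.records)

    @property
    def group(self) -> str:
        """Design cell (genotype, cell type), e.g. ``sibling:HEC``."""
        return f"{self.genotype}:{self.cell_type}"


def merge_dyads(records: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of records sharing (chrom, pos0).

    Idempotent and order-independent; used after mapping both strands of a
    CpG dyad onto the plus-strand C position.
    """
    if len(records) == 0:
        return records.loc[:, list(CPG_COLUMNS)].reset_index(drop=True)
    merged = (
        records.groupby(["chrom", "pos0"], sort=True, as_index=False)[["meth", "total"]]
        .sum()
    )
    return merged.loc[:, list(CPG_COLUMNS)]
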