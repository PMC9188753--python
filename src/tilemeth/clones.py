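"""Clonal bisulfite-PCR sequencing summaries.

Input is a pre-called binary matrix (rows = sequenced clones, columns =
CpG positions within the amplicon, entries 1 = methylated, 0 =
unmethylated, NA = no call).  The amplicon summary is the percentage of
methylated CpG sites over all called CpG sites across all clones; the
per-CpG profile supports lollipop-style exports.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def read_clone_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a clones x CpG TSV (values 1/0/NA; first column = clone id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    vals = mat.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0) | (vals == 1)
    if not ok.all():
        raise ValueError(f"{path}: clone matrix entries must be 1, 0 or NA")
    return mat


def clone_methylation_percentage(matrix: pd.DataFrame) -> float:
    """100 x methylated entries / non-missing entries over the whole matrix."""
    vals = matrix.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty clone matrix")
    called = np.isfinite(vals)
    if not called.any():
        raise ValueError("clone matrix has no called entries")
    return float(100.0 * vals[called].sum() / called.sum())


def per_cpg_profile(matrix: pd.DataFrame) -> pd.Series:
    """Methylated fraction per CpG column over clones with a call there."""
    vals = matrix.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty clone matrix")
    called = np.isfinite(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.nansum(vals, axis=0) / called.sum(axis=0)
    return pd.Series(frac, index=matrix.columns, name="meth_fraction")
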