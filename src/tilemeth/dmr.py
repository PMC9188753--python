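"""Pairwise DMR calling and six-pattern clustering across EC/HEC/HSPC.

A tile is a DMR between two groups of replicate samples when the absolute
difference of the group means of its per-replicate levels exceeds 0.2 and
the Benjamini-Hochberg adjusted p of an unpaired two-tailed equal-variance
Student's t-test on the replicate levels is below 0.05.  Before testing,
counts are re-pooled over only the CpG sites covered (total > 0) in every
sample of both groups, so both groups measure the same sites.

DMRs collected over the two adjacent-stage comparisons (EC vs HEC, HEC vs
HSPC) are grouped into six canonical patterns from their (EC, HEC, HSPC)
mean-level profile: gradual gain towards HSPC (C1), HSPC-specific hyper
(C2), HEC-specific hypo (C3), HEC-specific hyper (C4), EC-specific hypo
(C5) and HSPC-specific hypo (C6).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tiling import TileMatrix

logger = logging.getLogger(__name__)

#: Canonical min-max-normalised (EC, HEC, HSPC) profiles of the six patterns.
CANONICAL_PROFILES: dict[str, tuple[float, float, float]] = {
    "C1": (0.0, 0.5, 1.0),  # gradual gain towards HSPC
    "C2": (0.0, 0.0, 1.0),  # HSPC-specific hyper
    "C3": (1.0, 0.0, 1.0),  # HEC-specific hypo
    "C4": (0.0, 1.0, 0.0),  # HEC-specific hyper
    "C5": (0.0, 1.0, 1.0),  # EC-specific hypo
    "C6": (1.0, 1.0, 0.0),  # HSPC-specific hypo
}

PATTERN_NAMES: dict[str, str] = {
    "C1": "gradual-gain",
    "C2": "HSPC-hyper",
    "C3": "HEC-hypo",
    "C4": "HEC-hyper",
    "C5": "EC-hypo",
    "C6": "HSPC-hypo",
}


def student_t_two_sample(a, b) -> tuple[float, float]:
    """Unpaired two-tailed equal-variance Student's t-test.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    with no within-group variance give (inf, 0), logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.info("zero-variance groups with unequal means: p set to 0")
        return float(np.inf) * np.sign(b.mean() - a.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _replicate_levels_shared(
    tm: TileMatrix, cols_a: np.ndarray, cols_b: np.ndarray
):
    """Per-replicate tile levels re-pooled over CpGs covered in all samples.

    Returns (levels_a, levels_b, n_shared_cpg) where levels_* are
    (n_tiles, n_reps) arrays with NaN for tiles without shared coverage.
    """
    cohort = tm.cohort
    cols = np.concatenate([cols_a, cols_b])
    shared = (cohort.total[:, cols] > 0).all(axis=1)
    idx = tm.site_tile
    n_tiles = len(tm.tiles)
    n_shared = np.bincount(idx, weights=shared, minlength=n_tiles).astype(np.int64)

    def pool(columns: np.ndarray) -> np.ndarray:
        lv = np.empty((n_tiles, len(columns)))
        for k, j in enumerate(columns):
            meth = np.bincount(idx, weights=cohort.meth[:, j] * shared, minlength=n_tiles)
            total = np.bincount(idx, weights=cohort.total[:, j] * shared, minlength=n_tiles)
            with np.errstate(invalid="ignore", divide="ignore"):
                lv[:, k] = np.where(total > 0, meth / total, np.nan)
        return lv

    return pool(cols_a), pool(cols_b), n_shared


def call_dmrs(
    tm: TileMatrix,
    group_a: list[str],
    group_b: list[str],
    min_shared_cpg: int = 3,
    diff_threshold: float = 0.2,
    alpha: float = 0.05,
    return_tested: bool = False,
) -> pd.DataFrame:
    """Call DMR tiles between two groups of samples.

    Emitted calls satisfy |mean_b - mean_a| > ``diff_threshold`` and BH
    adjusted p < ``alpha``; ``direction`` is "hyper" when group_b is higher.
    With ``return_tested`` the full table of tested tiles is returned
    instead (column ``called`` flags the DMRs).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    cols_a = tm.cohort.columns(group_a)
    cols_b = tm.cohort.columns(group_b)
    lv_a, lv_b, n_shared = _replicate_levels_shared(tm, cols_a, cols_b)

    ok_a = (~np.isnan(lv_a)).sum(axis=1) >= 2
    ok_b = (~np.isnan(lv_b)).sum(axis=1) >= 2
    testable = (n_shared >= min_shared_cpg) & ok_a & ok_b
    if not testable.any():
        logger.warning("no testable tile in comparison")
    a = lv_a[testable]
    b = lv_b[testable]
    if len(a):
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # near-constant tiles trigger scipy precision warnings; the
            # zero-variance fix-up below handles those rows explicitly
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
    else:
        mean_a = mean_b = t = p = np.array([])
    # zero-variance fix-up: scipy yields NaN when both groups are constant
    degenerate = np.isnan(p)
    if degenerate.any():
        same = degenerate & np.isclose(mean_a, mean_b)
        p[same] = 1.0
        t[same] = 0.0
        diff0 = degenerate & ~np.isclose(mean_a, mean_b)
        if diff0.any():
            logger.info("%d zero-variance tiles with unequal means: p set to 0", diff0.sum())
        p[diff0] = 0.0
        t[diff0] = np.inf

    p_adj = bh_adjust(p) if len(p) else np.array([])
    diff = mean_b - mean_a
    called = (np.abs(diff) > diff_threshold) & (p_adj < alpha)

    out = tm.tiles.loc[testable, ["tile_id", "chrom", "start0", "end0"]].reset_index(drop=True)
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["diff"] = diff
    out["t"] = t
    out["p_raw"] = p
    out["p_adj"] = p_adj
    out["n_shared_cpg"] = n_shared[testable]
    out["direction"] = np.where(diff > 0, "hyper", "hypo")
    out["called"] = called
    if return_tested:
        return out
    return out[out["called"]].drop(columns="called").reset_index(drop=True)


def dmr_direction_summary(calls: pd.DataFrame) -> dict:
    """Counts and percentages of hyper- and hypo-DMRs in one comparison."""
    n_hyper = int((calls["direction"] == "hyper").sum())
    n_hypo = int((calls["direction"] == "hypo").sum())
    n = n_hyper + n_hypo
    return {
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": 100.0 * n_hyper / n if n else float("nan"),
        "pct_hypo": 100.0 * n_hypo / n if n else float("nan"),
    }


def _normalize_profiles(profiles: np.ndarray) -> np.ndarray:
    lo = profiles.min(axis=1, keepdims=True)
    hi = profiles.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = (profiles - lo) / span
    norm[flat] = 0.5  # flat profiles are equidistant; tie broken downstream
    return norm


def assign_six_clusters(
    profiles: pd.DataFrame, backend: str = "rule", random_state: int = 0
) -> pd.DataFrame:
    """Assign each DMR's (EC, HEC, HSPC) level profile to one of six patterns.

    ``profiles`` must carry columns EC, HEC, HSPC (mean sibling levels per
    cell type).  The default backend min-max-normalises each profile and
    picks the nearest canonical pattern centroid (Euclidean, ties to the
    lowest cluster index).  ``backend="kmeans"`` instead runs seeded k-means
    with k=6 on z-scored profiles and relabels each k-means cluster by its
    centroid's nearest canonical pattern (a sensitivity-analysis backend; no
    claim the study's heatmap used it).

    Rows with a missing cell-type level are returned with cluster ``NA``.
    """
    for col in ("EC", "HEC", "HSPC"):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing column {col!r}")
    mat = profiles[["EC", "HEC", "HSPC"]].to_numpy(dtype=float)
    ok = ~np.isnan(mat).any(axis=1)
    labels = np.array(["NA"] * len(mat), dtype=object)
    if ok.any():
        centroids = np.array([CANONICAL_PROFILES[c] for c in sorted(CANONICAL_PROFILES)])
        names = sorted(CANONICAL_PROFILES)
        norm = _normalize_profiles(mat[ok])
        if backend == "rule":
            d = ((norm[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            labels[ok] = [names[j] for j in d.argmin(axis=1)]
        elif backend == "kmeans":
            from sklearn.cluster import KMeans

            z = (norm - norm.mean(axis=0)) / (norm.std(axis=0) + 1e-12)
            km = KMeans(n_clusters=6, n_init=10, random_state=random_state).fit(z)
            # map each k-means centroid back to level space, then to patterns
            centers = km.cluster_centers_ * (norm.std(axis=0) + 1e-12) + norm.mean(axis=0)
            d = ((centers[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            mapping = {i: names[j] for i, j in enumerate(d.argmin(axis=1))}
            labels[ok] = [mapping[i] for i in km.labels_]
        else:
            raise ValueError(f"unknown backend {backend!r}")
    out = profiles.copy()
    out["cluster"] = labels
    out["pattern"] = [PATTERN_NAMES.get(c, "NA") for c in labels]
    return out
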