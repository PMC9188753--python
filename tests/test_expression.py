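"""Normalisation, DE calling, promoter levels, correlation and integration."""

import numpy as np
import pandas as pd
import pytest

from tilemeth.annotation import GeneModel
from tilemeth.core import MethylomeSample
from tilemeth.expression import (
    call_degs,
    integrate,
    normalize_counts,
    pearson_correlation,
    promoter_methylation_matrix,
    promoter_methylation_per_gene,
    size_factors,
    stage_transition_filter,
)
from tilemeth.tiling import MethylomeCohort

from conftest import random_records


class TestNormalize:
    def test_identical_samples_unit_factors(self, rng):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_factor_ratio_two(self):
        a = np.array([10, 100, 50, 7])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        norm = normalize_counts(counts)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))

    def test_single_gene_matrix_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            normalize_counts(pd.DataFrame({"a": [5], "b": [6]}))


class TestCallDegs:
    def groups(self):
        return ["a1", "a2", "a3"], ["b1", "b2", "b3"]

    def test_flat_gene_not_passing(self, rng):
        ga, gb = self.groups()
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 6)), columns=ga + gb, dtype=float
        )
        counts.iloc[0] = 100.0
        degs = call_degs(counts, ga, gb)
        assert degs["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not degs["passes"].iloc[0]

    def test_planted_eightfold_change_passes(self, rng):
        ga, gb = self.groups()
        counts = pd.DataFrame(
            rng.poisson(200, size=(60, 6)), columns=ga + gb, dtype=float
        )
        counts.iloc[0, :3] = rng.poisson(100, 3)
        counts.iloc[0, 3:] = rng.poisson(800, 3)
        degs = call_degs(normalize_counts(counts), ga, gb)
        assert degs["passes"].iloc[0]
        assert degs["log2fc"].iloc[0] == pytest.approx(3.0, abs=0.5)

    def test_sub_threshold_fold_change_never_passes(self):
        ga, gb = self.groups()
        # |log2fc| ~ 0.9 with essentially zero within-group variance
        counts = pd.DataFrame(
            {
                **{s: [1000.0, 50] for s in ga},
                **{s: [1865.0, 50] for s in gb},
            },
            index=["g_small_fc", "g_flat"],
        )
        degs = call_degs(counts, ga, gb).set_index("gene_id")
        row = degs.loc["g_small_fc"]
        assert 0.8 < abs(row["log2fc"]) < 1.0
        assert row["p_adj"] < 0.05
        assert not row["passes"]

    def test_null_simulation_passes_below_one_percent(self, rng):
        ga, gb = self.groups()
        counts = pd.DataFrame(
            rng.poisson(150, size=(2000, 6)), columns=ga + gb, dtype=float
        )
        degs = call_degs(normalize_counts(counts), ga, gb)
        assert degs["passes"].mean() < 0.01

    def test_overlapping_groups_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (10, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            call_degs(counts, ["a", "b"], ["b", "c"])


class TestPromoterLevels:
    def test_pooled_counts_over_promoter(self):
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos0": [4500, 5500], "meth": [2, 2], "total": [4, 4]}
        )
        g = GeneModel("g1", "chr1", "+", 5000, 7000, [(5000, 7000)])
        levels = promoter_methylation_per_gene(rec, [g])
        assert levels["g1"] == pytest.approx(0.5)

    def test_promoter_without_cpg_is_missing(self):
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos0": [100], "meth": [1], "total": [2]}
        )
        g = GeneModel("g1", "chr1", "+", 50_000, 52_000, [(50_000, 52_000)])
        assert np.isnan(promoter_methylation_per_gene(rec, [g])["g1"])

    def test_matrix_matches_bruteforce_scan(self, rng):
        rec = random_records(rng, n=300, max_pos=50_000)
        genes = []
        for k in range(10):
            start = 2000 + 4500 * k
            strand = "+" if k % 2 else "-"
            genes.append(
                GeneModel(f"g{k}", "chr1", strand, start, start + 1500,
                          [(start, start + 1500)])
            )
        sample = MethylomeSample("s1", "EC", "sibling", 1, rec)
        cohort = MethylomeCohort.from_samples([sample])
        mat = promoter_methylation_matrix(cohort, genes)
        single = promoter_methylation_per_gene(rec, genes)
        for g in genes:
            from tilemeth.annotation import promoter_region

            s, e = promoter_region(g)
            sub = rec[(rec["pos0"] >= s) & (rec["pos0"] < e)]
            expected = (
                sub["meth"].sum() / sub["total"].sum()
                if sub["total"].sum() > 0
                else np.nan
            )
            for got in (mat.loc[g.gene_id, "s1"], single[g.gene_id]):
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)


class TestPearson:
    def test_perfect_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_constant_vector_is_missing(self):
        assert np.isnan(pearson_correlation([1, 2, 3], [5, 5, 5]))

    def test_matches_direct_formula(self, rng):
        for _ in range(30):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            xc, yc = x - x.mean(), y - y.mean()
            ref = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert pearson_correlation(x, y) == pytest.approx(ref, abs=1e-12)

    def test_symmetry_and_shift_scale_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r)
        assert pearson_correlation(3 * x + 7, y) == pytest.approx(r)
        assert -1 <= r <= 1


def integration_inputs(corr_sibling_level, corr_mutant_level, meth_range=0.5):
    """Build promoter/expression tables realising the requested correlations.

    ``corr_*_level``: "neg" for a strong negative coupling, "flat" for none.
    """
    meta = pd.DataFrame(
        {
            "sample_id": [f"{g}{i}" for g in ("s", "m") for i in range(9)],
            "genotype": ["sibling"] * 9 + ["mutant"] * 9,
            "cell_type": (["EC"] * 3 + ["HEC"] * 3 + ["HSPC"] * 3) * 2,
        }
    )
    base_meth = np.linspace(0.3, 0.3 + meth_range, 9)
    jitter = np.linspace(-0.01, 0.01, 9)
    prom, expr = {}, {}
    for geno, mode in (("s", corr_sibling_level), ("m", corr_mutant_level)):
        meth = base_meth if mode != "static" else 0.5 + jitter
        e = 1000 * 2 ** (-3 * meth) if mode == "neg" else 400 + 10 * jitter
        for i in range(9):
            prom[f"{geno}{i}"] = meth[i]
            expr[f"{geno}{i}"] = e[i] if np.ndim(e) else e
    degs = pd.DataFrame({"gene_id": ["g1"]})
    prom_df = pd.DataFrame(prom, index=["g1"])
    expr_df = pd.DataFrame(expr, index=["g1"])
    return degs, prom_df, expr_df, meta


class TestIntegrate:
    def test_sibling_negative_mutant_flat_selected(self):
        out = integrate(*integration_inputs("neg", "flat"))
        assert out["corr_sibling"].iloc[0] < -0.3
        assert out["selected"].iloc[0]

    def test_negative_in_both_genotypes_not_selected(self):
        out = integrate(*integration_inputs("neg", "neg"))
        assert out["corr_mutant"].iloc[0] < -0.3
        assert not out["selected"].iloc[0]

    def test_weak_sibling_correlation_not_selected(self):
        out = integrate(*integration_inputs("flat", "flat"))
        assert not out["selected"].iloc[0]

    def test_static_promoter_correlation_treated_as_uninformative(self):
        # mutant methylation is static: even a spuriously negative r there
        # must not veto selection
        degs, prom, expr, meta = integration_inputs("neg", "neg")
        mut = [f"m{i}" for i in range(9)]
        prom.loc["g1", mut] = 0.5 + np.linspace(-0.01, 0.01, 9)  # range << 0.2
        out = integrate(degs, prom, expr, meta)
        assert out["meth_range_mutant"].iloc[0] < 0.2
        assert out["selected"].iloc[0]

    def test_selection_monotone_in_sibling_correlation(self):
        # strengthening the sibling anticorrelation never de-selects
        degs, prom, expr, meta = integration_inputs("neg", "flat")
        sib = [f"s{i}" for i in range(9)]
        meth = prom.loc["g1", sib].to_numpy(dtype=float)
        noise = np.array([1.0, -1, 1, -1, 1, -1, 1, -1, 0])
        mc = meth - meth.mean()
        noise = noise - noise.mean() - mc * (noise @ mc) / (mc @ mc)  # orthogonal
        selected_flags = []
        corrs = []
        for mix in (0.0, 0.3, 1.0, 6.0):  # growing noise, weakening coupling
            # build expression so its log2 is exactly 12 - 3*meth + mix*noise
            expr.loc["g1", sib] = np.exp2(12 - 3 * meth + mix * noise) - 1
            out = integrate(degs, prom, expr, meta)
            corrs.append(out["corr_sibling"].iloc[0])
            selected_flags.append(bool(out["selected"].iloc[0]))
        assert corrs == sorted(corrs)  # orthogonal noise only weakens r
        # once a weaker coupling is selected, every stronger one must be too
        for weaker, stronger in zip(selected_flags[1:], selected_flags):
            if weaker:
                assert stronger
        assert selected_flags[0] and not selected_flags[-1]


class TestStageTransitionFilter:
    def build(self, sib_meth, sib_expr, mut_meth, mut_expr):
        meta = pd.DataFrame(
            {
                "sample_id": [f"{g}_{ct}_{i}" for g in ("sibling", "mutant")
                              for ct in ("EC", "HEC", "HSPC") for i in range(3)],
                "genotype": ["sibling"] * 9 + ["mutant"] * 9,
                "cell_type": (["EC"] * 3 + ["HEC"] * 3 + ["HSPC"] * 3) * 2,
            }
        )
        prom, expr = {}, {}
        for geno, meths, exprs in (
            ("sibling", sib_meth, sib_expr),
            ("mutant", mut_meth, mut_expr),
        ):
            for ct, m, e in zip(("EC", "HEC", "HSPC"), meths, exprs):
                for i in range(3):
                    prom[f"{geno}_{ct}_{i}"] = m
                    expr[f"{geno}_{ct}_{i}"] = e
        return (
            pd.DataFrame(prom, index=["g1"]),
            pd.DataFrame(expr, index=["g1"]),
            meta,
        )

    def test_sibling_gain_and_silencing_mutant_flat_passes(self):
        prom, expr, meta = self.build(
            (0.5, 0.7, 0.7), (100, 40, 40), (0.5, 0.5, 0.5), (100, 100, 100)
        )
        out = stage_transition_filter(["g1"], prom, expr, meta)
        assert out["EC->HEC"] == ["g1"]
        assert out["HEC->HSPC"] == []

    def test_decreasing_sibling_methylation_fails(self):
        prom, expr, meta = self.build(
            (0.7, 0.5, 0.5), (100, 40, 40), (0.5, 0.5, 0.5), (100, 100, 100)
        )
        out = stage_transition_filter(["g1"], prom, expr, meta)
        assert out["EC->HEC"] == []

    def test_same_change_in_mutant_vetoes(self):
        prom, expr, meta = self.build(
            (0.5, 0.7, 0.7), (100, 40, 40), (0.5, 0.7, 0.7), (100, 40, 40)
        )
        out = stage_transition_filter(["g1"], prom, expr, meta)
        assert out["EC->HEC"] == []
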