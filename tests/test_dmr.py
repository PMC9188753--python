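"""t-test, BH adjustment, DMR calling and six-pattern assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilemeth.core import MethylomeSample
from tilemeth.dmr import (
    CANONICAL_PROFILES,
    assign_six_clusters,
    bh_adjust,
    call_dmrs,
    dmr_direction_summary,
    student_t_two_sample,
)
from tilemeth.tiling import MethylomeCohort, TileMatrix, make_tiles


def pooled_t_oracle(a, b):
    """Textbook pooled-variance Student's t and two-tailed p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def bh_oracle(p):
    """Step-up BH from its definition: p_(i) * n / i with monotone tail min."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        t, p = student_t_two_sample([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p) == (0.0, 1.0)

    def test_matches_textbook_formula(self):
        a, b = (0.1, 0.2, 0.15), (0.8, 0.9, 0.85)
        t, p = student_t_two_sample(a, b)
        t_ref, p_ref = pooled_t_oracle(a, b)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)
        assert p < 1e-4

    def test_swap_flips_sign_keeps_p(self):
        a, b = (0.1, 0.25, 0.15), (0.4, 0.5, 0.45)
        t1, p1 = student_t_two_sample(a, b)
        t2, p2 = student_t_two_sample(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            student_t_two_sample([0.5], [0.4, 0.6])

    def test_zero_variance_unequal_means_p0(self):
        _, p = student_t_two_sample([0.2, 0.2], [0.8, 0.8])
        assert p == 0.0


class TestBHAdjust:
    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_definition_oracle(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_oracle(ps), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def cohort_from_levels(levels, n_cpg=5, depth=1000, tile_size=500):
    """Cohort whose tile levels are (nearly) the given (tiles x samples) array."""
    levels = np.asarray(levels, float)
    n_tiles, n_samples = levels.shape
    pos = np.concatenate(
        [t * tile_size + 10 + 20 * np.arange(n_cpg) for t in range(n_tiles)]
    )
    samples = []
    for j in range(n_samples):
        meth = np.repeat(np.round(levels[:, j] * depth).astype(int), n_cpg)
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos0": pos, "meth": meth, "total": depth}
        )
        ct = ["EC", "HEC", "HSPC"][j % 3]
        samples.append(MethylomeSample(f"s{j}", ct, "sibling", j, rec))
    cohort = MethylomeCohort.from_samples(samples)
    tiles = make_tiles({"chr1": n_tiles * tile_size}, tile_size)
    return TileMatrix.from_cohort(cohort, tiles), [f"s{j}" for j in range(n_samples)]


class TestCallDmrs:
    def test_effect_size_filter_is_conjunctive(self):
        # highly significant but |diff| <= 0.2: never a DMR
        lv = np.column_stack([[0.50, 0.50]] * 3 + [[0.58, 0.95]] * 3)
        tm, ids = cohort_from_levels(lv)
        calls = call_dmrs(tm, ids[:3], ids[3:], min_shared_cpg=1)
        tested = call_dmrs(tm, ids[:3], ids[3:], min_shared_cpg=1, return_tested=True)
        assert tested["p_adj"].iloc[0] < 0.05 or tested["p_raw"].iloc[0] < 0.05
        assert "chr1:0-500" not in set(calls["tile_id"])
        assert "chr1:500-1000" in set(calls["tile_id"])

    def test_direction_antisymmetric_under_group_swap(self):
        lv = np.column_stack([[0.2], [0.25], [0.22], [0.8], [0.85], [0.82]])
        tm, ids = cohort_from_levels(lv.T.reshape(1, 6).repeat(2, axis=0) * [[1], [0.9]])
        fwd = call_dmrs(tm, ids[:3], ids[3:], min_shared_cpg=1)
        rev = call_dmrs(tm, ids[3:], ids[:3], min_shared_cpg=1)
        assert set(fwd["tile_id"]) == set(rev["tile_id"])
        merged = fwd.merge(rev, on="tile_id", suffixes=("_f", "_r"))
        assert (merged["direction_f"] != merged["direction_r"]).all()
        np.testing.assert_allclose(merged["diff_f"], -merged["diff_r"])

    def test_shared_cpg_rule_repools_intersection_only(self):
        # one CpG uncovered in one sample of group b must be excluded for all
        pos = [10, 30, 50]
        recs = []
        for j, (meths, totals) in enumerate(
            [
                ([5, 5, 0], [10, 10, 10]),
                ([5, 5, 0], [10, 10, 10]),
                ([9, 9, 9], [10, 10, 10]),
                ([9, 9, 0], [10, 10, 0]),  # third CpG uncovered here
            ]
        ):
            rec = pd.DataFrame(
                {"chrom": "chr1", "pos0": pos, "meth": meths, "total": totals}
            )
            recs.append(MethylomeSample(f"s{j}", "EC", "sibling", j, rec))
        cohort = MethylomeCohort.from_samples(recs)
        tm = TileMatrix.from_cohort(cohort, make_tiles({"chr1": 500}))
        tested = call_dmrs(
            tm, ["s0", "s1"], ["s2", "s3"], min_shared_cpg=2, return_tested=True
        )
        assert tested["n_shared_cpg"].iloc[0] == 2
        # group a level over shared CpGs: 10/20; with the third CpG it would be 10/30
        assert tested["mean_a"].iloc[0] == pytest.approx(0.5)
        assert tested["mean_b"].iloc[0] == pytest.approx(0.9)

    def test_min_shared_cpg_excludes_tile(self):
        lv = np.column_stack([[0.2]] * 3 + [[0.8]] * 3)
        tm, ids = cohort_from_levels(lv, n_cpg=2)
        tested = call_dmrs(tm, ids[:3], ids[3:], min_shared_cpg=3, return_tested=True)
        assert len(tested) == 0

    def test_group_errors(self):
        lv = np.column_stack([[0.2]] * 3 + [[0.8]] * 3)
        tm, ids = cohort_from_levels(lv)
        with pytest.raises(ValueError):
            call_dmrs(tm, [], ids[3:])
        with pytest.raises(ValueError):
            call_dmrs(tm, ids[:3], ids[2:])
        with pytest.raises(ValueError):
            call_dmrs(tm, ids[:3], ids[3:], alpha=1.5)


class TestDirectionSummary:
    def test_percentages(self):
        calls = pd.DataFrame({"direction": ["hyper"] * 3 + ["hypo"]})
        s = dmr_direction_summary(calls)
        assert (s["n_hyper"], s["n_hypo"]) == (3, 1)
        assert s["pct_hyper"] == pytest.approx(75.0)
        assert s["pct_hypo"] == pytest.approx(25.0)

    def test_no_calls_reported_as_undefined(self):
        s = dmr_direction_summary(pd.DataFrame({"direction": []}))
        assert (s["n_hyper"], s["n_hypo"]) == (0, 0)
        assert np.isnan(s["pct_hyper"])


class TestSixClusters:
    def test_noiseless_ec_hypo_profile(self):
        out = assign_six_clusters(
            pd.DataFrame({"EC": [0.2], "HEC": [0.8], "HSPC": [0.8]})
        )
        assert out["cluster"].iloc[0] == "C5"
        assert out["pattern"].iloc[0] == "EC-hypo"

    def test_noiseless_hec_hypo_profile(self):
        out = assign_six_clusters(
            pd.DataFrame({"EC": [0.8], "HEC": [0.2], "HSPC": [0.8]})
        )
        assert out["cluster"].iloc[0] == "C3"

    def test_six_canonical_profiles_get_six_distinct_labels(self):
        profiles = pd.DataFrame(
            [CANONICAL_PROFILES[c] for c in sorted(CANONICAL_PROFILES)],
            columns=["EC", "HEC", "HSPC"],
        )
        out = assign_six_clusters(profiles)
        assert list(out["cluster"]) == sorted(CANONICAL_PROFILES)

    def test_assignment_invariant_to_row_order(self, rng):
        profiles = pd.DataFrame(
            rng.uniform(0, 1, size=(40, 3)), columns=["EC", "HEC", "HSPC"]
        )
        out = assign_six_clusters(profiles)
        perm = rng.permutation(40)
        out_perm = assign_six_clusters(profiles.iloc[perm].reset_index(drop=True))
        assert list(out_perm["cluster"]) == [out["cluster"].iloc[i] for i in perm]

    def test_missing_level_unassigned(self):
        out = assign_six_clusters(
            pd.DataFrame({"EC": [np.nan], "HEC": [0.5], "HSPC": [0.9]})
        )
        assert out["cluster"].iloc[0] == "NA"

    def test_kmeans_backend_recovers_separated_patterns(self, rng):
        names = sorted(CANONICAL_PROFILES)
        base = np.array([CANONICAL_PROFILES[c] for c in names])
        profiles = np.repeat(base, 30, axis=0) * 0.6 + 0.2
        profiles += rng.normal(0, 0.02, profiles.shape)
        out = assign_six_clusters(
            pd.DataFrame(profiles, columns=["EC", "HEC", "HSPC"]),
            backend="kmeans",
            random_state=0,
        )
        truth = np.repeat(names, 30)
        assert (out["cluster"].to_numpy() == truth).mean() > 0.95
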