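"""Cohort comparison statistics against literal-transcription oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from piwas.io import SampleManifest
from piwas.stats import (MAD_SCALE, distribution_summary, fdr_adjust, hedges_g,
                         ks_test, mann_whitney, outlier_sum, permutation_null,
                         rank_proteome)


def _quantile_linear(sorted_vals, q):
    """Linear-interpolation quantile, written out longhand."""
    h = (len(sorted_vals) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(sorted_vals) - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def oracle_outlier_sum(case, control):
    """Step-by-step transcription of the outlier-sum definition: joint
    median/MAD standardization, fence at q75 + IQR, sum of case values
    strictly above the fence."""
    combined = list(case) + list(control)
    med = _quantile_linear(sorted(combined), 0.5)
    abs_dev = sorted(abs(x - med) for x in combined)
    mad = MAD_SCALE * _quantile_linear(abs_dev, 0.5)
    if mad == 0.0:
        mad = np.finfo(float).eps * max(1.0, max(abs(x) for x in combined))
    z = [(x - med) / mad for x in combined]
    zs = sorted(z)
    q75 = _quantile_linear(zs, 0.75)
    q25 = _quantile_linear(zs, 0.25)
    fence = q75 + (q75 - q25)
    return sum(v for v in z[:len(case)] if v > fence)


def oracle_permutation_null(case, control, n_perm, rng):
    """Literal permutation null: relabel, recompute the full statistic."""
    combined = np.concatenate([case, control])
    stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.argsort(rng.random(combined.size))[:len(case)]
        mask = np.zeros(combined.size, bool)
        mask[perm] = True
        stats[i] = outlier_sum(combined[mask], combined[~mask])
    return stats


class TestOutlierSum:
    def test_all_equal_values_give_zero(self):
        assert outlier_sum([1.0] * 3, [1.0] * 5) == 0.0

    def test_deterministic_in_labelling_only(self):
        case = [10.0, 0.0, 0.0]
        control = [0.1, -0.2, 0.05, 0.0, -0.1, 0.15]
        assert outlier_sum(case, control) == outlier_sum(case, control)
        assert outlier_sum(case, control) != outlier_sum(control, case)

    def test_small_instance_matches_literal_oracle(self):
        case = [10.0, 0.0, 0.0]
        control = [0.1, -0.2, 0.05, 0.0, -0.1, 0.15]
        assert outlier_sum(case, control) == pytest.approx(
            oracle_outlier_sum(case, control), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_instances_match_literal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_case = int(rng.integers(1, 10))
        n_ctrl = int(rng.integers(2, 12))
        case = rng.normal(size=n_case) * 10.0 ** rng.integers(-2, 3)
        control = rng.normal(size=n_ctrl) * 10.0 ** rng.integers(-2, 3)
        assert outlier_sum(case, control) == pytest.approx(
            oracle_outlier_sum(case, control), abs=1e-12)

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError):
            outlier_sum([], [1.0, 2.0])


class TestPermutationNull:
    def test_null_matches_literal_relabelling(self):
        """The vectorized subset-sum null equals recomputing the full
        statistic per permutation (standardization is label-invariant)."""
        rng = np.random.default_rng(0)
        case, control = rng.gumbel(size=8), rng.gumbel(size=15)
        res = permutation_null(case, control, n_perm=400,
                               rng=np.random.default_rng(99))
        oracle = oracle_permutation_null(case, control, 400,
                                         np.random.default_rng(99))
        assert res.null_mean == pytest.approx(oracle.mean(), abs=1e-10)
        assert res.null_sd == pytest.approx(oracle.std(ddof=1), abs=1e-10)

    def test_identical_constant_data_degenerate(self):
        res = permutation_null([2.0] * 4, [2.0] * 6, n_perm=200, rng=1)
        assert res.degenerate and res.os_p == 1.0

    def test_scale_invariance_of_z(self):
        rng = np.random.default_rng(2)
        case, control = rng.gumbel(size=10) + 3, rng.gumbel(size=20)
        r1 = permutation_null(case, control, n_perm=500, rng=7)
        r2 = permutation_null(2 * case, 2 * control, n_perm=500, rng=7)
        assert r1.os_z == pytest.approx(r2.os_z, rel=1e-9)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null([1.0], [2.0, 3.0], n_perm=10, rng=0)


class TestClassicalTests:
    def test_mann_whitney_exact_separated_groups(self):
        # 20 arrangements of 3+3 ranks; only one puts all cases on top
        assert mann_whitney([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_mann_whitney_no_shift_is_half(self):
        p = mann_whitney([1.5, 2.5, 3.5], [1.0, 2.0, 3.0, 1.2, 2.2, 3.2])
        assert 0.2 < p < 0.8

    def test_mann_whitney_label_swap_complements(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=30)
        assert mann_whitney(a, b) + mann_whitney(b, a) == pytest.approx(1.0, abs=0.01)

    def test_ks_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ks_test(x, x) == 1.0

    def test_ks_disjoint_supports(self):
        assert ks_test(np.arange(10) + 100.0, np.arange(10.0)) < 1e-4

    def test_hedges_g_closed_form(self):
        # d = 3, J = 1 - 3/15 = 0.8, g = 2.4
        assert hedges_g([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(2.4)

    def test_hedges_g_zero_and_antisymmetric(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 5.0]
        assert hedges_g(a, a) == 0.0
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_hedges_g_degenerate_pooled_sd(self):
        assert math.isnan(hedges_g([1.0, 1.0], [1.0, 1.0]))


class TestFdr:
    def test_two_value_example(self):
        assert fdr_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_step_up_by_hand(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = fdr_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _toy_scores(rng, n_prot=4, n_case=5, n_ctrl=8):
    rows = []
    manifest_rows = []
    for i in range(n_case):
        manifest_rows.append((f"t{i}", f"t{i}.txt", "case"))
    for i in range(n_ctrl):
        manifest_rows.append((f"u{i}", f"u{i}.txt", "control"))
    manifest = SampleManifest(tuple(manifest_rows))
    # signal in a 2-sample subset of the cases: the regime the outlier sum
    # is built for (a shift of ALL cases would drag the fence up with it)
    for sid, _, cohort in manifest_rows:
        signal = cohort == "case" and sid in ("t0", "t1")
        for p in range(n_prot):
            boost = 8.0 if (signal and p == 0) else 0.0
            rows.append((sid, f"p{p}", float(rng.gumbel() + boost),
                         int(rng.integers(0, 50))))
    return pd.DataFrame(rows, columns=["sample_id", "protein_id",
                                       "piwas_score", "piwas_loc"]), manifest


class TestRankProteome:
    def test_signal_protein_ranks_first(self):
        scores, manifest = _toy_scores(np.random.default_rng(5))
        table = rank_proteome(scores, manifest, n_perm=300, seed=1)
        assert table.iloc[0]["protein_id"] == "p0"
        assert set(table["protein_id"]) == {"p0", "p1", "p2", "p3"}

    def test_sample_order_invariance(self):
        scores, manifest = _toy_scores(np.random.default_rng(6))
        shuffled = scores.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t1 = rank_proteome(scores, manifest, n_perm=300, seed=2)
        t2 = rank_proteome(shuffled, manifest, n_perm=300, seed=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_protein_order_invariance(self):
        scores, manifest = _toy_scores(np.random.default_rng(7))
        reordered = scores.sort_values("protein_id", ascending=False,
                                       kind="mergesort").reset_index(drop=True)
        t1 = rank_proteome(scores, manifest, n_perm=300, seed=2)
        t2 = rank_proteome(reordered, manifest, n_perm=300, seed=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_all_zero_protein_reported_with_p_one(self):
        scores, manifest = _toy_scores(np.random.default_rng(8))
        scores.loc[scores["protein_id"] == "p3", "piwas_score"] = 0.0
        table = rank_proteome(scores, manifest, n_perm=300, seed=0)
        row = table[table["protein_id"] == "p3"].iloc[0]
        assert row["os_p"] == 1.0 and row["mw_p"] == 1.0

    def test_manifest_scores_mismatch_rejected(self):
        scores, manifest = _toy_scores(np.random.default_rng(9))
        with pytest.raises(ValueError, match="missing"):
            rank_proteome(scores[scores["sample_id"] != "t0"], manifest,
                          n_perm=300, seed=0)


class TestDistributionSummary:
    def test_counts_conserved_per_sample(self):
        rng = np.random.default_rng(10)
        vals = {"a": rng.normal(size=100), "b": rng.normal(size=57)}
        df = distribution_summary(vals, bins=10)
        sums = df.groupby("sample_id")["count"].sum()
        assert sums["a"] == 100 and sums["b"] == 57

    def test_all_zero_values_fall_in_one_bin(self):
        df = distribution_summary({"a": np.zeros(12)}, bins=10)
        assert df["count"].sum() == 12
        assert (df[df["count"] > 0]["count"] == 12).all()

    def test_case_cohort_shows_heavier_right_tail(self):
        rng = np.random.default_rng(11)
        vals = {"case": np.concatenate([rng.gumbel(size=90), rng.gumbel(8, 1, size=10)]),
                "control": rng.gumbel(size=100)}
        df = distribution_summary(vals, bins=20)
        upper = df[df["bin_left"] > 5]
        tail = upper.groupby("sample_id")["count"].sum()
        assert tail.get("case", 0) > tail.get("control", 0)
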