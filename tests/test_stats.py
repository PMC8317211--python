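import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs
from scipy import stats as sps

import tmtpipe as tp
from tmtpipe import stats as st
from tmtpipe.errors import InsufficientDataError

from conftest import make_matrix


def four_group_matrix(rng, n=50, reps=4, effect_ids=(), effect=0.0, sigma=0.25):
    """Single-table log2 matrix, n proteins x 4 groups x reps, optional
    MC-group shift on selected rows."""
    groups = sum(([g] * reps for g in ("MC", "FC", "MN", "FN")), [])
    vals = rng.normal(15.0, 1.0, size=(n, 1)) + rng.normal(
        0.0, sigma, size=(n, 4 * reps))
    for i in effect_ids:
        vals[i, :reps] += effect
    return make_matrix(vals, groups, scale="log2")


class TestDStatistic:
    def test_s0_zero_reduces_to_pooled_t(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 9))
            b = rng.normal(0.5, 1.3, size=rng.integers(3, 9))
            _, d = tp.d_statistic(a, b, s0=0.0)
            t = sps.ttest_ind(a, b, equal_var=True).statistic
            assert d == pytest.approx(t, abs=1e-12)

    def test_hand_case_zero_variance(self):
        diff, d = tp.d_statistic([2.0, 2.0], [1.0, 1.0], s0=0.5)
        assert diff == pytest.approx(1.0)
        assert d == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        _, d = tp.d_statistic([3.0, 5.0], [4.0, 4.0], s0=0.7)
        assert d == pytest.approx(0.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            tp.d_statistic([1.0], [2.0, 3.0], s0=0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hs.integers(0, 10_000), hs.floats(0.0, 2.0), hs.floats(0.0, 2.0))
    def test_increasing_s0_never_increases_abs_d(self, seed, s0a, s0b):
        lo, hi = sorted([s0a, s0b])
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 5), r.normal(1, 1, 5)
        _, d_lo = tp.d_statistic(a, b, s0=lo)
        _, d_hi = tp.d_statistic(a, b, s0=hi)
        assert abs(d_hi) <= abs(d_lo) + 1e-12


class TestAnovaPrefilter:
    def test_matches_f_oneway_and_keeps_shifted_protein(self, rng):
        m = four_group_matrix(rng, n=40, effect_ids=[0], effect=2.5)
        cfg = tp.TestConfig(anova_fdr=0.05)
        kept, table = tp.anova_prefilter(m, cfg)
        labels = m.group_labels()
        blocks = [m.values[labels.index[labels == g]].to_numpy()
                  for g in ("MC", "FC", "MN", "FN")]
        for i in range(5):
            f_ref, p_ref = sps.f_oneway(*[b[i] for b in blocks])
            assert table["F"].iloc[i] == pytest.approx(f_ref, rel=1e-10)
            assert table["p_value"].iloc[i] == pytest.approx(p_ref, rel=1e-10)
        assert "P0001" in kept.values.index  # 10-sigma-style shift retained

    def test_constant_protein_dropped(self, rng):
        m = four_group_matrix(rng, n=10)
        m.values.iloc[0, :] = 15.0
        kept, table = tp.anova_prefilter(m, tp.TestConfig())
        assert np.isnan(table["F"].iloc[0])
        assert "P0001" not in kept.values.index


class TestPermutationFdr:
    def test_exhaustive_enumeration_for_four_vs_four(self, rng):
        m = four_group_matrix(rng, n=20)
        res = tp.permutation_fdr(m, "MC", "FC", tp.TestConfig(seed=1))
        assert res.n_permutations == 69  # C(8,4) - identity

    def test_q_monotone_non_increasing_in_abs_d(self, rng):
        m = four_group_matrix(rng, n=60, effect_ids=range(6), effect=1.0)
        res = tp.permutation_fdr(m, "MC", "FC", tp.TestConfig(seed=2))
        t = res.table.assign(abs_d=lambda x: x["d"].abs()).sort_values("abs_d")
        assert (np.diff(t["q_value"].to_numpy()) <= 1e-12).all()

    def test_reversed_groups_flip_sign_and_direction_only(self, rng):
        m = four_group_matrix(rng, n=40, effect_ids=range(4), effect=1.2)
        cfg = tp.TestConfig(seed=3)
        fwd = tp.permutation_fdr(m, "MC", "FC", cfg)
        rev = tp.permutation_fdr(m, "FC", "MC", cfg)
        np.testing.assert_allclose(fwd.table["log2_fc"], -rev.table["log2_fc"])
        np.testing.assert_allclose(fwd.table["q_value"], rev.table["q_value"],
                                   atol=1e-12)
        flipped = fwd.table["direction"].map({"up": "down", "down": "up"})
        assert (flipped == rev.table["direction"]).all()

    def test_duplicated_rows_share_q_values(self, rng):
        m = four_group_matrix(rng, n=20)
        vals = pd.concat([m.values, m.values.set_axis(
            [f"D{i}" for i in range(20)], axis=0)])
        m2 = make_matrix(vals.to_numpy(), list(m.group_labels()), scale="log2",
                         ids=list(vals.index))
        res = tp.permutation_fdr(m2, "MC", "FC", tp.TestConfig(seed=4))
        np.testing.assert_allclose(res.table["q_value"].iloc[:20].to_numpy(),
                                   res.table["q_value"].iloc[20:].to_numpy())

    def test_single_large_effect_attains_minimum_q(self, rng):
        m = four_group_matrix(rng, n=100, effect_ids=[7], effect=2.5)
        res = tp.permutation_fdr(m, "MC", "FC", tp.TestConfig(seed=5))
        q = res.table["q_value"]
        assert q.loc["P0008"] == q.min()


class TestPairwiseSuite:
    def test_sex_effects_dominate_sex_contrast(self):
        d = tp.SyntheticDesign(n_proteins=300, frac_sex_de=0.15,
                               frac_trt_de_f=0.0, frac_trt_de_m=0.0,
                               frac_missing=0.0, frac_decoy=0.0,
                               frac_contaminant=0.0, frac_only_site=0.0,
                               seed=21)
        m, _ = tp.generate_dataset(d)
        norm, _ = tp.normalize_pipeline(tp.filter_rows(m), "irs")
        res, _ = tp.run_pairwise_suite(norm, tp.TestConfig(seed=1,
                                                           anova_enabled=False))
        n_sex = res["MC_vs_FC"].counts()["n_significant"]
        n_trt = (res["FN_vs_FC"].counts()["n_significant"]
                 + res["MN_vs_MC"].counts()["n_significant"])
        assert n_sex > 5 * max(n_trt, 1)

    def test_anova_toggle_changes_tested_universe(self):
        d = tp.SyntheticDesign(n_proteins=200, seed=22, frac_missing=0.0,
                               frac_decoy=0.0, frac_contaminant=0.0,
                               frac_only_site=0.0)
        m, _ = tp.generate_dataset(d)
        norm, _ = tp.normalize_pipeline(tp.filter_rows(m), "irs")
        with_f, anova_tbl = tp.run_pairwise_suite(
            norm, tp.TestConfig(seed=2, anova_enabled=True))
        without, none_tbl = tp.run_pairwise_suite(
            norm, tp.TestConfig(seed=2, anova_enabled=False))
        assert none_tbl is None
        n_with = with_f["MC_vs_FC"].counts()["n_tested"]
        n_without = without["MC_vs_FC"].counts()["n_tested"]
        assert n_with == int(anova_tbl["keep"].sum())
        assert n_with < n_without == norm.n_proteins


def test_volcano_table_has_finite_neg_log10_q(rng):
    m = four_group_matrix(rng, n=30, effect_ids=[0], effect=2.0)
    res = tp.permutation_fdr(m, "MC", "FC", tp.TestConfig(seed=6))
    v = st.volcano_table(res)
    assert np.isfinite(v["neg_log10_q"]).all()
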