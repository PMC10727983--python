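"""Normalization, entropy, scaling, rank tests, BH, feature sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfrepeat import features
from cfrepeat.features import (
    bh_adjust,
    build_feature_sets,
    group_fractions,
    log_transform,
    normalize,
    pca,
    pearson_matrix,
    shannon_entropy,
    size_factors,
    wilcoxon_rank_sum,
    zscore,
)
from cfrepeat.quantify import CountMatrix


def cm(values, features=None, samples=None, state="raw"):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=features, columns=samples), state=state)


class TestSizeFactors:
    def test_hand_computed_two_by_two(self):
        # rows [2,4] and [6,12]: geometric means (2.828, 8.485); ratios 1/sqrt(2), sqrt(2)
        s = size_factors(cm([[2, 4], [6, 12]]))
        assert s.tolist() == pytest.approx([0.70710678, 1.41421356])

    def test_identical_columns_equal_factors(self):
        s = size_factors(cm([[5, 5, 5], [9, 9, 9]]))
        assert s.nunique() == 1

    def test_scaling_column_triples_its_relative_factor(self):
        # factors are defined up to the geometric-mean reference, so the
        # invariant is on ratios between samples
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(50, 6)).astype(float) + 1
        scaled = base.copy()
        scaled[:, 2] *= 3
        s0 = size_factors(cm(base))
        s1 = size_factors(cm(scaled))
        rel0 = s0.iloc[2] / s0.iloc[0]
        rel1 = s1.iloc[2] / s1.iloc[0]
        assert rel1 / rel0 == pytest.approx(3.0, rel=1e-9)

    def test_no_allpositive_feature_errors(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(cm([[0, 5], [5, 0]]))

    def test_normalize_undoes_scaling(self):
        base = np.array([[10.0, 10.0], [4.0, 4.0]])
        scaled = base * [1.0, 2.0]
        mat = cm(scaled)
        norm = normalize(mat, size_factors(mat))
        np.testing.assert_allclose(norm.data.values[:, 0], norm.data.values[:, 1])

    def test_unit_factors_identity(self):
        mat = cm([[3, 4], [5, 6]])
        s = pd.Series([1.0, 1.0], index=mat.data.columns)
        pd.testing.assert_frame_equal(normalize(mat, s).data, mat.data)


class TestEntropy:
    GROUPS = {f"f{i}": "SINE" for i in range(4)}

    def test_uniform_is_log2_n(self):
        ent = shannon_entropy(cm([[5], [5], [5], [5]], state="normalized"), self.GROUPS)
        assert ent.loc["s0", "SINE"] == pytest.approx(2.0)

    def test_degenerate_is_zero(self):
        ent = shannon_entropy(cm([[7], [0], [0], [0]], state="normalized"), self.GROUPS)
        assert ent.loc["s0", "SINE"] == 0.0

    def test_half_quarter_quarter(self):
        ent = shannon_entropy(cm([[2], [1], [1], [0]], state="normalized"), self.GROUPS)
        assert ent.loc["s0", "SINE"] == pytest.approx(1.5)

    def test_zero_group_total_is_nan_with_warning(self, caplog):
        groups = {"f0": "SINE", "f1": "LINE"}
        with caplog.at_level("WARNING"):
            ent = shannon_entropy(cm([[4], [0]], state="normalized"), groups)
        assert np.isnan(ent.loc["s0", "LINE"])
        assert "undefined" in caplog.text

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_on_random_compositions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        counts = rng.random(n) * (rng.random(n) < 0.8)
        if counts.sum() == 0:
            counts[0] = 1.0
        groups = {f"f{i}": "g" for i in range(n)}
        ent = shannon_entropy(cm(counts[:, None], state="normalized"), groups)
        h = ent.loc["s0", "g"]
        nonzero = int((counts > 0).sum())
        assert -1e-12 <= h <= np.log2(max(nonzero, 1)) + 1e-9


class TestFractions:
    def test_single_group_fraction_one(self):
        frac = group_fractions(cm([[3], [9]], state="normalized"), {"f0": "SINE", "f1": "SINE"})
        assert frac.loc["s0", "SINE"] == 1.0

    def test_two_equal_groups(self):
        frac = group_fractions(cm([[5], [5]], state="normalized"), {"f0": "SINE", "f1": "LINE"})
        assert frac.loc["s0"].tolist() == [0.5, 0.5]

    def test_fractions_sum_to_one_random(self):
        rng = np.random.default_rng(3)
        mat = cm(rng.random((20, 6)) + 0.01, state="normalized")
        groups = {f"f{i}": f"g{i % 4}" for i in range(20)}
        frac = group_fractions(mat, groups)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)


class TestZscoreAndPCA:
    def test_one_two_three(self):
        z = zscore(cm([[1, 2, 3]]))
        np.testing.assert_allclose(z.data.values[0], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        z = zscore(cm([[4, 4, 4], [1, 2, 3]]))
        assert list(z.data.index) == ["f1"]

    def test_mean_zero_sd_one_random(self):
        rng = np.random.default_rng(1)
        z = zscore(cm(rng.random((30, 8))))
        np.testing.assert_allclose(z.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.data.std(axis=1, ddof=1), 1.0)

    def test_planted_two_groups_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (40, 1)) + rng.normal(0, 0.05, (40, 5))
        b = a + 4.0
        mat = cm(np.hstack([a + rng.normal(0, 0.05, (40, 5)), b]), state="log")
        res = pca(mat, rank=5)
        pc1 = res.scores["PC1"].values
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()

    def test_orthonormal_loadings_and_decreasing_variance(self):
        rng = np.random.default_rng(4)
        res = pca(cm(rng.random((30, 10))), rank=6)
        gram = res.loadings.values.T @ res.loadings.values
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and evr.sum() <= 1 + 1e-9

    def test_pca_on_zscored_equals_internal_scaling(self):
        rng = np.random.default_rng(5)
        mat = cm(rng.random((25, 9)))
        direct = pca(mat, rank=4, scale=True)
        via_z = pca(zscore(mat), rank=4, scale=False)
        np.testing.assert_allclose(
            np.abs(direct.scores.values), np.abs(via_z.scores.values), atol=1e-8
        )

    def test_pearson_properties(self):
        rng = np.random.default_rng(6)
        mat = cm(rng.random((15, 5)))
        corr = pearson_matrix(mat)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)
        anti = cm(np.array([[1, 4], [2, 3], [3, 2], [4, 1]], dtype=float))
        assert pearson_matrix(anti).iloc[0, 1] == pytest.approx(-1.0)


def brute_force_mannwhitney_p(x, y):
    """Enumerate all group assignments of the pooled sample (no ties)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    observed = u_stat(range(n1))
    n = len(pooled)
    us = [u_stat(c) for c in combinations(range(n), n1)]
    mean_u = len(x) * len(y) / 2
    dev = abs(observed - mean_u)
    extreme = sum(abs(u - mean_u) >= dev - 1e-12 for u in us)
    return extreme / len(us)


class TestWilcoxon:
    def test_printed_exact_example(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(12):
            n1, n2 = rng.integers(3, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(brute_force_mannwhitney_p(x, y), abs=1e-12)

    def test_paired_all_zero_differences(self, caplog):
        with caplog.at_level("WARNING"):
            _, p = wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0], paired=True)
        assert p == 1.0

    def test_paired_detects_shift(self):
        x = np.arange(1, 11, dtype=float)
        _, p = wilcoxon_rank_sum(x + 1.0, x, paired=True)
        assert p < 0.01


class TestBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_never_decreases_and_permutation_invariant(self, ps):
        ps = np.array(ps)
        adj = bh_adjust(ps)
        assert (adj >= ps - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(bh_adjust(ps[perm]), adj[perm])


class DummyDE:
    def __init__(self, table, sample_ids):
        self.table = table
        self.sample_ids = sample_ids


class TestFeatureSets:
    @pytest.fixture()
    def pieces(self):
        aware = ["G1", "G2", "rmsk:AluY", "rmsk:(TA)n"]
        naive = ["G1", "G2"]
        de_tab = pd.DataFrame(
            {"padj": [0.001, 0.5, 0.004, 0.9]},
            index=["rmsk:AluY", "G1", "G2", "rmsk:(TA)n"],
        )
        return aware, naive, de_tab

    def test_eight_sets_with_expected_members(self, pieces):
        aware, naive, de_tab = pieces
        sets = build_feature_sets(
            aware, naive, ["SINE", "LINE"], DummyDE(de_tab, ["a", "b"]), ["a", "b", "c"]
        )
        assert len(sets) == 8
        assert all(f.startswith("rmsk:") for f in sets["total_repeat_alone"].feature_ids)
        assert sets["de_aware"].feature_ids == ["rmsk:AluY", "G2"]
        assert sets["de_repeat_alone"].feature_ids == ["rmsk:AluY"]
        assert sets["entropy_clade"].feature_ids == ["entropy:SINE", "entropy:LINE"]
        assert set(sets["entropy_clade_plus_naive"].feature_ids) == {
            "entropy:SINE",
            "entropy:LINE",
            "G1",
            "G2",
        }

    def test_leaked_de_provenance_rejected(self, pieces):
        aware, naive, de_tab = pieces
        with pytest.raises(ValueError, match="non-training"):
            build_feature_sets(
                aware, naive, ["SINE"], DummyDE(de_tab, ["a", "test_sample"]), ["a", "b"]
            )
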