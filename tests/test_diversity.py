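import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from viromix.diversity import (alpha_diversity, bray_curtis, dbrda,
                               envfit_factor, observed_features, pca,
                               permanova, rarefaction_curve, rarefy_counts,
                               shannon)


class TestRarefy:
    def test_full_depth_returns_row_unchanged(self, rng):
        row = np.array([5, 0, 3, 2])
        assert (rarefy_counts(row, 10, rng) == row).all()

    def test_depth_one_draws_single_read(self, rng):
        sub = rarefy_counts(np.array([5, 5, 5]), 1, rng)
        assert sub.sum() == 1 and observed_features(sub) == 1

    def test_depth_beyond_total_rejected(self, rng):
        with pytest.raises(ValueError, match="depth"):
            rarefy_counts(np.array([1, 1]), 3, rng)

    def test_hypergeometric_mean_and_spread(self, rng):
        """Mean per-feature draw matches the hypergeometric expectation."""
        row = np.array([5000, 5000])
        reps = np.array([rarefy_counts(row, 1000, rng)[0] for _ in range(2000)])
        sd = np.sqrt(1000 * 0.25 * (10000 - 1000) / (10000 - 1))
        assert abs(reps.mean() - 500) < 3 * sd / np.sqrt(len(reps))

    def test_rarefied_richness_never_exceeds_full(self, rng):
        row = rng.integers(0, 50, size=30)
        row[0] += 10
        sub = rarefy_counts(row, int(row.sum() // 3), rng)
        assert observed_features(sub) <= observed_features(row)

    def test_curve_marks_shallow_samples_absent(self, rng):
        counts = pd.DataFrame({"a": [10, 100], "b": [10, 100]}, index=["s1", "s2"])
        curve = rarefaction_curve(counts, depths=[15, 150], n_replicates=2, rng=rng)
        shallow = curve[(curve["sample"] == "s1") & (curve["depth"] == 150)]
        assert shallow["observed"].isna().all()


class TestAlphaClosedForms:
    def test_shannon_uniform_four(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_shannon_single_feature_zero(self):
        assert shannon([10, 0, 0]) == 0.0

    def test_shannon_hand_value(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)

    def test_shannon_scale_invariant(self):
        assert shannon([2, 1, 1]) == pytest.approx(shannon([200, 100, 100]))

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    @pytest.mark.parametrize("x,expected", [([3, 0, 1], 2), ([0, 0], 0)])
    def test_observed_features(self, x, expected):
        assert observed_features(x) == expected

    def test_alpha_diversity_common_depth(self, rng):
        counts = pd.DataFrame({"a": [50, 500], "b": [50, 500], "c": [0, 500]},
                              index=["s1", "s2"])
        alpha = alpha_diversity(counts, n_replicates=3, rng=rng)
        assert alpha.loc["s1", "observed"] == 2  # c never seen in s1
        assert alpha.loc["s2", "observed"] <= 3


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        abund = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(abund).loc["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        abund = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(abund).loc["a", "b"] == 1.0

    def test_hand_example(self):
        abund = pd.DataFrame([[2, 1], [1, 1]], index=["x", "y"])
        assert bray_curtis(abund).loc["x", "y"] == pytest.approx(0.2)

    def test_symmetric_zero_diagonal_bounded(self, rng):
        abund = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"))
        D = bray_curtis(abund)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert ((D.values >= 0) & (D.values <= 1)).all()

    def test_all_zero_pair_defined_as_zero(self):
        abund = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"])
        assert bray_curtis(abund).loc["a", "b"] == 0.0


class TestPCA:
    def test_two_clusters_separate_on_pc1(self, rng):
        block = np.vstack([rng.normal(0, 0.05, size=(10, 4)),
                           rng.normal(3, 0.05, size=(10, 4))])
        abund = pd.DataFrame(block)
        result = pca(abund)
        scores = result.axis_scores["PC1"]
        assert result.explained_fraction[0] > 0.5
        assert (scores.iloc[:10] * scores.iloc[10:].mean() < 0).all()

    def test_explained_fractions_sum_to_one(self, rng):
        abund = pd.DataFrame(rng.random((8, 5)))
        assert pca(abund).explained_fraction.sum() == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self, rng):
        X = rng.random((5, 4))
        abund = pd.DataFrame(np.vstack([X, X[0]]))
        scores = pca(abund).axis_scores
        assert np.allclose(scores.iloc[0], scores.iloc[5], atol=1e-9)


def _grouped_data(rng, n_per=8, sep=0.0, n_feat=6, k=3):
    blocks, labels = [], []
    for g in range(k):
        block = rng.random((n_per, n_feat))
        block[:, g % n_feat] += sep  # each group enriched in its own feature
        blocks.append(block)
        labels += [f"g{g}"] * n_per
    df = pd.DataFrame(np.vstack(blocks),
                      index=[f"s{i}" for i in range(n_per * k)])
    df = df.div(df.sum(axis=1), axis=0)
    return df, labels


class TestDbrda:
    def test_no_group_structure_gives_tiny_constrained_inertia(self, rng):
        abund, labels = _grouped_data(rng, sep=0.0)
        result = dbrda(bray_curtis(abund), labels)
        assert result.explained_fraction.sum() < 0.25

    def test_planted_separation_concentrates_on_cap_axes(self, rng):
        abund, labels = _grouped_data(rng, sep=1.0)
        result = dbrda(bray_curtis(abund), labels)
        assert result.constrained_axes[:2] == ["CAP1", "CAP2"]
        assert result.explained_fraction[:2].sum() > 0.5

    def test_constrained_axis_count_bounded_by_groups(self, rng):
        abund, labels = _grouped_data(rng, sep=0.5, k=3)
        result = dbrda(bray_curtis(abund), labels)
        assert len(result.constrained_axes) <= 2

    def test_singleton_group_rejected(self, rng):
        abund, labels = _grouped_data(rng)
        labels[0] = "lonely"
        with pytest.raises(ValueError, match="size 1"):
            dbrda(bray_curtis(abund), labels)


class TestEnvfit:
    def test_perfect_separation_minimal_p(self, rng):
        abund, labels = _grouped_data(rng, sep=5.0, k=2)
        result = pca(abund)
        r2, p = envfit_factor(result, labels, n_perm=99, rng=rng)
        # group centroids differ along PC1; PC2 carries pure noise, so r2
        # sits near the PC1 share of the two-axis variance
        assert r2 > 0.4
        assert p == pytest.approx(1 / 100)

    def test_single_group_zero_r2(self, rng):
        abund, labels = _grouped_data(rng)
        r2, p = envfit_factor(pca(abund), ["same"] * len(labels), rng=rng)
        assert (r2, p) == (0.0, 1.0)

    def test_null_p_uniformity(self, rng):
        """Shuffled labels against structure-free scores give ~uniform p."""
        pvals = []
        for _ in range(100):
            abund, labels = _grouped_data(rng, n_per=6, sep=0.0)
            result = pca(abund)
            r2, p = envfit_factor(result, rng.permutation(labels), n_perm=49, rng=rng)
            pvals.append(p)
        assert 0.25 < np.mean(pvals) < 0.75
        assert np.mean(np.asarray(pvals) <= 0.1) < 0.25


class TestPermanova:
    def test_extreme_separation(self, rng):
        abund = pd.DataFrame(np.vstack([np.eye(3)[np.zeros(6, int)],
                                        np.eye(3)[np.ones(6, int)]]))
        labels = ["A"] * 6 + ["B"] * 6
        res = permanova(bray_curtis(abund), labels, n_perm=99, rng=rng)
        assert res.p == pytest.approx(1 / 100)
        assert res.r2 > 0.9

    def test_matches_reference_implementation(self, rng):
        """Pseudo-F agrees with the scikit-bio PERMANOVA on the same input."""
        abund, labels = _grouped_data(rng, sep=0.3)
        D = bray_curtis(abund)
        ours = permanova(D, labels, n_perm=99, rng=rng)
        ref = skbio_permanova(DistanceMatrix(D.values, ids=list(D.index)),
                              grouping=list(labels), permutations=0)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_r2_matches_one_way_anova_on_euclidean_1d(self, rng):
        """With Euclidean distance on 1-D data, R2 equals ANOVA eta-squared."""
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)])
        labels = ["A"] * 10 + ["B"] * 10
        D = np.abs(values[:, None] - values[None, :])
        res = permanova(D, labels, n_perm=49, rng=rng)
        grand = values.mean()
        ss_total = ((values - grand) ** 2).sum()
        ss_within = sum(((values[i * 10:(i + 1) * 10]
                          - values[i * 10:(i + 1) * 10].mean()) ** 2).sum()
                        for i in range(2))
        eta2 = 1 - ss_within / ss_total
        assert res.r2 == pytest.approx(eta2, rel=1e-9)

    def test_adjusted_r2_below_r2_and_p_floor(self, rng):
        abund, labels = _grouped_data(rng, sep=0.2)
        res = permanova(bray_curtis(abund), labels, n_perm=49, rng=rng)
        assert res.r2_adjusted <= res.r2
        assert res.p >= 1 / 50

    def test_numeric_covariate_single_regression_df(self, rng):
        abund, _ = _grouped_data(rng)
        x = rng.normal(size=len(abund))
        res = permanova(bray_curtis(abund), x, n_perm=49, rng=rng)
        assert res.df_model == 1

    def test_constant_grouping_rejected(self, rng):
        abund, _ = _grouped_data(rng)
        with pytest.raises(ValueError, match="constant"):
            permanova(bray_curtis(abund), ["x"] * len(abund), rng=rng)
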