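"""t-tests, PCA, classifier, k-means, indices, FRET, heat maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import chromatex as cx
from chromatex.errors import (
    BadKError,
    DegenerateAxisError,
    DegenerateMarginWarning,
    TooFewConditionsError,
    TooFewSamplesError,
    ZeroAcceptorError,
    ZeroCountsError,
)

from .conftest import random_descriptor_frame
from .oracles import brute_pca_scores


def dataset(frame, conditions):
    return cx.DescriptorDataset(frame, pd.Series(conditions))


def tiled_dataset(per_descriptor_values, condition):
    """Every descriptor column holds the same small sample."""
    col = np.asarray(per_descriptor_values, dtype=float)
    X = np.tile(col[:, None], (1, 104))
    return dataset(
        pd.DataFrame(X, columns=cx.descriptor_names()), [condition] * len(col)
    )


class TestTTestMatrix:
    def test_pooled_variance_closed_form(self):
        """{1,2,3} vs {4,5,6}: t = -3.674, df = 4, p ~ 0.02139."""
        res = cx.ttest_matrix(tiled_dataset([1, 2, 3], "a"),
                              tiled_dataset([4, 5, 6], "b"))
        t_expected = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_expected = 2 * sps.t.sf(abs(t_expected), df=4)
        assert len(res) == 104
        np.testing.assert_allclose(res["t"], t_expected, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], p_expected, atol=1e-10)
        assert p_expected == pytest.approx(0.02139, abs=1e-4)

    def test_identical_groups_give_p_one(self):
        res = cx.ttest_matrix(tiled_dataset([1, 2, 3], "a"),
                              tiled_dataset([1, 2, 3], "b"))
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_welch_flag_changes_degrees_of_freedom(self):
        a = tiled_dataset([1.0, 2.0, 3.0, 9.0], "a")
        b = tiled_dataset([4.0, 5.0, 6.0], "b")
        student = cx.ttest_matrix(a, b)["p_value"].iloc[0]
        welch = cx.ttest_matrix(a, b, welch=True)["p_value"].iloc[0]
        assert student != welch

    def test_fdr_column_is_monotone_in_p(self):
        rng = np.random.default_rng(0)
        a = dataset(random_descriptor_frame(rng, 6), ["a"] * 6)
        b = dataset(random_descriptor_frame(rng, 6, shift=0.5), ["b"] * 6)
        res = cx.ttest_matrix(a, b, fdr=True)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(TooFewSamplesError):
            cx.ttest_matrix(tiled_dataset([1.0], "a"), tiled_dataset([1, 2], "b"))


class TestFitPCA3:
    def test_rank_one_data_explains_everything_on_pc1(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(30)
        direction = rng.standard_normal(104)
        X = np.outer(t, direction)
        emb = cx.fit_pca3(dataset(
            pd.DataFrame(X, columns=cx.descriptor_names()), ["c"] * 30
        ))
        np.testing.assert_allclose(
            emb.explained_variance_fraction, [1.0, 0.0, 0.0], atol=1e-8
        )

    def test_loadings_orthonormal_and_scores_consistent(self):
        rng = np.random.default_rng(2)
        data = dataset(random_descriptor_frame(rng, 25), ["c"] * 25)
        emb = cx.fit_pca3(data)
        np.testing.assert_allclose(
            emb.loadings.T @ emb.loadings, np.eye(3), atol=1e-8
        )
        Z = (data.matrix - emb.center) / emb.scale
        np.testing.assert_allclose(emb.scores, Z @ emb.loadings, atol=1e-10)

    @pytest.mark.parametrize("n", [5, 20])
    def test_matches_eigendecomposition_oracle(self, n):
        rng = np.random.default_rng(3)
        data = dataset(random_descriptor_frame(rng, n), ["c"] * n)
        emb = cx.fit_pca3(data)
        ref_scores, ref_loadings, ref_evr = brute_pca_scores(data.matrix)
        np.testing.assert_allclose(emb.scores, ref_scores, atol=1e-8)
        np.testing.assert_allclose(emb.loadings, ref_loadings, atol=1e-8)
        np.testing.assert_allclose(
            emb.explained_variance_fraction, ref_evr, atol=1e-8
        )

    def test_zero_variance_columns_tolerated(self):
        rng = np.random.default_rng(4)
        frame = random_descriptor_frame(rng, 10)
        frame.iloc[:, :5] = 7.0
        emb = cx.fit_pca3(dataset(frame, ["c"] * 10))
        assert np.isfinite(emb.scores).all()

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(TooFewSamplesError):
            cx.fit_pca3(dataset(random_descriptor_frame(rng, 3), ["c"] * 3))


def shifted_cohorts(seed, n=30, gap=5.0):
    """Two descriptor cohorts separated along a fixed direction."""
    rng = np.random.default_rng(seed)
    direction = np.zeros(104)
    direction[:10] = gap / np.sqrt(10)
    open_f = random_descriptor_frame(rng, n, shift=direction)
    closed_f = random_descriptor_frame(rng, n, shift=-direction)
    return (
        dataset(open_f, ["open"] * n),
        dataset(closed_f, ["closed"] * n),
    )


class TestClassifier:
    def test_separable_cohorts_train_perfectly(self):
        open_set, closed_set = shifted_cohorts(seed=6)
        both = dataset(
            pd.concat([open_set.features, closed_set.features],
                      ignore_index=True),
            ["open"] * open_set.n + ["closed"] * closed_set.n,
        )
        emb = cx.fit_pca3(both)
        clf = cx.train_classifier(open_set, closed_set, emb, seed=0)
        assert (clf.predict(open_set) == "open").all()
        assert (clf.predict(closed_set) == "closed").all()

    def test_margin_sign_convention_open_positive(self):
        open_set, closed_set = shifted_cohorts(seed=7)
        both = dataset(
            pd.concat([open_set.features, closed_set.features],
                      ignore_index=True),
            ["open"] * open_set.n + ["closed"] * closed_set.n,
        )
        emb = cx.fit_pca3(both)
        clf = cx.train_classifier(open_set, closed_set, emb, seed=0)
        assert (clf.margin(open_set) > 0).all()
        assert (clf.margin(closed_set) < 0).all()

    def test_identical_cohorts_warn_degenerate(self):
        rng = np.random.default_rng(8)
        frame = random_descriptor_frame(rng, 10)
        a = dataset(frame, ["open"] * 10)
        b = dataset(frame.copy(), ["closed"] * 10)
        emb = cx.fit_pca3(dataset(
            pd.concat([frame, frame], ignore_index=True), ["c"] * 20
        ))
        with pytest.warns(DegenerateMarginWarning):
            cx.train_classifier(a, b, emb, seed=0)


class TestEvaluateClassifier:
    def test_confusion_arithmetic_perfect_and_degenerate(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        perfect = cx.sensitivity_specificity(y, y)
        assert (perfect["sensitivity"] == 1.0).all()
        assert (perfect["specificity"] == 1.0).all()
        all_b = cx.sensitivity_specificity(y, np.array(["b"] * 10))
        assert all_b.loc["b", "sensitivity"] == 1.0
        assert all_b.loc["b", "specificity"] == 0.0
        assert all_b.loc["a", "sensitivity"] == 0.0

    def test_separable_classes_cross_validate_perfectly(self):
        open_set, closed_set = shifted_cohorts(seed=9, n=20)
        data = dataset(
            pd.concat([open_set.features, closed_set.features],
                      ignore_index=True),
            ["open"] * 20 + ["closed"] * 20,
        )
        ev = cx.evaluate_classifier(data, seed=0)
        assert ev.macro_sensitivity == 1.0 and ev.macro_specificity == 1.0

    def test_permuted_labels_score_at_chance(self):
        """Random labels: accuracy inside the 95% binomial band around 0.5."""
        rng = np.random.default_rng(10)
        data = dataset(
            random_descriptor_frame(rng, 100),
            rng.permutation(["a"] * 50 + ["b"] * 50),
        )
        ev = cx.evaluate_classifier(data, seed=0)
        lo, hi = sps.binom.interval(0.95, 100, 0.5)
        assert lo / 100 <= ev.accuracy <= hi / 100

    def test_small_class_rejected(self):
        rng = np.random.default_rng(11)
        data = dataset(random_descriptor_frame(rng, 10),
                       ["a"] * 7 + ["b"] * 3)
        with pytest.raises(TooFewSamplesError):
            cx.evaluate_classifier(data)


class TestKMeans:
    def test_two_separated_clouds_recover_means(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.05, (40, 3)) + np.array([5.0, 0, 0])
        b = rng.normal(0, 0.05, (40, 3)) - np.array([5.0, 0, 0])
        scores = np.vstack([a, b])
        res = cx.kmeans_centroids(scores, k=2, seed=0)
        got = res.centroids[np.argsort(res.centroids[:, 0])]
        np.testing.assert_allclose(got[0], b.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(got[1], a.mean(axis=0), atol=1e-6)
        d = res.centroid_distances()
        assert d[0, 1] == pytest.approx(np.linalg.norm(got[1] - got[0]))

    def test_k_one_returns_global_mean(self):
        rng = np.random.default_rng(13)
        scores = rng.standard_normal((17, 3))
        res = cx.kmeans_centroids(scores, k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], scores.mean(axis=0),
                                   atol=1e-8)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(14)
        scores = rng.standard_normal((30, 3))
        r1 = cx.kmeans_centroids(scores, k=3, seed=5)
        r2 = cx.kmeans_centroids(scores, k=3, seed=5)
        np.testing.assert_array_equal(r1.centroids, r2.centroids)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(BadKError):
            cx.kmeans_centroids(np.zeros((3, 3)), k=4)


class TestPhenotypeParsingIndex:
    OPEN = np.array([2.0, 1.0, -1.0])
    CLOSED = np.array([-2.0, 0.0, 1.0])

    def test_references_map_to_extremes(self):
        assert cx.phenotype_parsing_index(self.OPEN, self.OPEN, self.CLOSED) == \
            pytest.approx(1.0)
        assert cx.phenotype_parsing_index(self.CLOSED, self.OPEN, self.CLOSED) == \
            pytest.approx(-1.0)

    def test_midpoint_maps_to_zero(self):
        mid = (self.OPEN + self.CLOSED) / 2
        assert cx.phenotype_parsing_index(mid, self.OPEN, self.CLOSED) == \
            pytest.approx(0.0)

    def test_strictly_increasing_along_axis(self):
        ts = np.linspace(0, 1, 9)
        values = [
            cx.phenotype_parsing_index(
                self.CLOSED + t * (self.OPEN - self.CLOSED),
                self.OPEN, self.CLOSED,
            )
            for t in ts
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_coordinate_mean_mode(self):
        assert cx.phenotype_parsing_index(
            np.array([1.0, 2.0, 3.0]), self.OPEN, self.CLOSED,
            mode="coordinate_mean",
        ) == pytest.approx(2.0)

    def test_coincident_references_rejected(self):
        with pytest.raises(DegenerateAxisError):
            cx.phenotype_parsing_index(self.OPEN, self.OPEN, self.OPEN)


class TestOpenChromatinIndex:
    def test_balanced_ratios(self):
        counts = cx.IEMCounts(10, 5, 4, 8)
        assert cx.open_chromatin_index(counts, log_scale=False) == \
            pytest.approx(1.0)
        assert cx.open_chromatin_index(counts) == pytest.approx(0.0)

    def test_equal_counts_map_to_zero(self):
        assert cx.open_chromatin_index(cx.IEMCounts(7, 7, 7, 7)) == \
            pytest.approx(0.0)

    def test_open_shifted_counts(self):
        counts = cx.IEMCounts(20, 5, 8, 4)
        assert cx.open_chromatin_index(counts, log_scale=False) == \
            pytest.approx(8.0)
        assert cx.open_chromatin_index(counts) == pytest.approx(3.0)

    def test_zero_denominator_rejected_unless_pseudocount(self):
        counts = cx.IEMCounts(10, 0, 4, 8)
        with pytest.raises(ZeroCountsError):
            cx.open_chromatin_index(counts)
        assert np.isfinite(cx.open_chromatin_index(counts, pseudocount=True))


class TestFRET:
    def test_pure_bleed_through_has_zero_efficiency(self):
        s = cx.FRETSample(A=100.0, B=0.3 * 100 + 0.2 * 50, C=50.0, b=0.3, c=0.2)
        assert cx.fret_efficiency(s) == pytest.approx(0.0)

    def test_full_transfer_unit_efficiency(self):
        s = cx.FRETSample(A=0.0, B=80.0, C=80.0, b=0.5, c=0.0)
        assert cx.fret_efficiency(s) == pytest.approx(1.0)

    def test_negative_corrected_signal_clipped(self):
        s = cx.FRETSample(A=100.0, B=10.0, C=50.0, b=0.5, c=0.5)
        assert cx.fret_efficiency(s) == 0.0

    def test_zero_acceptor_rejected(self):
        with pytest.raises(ZeroAcceptorError):
            cx.fret_efficiency(cx.FRETSample(A=1.0, B=1.0, C=0.0, b=0, c=0))


class TestNormalizeHeatmap:
    def test_min_max_and_constant_conventions(self):
        means = pd.DataFrame(
            {"d1": [1.0, 2.0, 3.0], "d2": [5.0, 5.0, 5.0], "d3": [9.0, 3.0, 6.0]},
            index=["c1", "c2", "c3"],
        )
        norm, rho = cx.normalize_heatmap(means)
        np.testing.assert_allclose(norm["d1"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(norm["d2"], 0.5)
        assert rho["d1"] == pytest.approx(1.0)
        assert rho["d2"] == 0.0

    def test_single_condition_rejected(self):
        with pytest.raises(TooFewConditionsError):
            cx.normalize_heatmap(pd.DataFrame({"d": [1.0]}))
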