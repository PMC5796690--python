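"""Population-level analyses: PCA, clustering, correlations, regression."""

import numpy as np
import pandas as pd
import pytest

from psfglm import (
    PSFFeatures,
    build_basis,
    cluster_psfs,
    cohens_d,
    generate_population,
    normalize_unit_power,
    pca_psfs,
    place_cell_fraction,
    regress_coherence,
    theta_features,
    timepoint_coherence_correlation,
)


@pytest.fixture(scope="module")
def psf_population(basis):
    """Ground-truth normalized PSF curves for an 80/20 bursty/refractory mix."""
    pop = generate_population(60, seed=31, duration=5.0)
    curves = np.vstack(
        [
            normalize_unit_power(basis.expand_smooth(c.psf_beta), basis.grid).values
            for c, _, _ in pop
        ]
    )
    labels = np.array([c.profile for c, _, _ in pop])
    return curves, labels


@pytest.fixture(scope="module")
def feature_table(basis):
    pop = generate_population(
        120, seed=33, duration=5.0,
        group_spec=[{"profile": "bursty", "fraction": 1.0}],
    )
    rows = [
        theta_features(
            normalize_unit_power(basis.expand_smooth(c.psf_beta), basis.grid)
        ).as_dict()
        for c, _, _ in pop
    ]
    return pd.DataFrame(rows)[list(PSFFeatures.FEATURE_NAMES)]


class TestPCA:
    def test_variance_fractions_sum_to_one(self, psf_population):
        curves, _ = psf_population
        res = pca_psfs(curves)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ten_coefficients_give_ten_components(self, rng):
        betas = rng.standard_normal((40, 10))
        res = pca_psfs(betas)
        assert res.components.shape[0] == 10
        assert np.all(res.variance_explained > 0)

    def test_first_component_separates_shape_families(self, basis):
        # two orthogonal bump families -> bimodal PC1 scores
        rng = np.random.default_rng(2)
        a = basis.matrix[:, 1]
        b = basis.matrix[:, 7]
        curves = np.vstack(
            [a * (1 + 0.05 * rng.standard_normal()) for _ in range(20)]
            + [b * (1 + 0.05 * rng.standard_normal()) for _ in range(20)]
        )
        res = pca_psfs(curves)
        s = res.scores[:, 0]
        assert (s[:20] > 0).all() != (s[20:] > 0).all()  # opposite signs

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pca_psfs(np.ones((10, 5)))
        with pytest.raises(ValueError):
            pca_psfs(np.ones((1, 5)))


class TestClustering:
    def test_ground_truth_labels_recovered(self, psf_population):
        curves, labels = psf_population
        res = cluster_psfs(curves, seed=0)
        assert np.mean(res.labels == labels) >= 0.95

    def test_duplication_invariance(self, psf_population):
        curves, _ = psf_population
        res1 = cluster_psfs(curves, seed=0)
        res2 = cluster_psfs(np.vstack([curves, curves]), seed=0)
        n = len(curves)
        assert np.array_equal(res2.labels[:n], res2.labels[n:])
        assert np.array_equal(res1.labels, res2.labels[:n])

    def test_within_exceeds_between_correlation(self, psf_population):
        curves, _ = psf_population
        res = cluster_psfs(curves, seed=0)
        assert res.within_correlation > res.between_correlation

    def test_bursty_cluster_has_higher_burstiness(self, psf_population):
        curves, _ = psf_population
        res = cluster_psfs(curves, seed=0)
        g = np.arange(31) * 1e-3
        b = np.trapezoid(curves[:, :31], g, axis=1)
        assert b[res.labels == "bursty"].mean() > b[res.labels == "refractory"].mean()

    def test_identical_psfs_degenerate(self):
        with pytest.raises(ValueError):
            cluster_psfs(np.tile(np.sin(np.arange(700)), (10, 1)))

    def test_rescaling_rows_leaves_partition(self, psf_population):
        curves, _ = psf_population
        rng = np.random.default_rng(3)
        scaled = curves * rng.uniform(0.5, 5.0, size=(len(curves), 1))
        res1 = cluster_psfs(curves, seed=0)
        res2 = cluster_psfs(scaled, seed=0, burstiness_values=None)
        assert np.array_equal(res1.assignments == res1.assignments[0],
                              res2.assignments == res2.assignments[0])


class TestTimepointCorrelation:
    def test_constructed_dependence_peaks_at_right_lag(self, psf_population):
        curves, _ = psf_population
        coherence = 2.0 * curves[:, 120] + 0.01 * np.random.default_rng(4).standard_normal(len(curves))
        r = timepoint_coherence_correlation(curves, coherence)
        assert abs(int(np.argmax(np.abs(r))) - 120) <= 15

    def test_shuffled_coherence_within_null_band(self, psf_population):
        curves, _ = psf_population
        rng = np.random.default_rng(5)
        coherence = 2.0 * curves[:, 120]
        maxima = []
        for _ in range(30):
            maxima.append(
                np.nanmax(np.abs(timepoint_coherence_correlation(
                    curves, rng.permutation(coherence)
                )))
            )
        observed = np.nanmax(np.abs(timepoint_coherence_correlation(curves, coherence)))
        assert observed > np.quantile(maxima, 0.99)
        # and the null maxima themselves are bounded well below 1
        assert np.median(maxima) < 0.6

    def test_degenerate_inputs_rejected(self, psf_population):
        curves, _ = psf_population
        with pytest.raises(ValueError):
            timepoint_coherence_correlation(curves, np.full(len(curves), 0.3))
        with pytest.raises(ValueError):
            timepoint_coherence_correlation(curves[:2], np.array([0.1, 0.2]))


class TestRegression:
    def test_noiseless_linear_gives_unit_r2(self, feature_table):
        w = np.arange(1, len(feature_table.columns) + 1, dtype=float)
        F = (feature_table - feature_table.mean()) / feature_table.std()
        y = F.to_numpy() @ w
        for interactions in (False, True):
            # the canonical feature set is structurally collinear
            # (depth = peak - trough), so the ridge fallback engages
            with pytest.warns(RuntimeWarning, match="ridge"):
                res = regress_coherence(feature_table, y, interactions=interactions)
            assert res.spearman_r2 == pytest.approx(1.0, abs=1e-6)
            assert res.pearson_r2 == pytest.approx(1.0, abs=1e-6)

    def test_independent_target_within_permutation_band(self, feature_table):
        rng = np.random.default_rng(6)
        r2s = [
            regress_coherence(
                feature_table, rng.standard_normal(len(feature_table)),
                interactions=False,
            ).spearman_r2
            for _ in range(20)
        ]
        # 7 noise predictors on n=120: in-sample r2 stays near p/n
        assert np.median(r2s) < 0.2

    def test_adding_predictors_never_hurts_in_sample(self, feature_table):
        rng = np.random.default_rng(7)
        y = feature_table["theta_depth"].to_numpy() + 0.5 * rng.standard_normal(
            len(feature_table)
        )
        main = regress_coherence(feature_table, y, interactions=False)
        full = regress_coherence(feature_table, y, interactions=True)
        assert full.pearson_r2 >= main.pearson_r2 - 1e-12

    def test_rank_deficient_design_ridge_stabilized(self):
        F = pd.DataFrame(
            {"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8], "c": [0.0, 1, 0, 1]}
        )
        with pytest.warns(RuntimeWarning, match="ridge"):
            res = regress_coherence(F, np.array([1.0, 2, 3, 4]), interactions=True)
        assert res.ridge_used is not None
        assert np.all(np.isfinite(res.predicted))


class TestEffectSizesAndFractions:
    def test_cohens_d_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_cohens_d_unit_separation(self):
        assert cohens_d([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_cohens_d_matches_formula(self, rng):
        a = rng.standard_normal(30) + 0.4
        b = rng.standard_normal(25)
        pooled = np.sqrt(
            ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
            / (len(a) + len(b) - 2)
        )
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_cohens_d_needs_two_observations(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])

    def test_place_cell_fraction_inclusive_threshold(self):
        res = place_cell_fraction(np.array([0.29, 0.30, 0.31]))
        assert res["all"] == pytest.approx(2 / 3)

    def test_place_cell_fraction_by_group(self):
        coh = np.array([0.5, 0.5, 0.1, 0.5])
        groups = np.array(["ctl", "ctl", "mam", "mam"])
        res = place_cell_fraction(coh, groups)
        assert res == {"ctl": 1.0, "mam": 0.5}
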