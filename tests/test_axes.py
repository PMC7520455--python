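import numpy as np
import pandas as pd
import pytest

from tetrachroma.axes import (
    aggregate_scores,
    coefficient_of_variation,
    ChromaticAxis,
    pca_axis,
    spherical_scores,
    spherical_to_xyz,
)


class TestPcaAxis:
    def test_collinear_cloud_gives_full_pc1(self):
        t = np.linspace(-2, 2, 50)
        X = np.outer(t, [1.0, 2.0, 2.0])
        rep = pca_axis(X)
        assert rep.pc_variance_fractions[0] == pytest.approx(1.0)
        assert rep.degenerate

    def test_isotropic_cloud_equal_fractions(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10_000, 3))
        rep = pca_axis(X)
        assert np.allclose(rep.pc_variance_fractions, 1 / 3, atol=0.02)

    def test_planted_axis_closed_form(self):
        # cov = sa^2 v v' + sn^2 I -> PC1 fraction (sa^2+sn^2)/(sa^2+3 sn^2)
        rng = np.random.default_rng(1)
        sa, sn = 2.0, 0.5
        v = np.array([0.0, 0.6, 0.8])
        X = rng.normal(0, sa, (10_000, 1)) * v + rng.normal(0, sn, (10_000, 3))
        rep = pca_axis(X)
        expected = (sa**2 + sn**2) / (sa**2 + 3 * sn**2)
        assert rep.pc_variance_fractions[0] == pytest.approx(expected, rel=0.02)
        assert abs(np.dot(rep.pc1_loadings, v)) > 0.99

    def test_sign_convention_nonnegative_z(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (200, 1)) * np.array([0.1, 0.2, -0.97])
        rep = pca_axis(X + rng.normal(0, 0.01, (200, 3)))
        assert rep.pc1_loadings[2] >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pca_axis(np.zeros((2, 3)))

    def test_estimator_api(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        est = ChromaticAxis().fit(X)
        assert est.variance_fractions_.sum() == pytest.approx(1.0)
        proj = est.transform(X)
        assert proj.shape == (100, 3)
        # projection onto PC1 has the largest variance
        assert proj[:, 0].var() == pytest.approx(X.var(axis=0).sum() * est.variance_fractions_[0], rel=0.05)


class TestSphericalScores:
    @pytest.mark.parametrize(
        "xyz,phi",
        [((0, 0, 1), np.pi / 2), ((1, 0, 0), 0.0), ((0, 1, -1), -np.pi / 4)],
    )
    def test_elevation_examples(self, xyz, phi):
        out = spherical_scores(np.array([xyz], dtype=float))
        assert out.loc[0, "phi"] == pytest.approx(phi)

    def test_origin_has_no_hue(self):
        out = spherical_scores(np.zeros((1, 3)))
        assert np.isnan(out.loc[0, "phi"]) and np.isnan(out.loc[0, "theta"])
        assert out.loc[0, "r_jnd"] == 0

    def test_roundtrip_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 3, (50, 3))
        sc = spherical_scores(X)
        back = spherical_to_xyz(sc["phi"], sc["theta"], sc["r_jnd"])
        assert np.abs(back - X).max() < 1e-10

    def test_opposite_points_have_opposite_phi(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 2, (20, 3))
        a = spherical_scores(X)["phi"].to_numpy()
        b = spherical_scores(-X)["phi"].to_numpy()
        assert np.allclose(a, -b)


def _scores_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["species", "sex", "region", "specimen_id", "phi", "luminance"],
    )


class TestAggregateScores:
    def test_simple_mean_within_specimen(self):
        df = _scores_frame(
            [
                ("Sp1", "M", "crown", "s1", 0.2, 0.5),
                ("Sp1", "M", "crown", "s1", 0.4, 0.7),
            ]
        )
        ds = aggregate_scores(df)
        assert ds.color.loc["Sp1", "crown"] == pytest.approx(0.3)
        assert ds.luminance.loc["Sp1", "crown"] == pytest.approx(0.6)
        assert ds.counts.loc["Sp1", "crown"] == 2

    def test_specimen_first_averaging(self):
        # specimen s1 heavily sampled; species mean must weight specimens
        # equally: mean(mean(0.0, 0.0, 0.0), 0.6) = 0.3, not patch mean 0.15
        df = _scores_frame(
            [
                ("Sp1", "M", "wing", "s1", 0.0, 0.1),
                ("Sp1", "M", "wing", "s1", 0.0, 0.1),
                ("Sp1", "M", "wing", "s1", 0.0, 0.1),
                ("Sp1", "M", "wing", "s2", 0.6, 0.5),
            ]
        )
        ds = aggregate_scores(df)
        assert ds.color.loc["Sp1", "wing"] == pytest.approx(0.3)

    def test_unmeasured_region_stays_missing(self):
        df = _scores_frame(
            [
                ("Sp1", "M", "crown", "s1", 0.2, 0.5),
                ("Sp2", "M", "wing", "s1", 0.1, 0.4),
            ]
        )
        ds = aggregate_scores(df)
        assert np.isnan(ds.color.loc["Sp1", "wing"])
        assert ds.counts.loc["Sp1", "wing"] == 0

    def test_male_only_drops_female_only_species_with_warning(self):
        df = _scores_frame(
            [
                ("Sp1", "M", "crown", "s1", 0.2, 0.5),
                ("Sp2", "F", "crown", "s2", 0.1, 0.4),
            ]
        )
        with pytest.warns(UserWarning, match="Sp2"):
            ds = aggregate_scores(df, sex_filter="male_only")
        assert list(ds.color.index) == ["Sp1"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"Sp{i%4}", "M", r, f"s{i%3}", rng.normal(), rng.uniform())
            for i, r in enumerate(["crown", "wing", "tail"] * 8)
        ]
        df = _scores_frame(rows)
        a = aggregate_scores(df)
        b = aggregate_scores(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a.color, b.color)

    def test_black_patches_count_for_luminance_not_color(self):
        df = _scores_frame(
            [
                ("Sp1", "M", "crown", "s1", np.nan, 0.0),
                ("Sp1", "M", "crown", "s1", 0.5, 0.8),
            ]
        )
        ds = aggregate_scores(df)
        assert ds.color.loc["Sp1", "crown"] == pytest.approx(0.5)
        assert ds.luminance.loc["Sp1", "crown"] == pytest.approx(0.4)


class TestCoefficientOfVariation:
    def _dataset(self, values):
        df = _scores_frame(
            [(f"Sp{i}", "M", "crown", "s1", v, abs(v)) for i, v in enumerate(values)]
        )
        return aggregate_scores(df)

    def test_constant_column_zero_cv(self):
        res = coefficient_of_variation(self._dataset([1.0, 1.0, 1.0]), "color", "crown")
        assert res.cv == 0.0 and not res.zero_mean

    def test_hand_computed_value(self):
        res = coefficient_of_variation(self._dataset([1.0, 2.0, 3.0]), "color", "crown")
        assert res.cv == pytest.approx(0.5)

    def test_zero_mean_flagged_missing(self):
        res = coefficient_of_variation(self._dataset([-1.0, 1.0]), "color", "crown")
        assert np.isnan(res.cv) and res.zero_mean
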