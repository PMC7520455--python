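import numpy as np
import pandas as pd
import pytest

from tetrachroma.phylo import bm_covariance
from tetrachroma.spectra import CANONICAL_GRID
from tetrachroma.synth import (
    BLACK,
    WHITE,
    SpectrumTemplate,
    SyntheticCladeSpec,
    make_spectrum,
    simulate_bm_traits,
    simulate_clade,
    simulate_tree,
)


class TestTemplates:
    def test_white_is_identically_plateau(self):
        s = make_spectrum(SpectrumTemplate("flat_high", plateau=1.0))
        assert np.all(s.reflectance == 1.0)

    def test_black_with_zero_baseline_is_zero(self):
        s = make_spectrum(SpectrumTemplate("near_zero", baseline=0.0, plateau=0.0))
        assert np.all(s.reflectance == 0.0)

    def test_sigmoid_hits_plateau_and_baseline(self):
        # logistic with scale 30: 150 nm from the inflection is > 99% of the rise
        t = SpectrumTemplate("long_pass_sigmoid", 550.0, 30.0, plateau=0.9, baseline=0.0)
        s = make_spectrum(t)
        r700 = s.reflectance[s.wavelengths == 700][0]
        r400 = s.reflectance[s.wavelengths == 400][0]
        assert r700 == pytest.approx(0.9, rel=0.01)
        assert r400 == pytest.approx(0.0, abs=0.01 * 0.9)

    def test_long_pass_monotone_and_gaussian_unimodal(self):
        lp = make_spectrum(SpectrumTemplate("long_pass_sigmoid", 520, 40, 0.8, 0.05))
        assert np.all(np.diff(lp.reflectance) >= 0)
        g = make_spectrum(SpectrumTemplate("short_wave_gaussian", 430, 50, 0.7, 0.05))
        peak = np.argmax(g.reflectance)
        assert np.all(np.diff(g.reflectance[: peak + 1]) >= 0)
        assert np.all(np.diff(g.reflectance[peak:]) <= 0)

    def test_noise_stays_physical_and_deterministic(self):
        t = SpectrumTemplate("flat_high", plateau=0.95)
        a = make_spectrum(t, seed=3, noise_sd=0.2)
        b = make_spectrum(t, seed=3, noise_sd=0.2)
        c = make_spectrum(t, seed=4, noise_sd=0.2)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert not np.array_equal(a.reflectance, c.reflectance)
        assert a.reflectance.min() >= 0 and a.reflectance.max() <= 1

    def test_grid_outside_supported_range_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum(WHITE, grid=np.arange(250.0, 701.0))
        with pytest.raises(ValueError):
            SpectrumTemplate("mystery")


class TestSimulateClade:
    def test_redistributed_plants_both_classes_everywhere(self):
        sim = simulate_clade(SyntheticCladeSpec(n_species=20, seed=1))
        cls = sim.metadata.groupby("species")["true_class"].agg(set)
        assert all({"long", "short"} <= s for s in cls)

    def test_one_sided_has_single_chromatic_class(self):
        sim = simulate_clade(
            SyntheticCladeSpec(n_species=10, seed=2, assignment_model="one_sided")
        )
        chromatic = sim.metadata.loc[
            sim.metadata["true_class"].isin(["long", "short"]), "true_class"
        ]
        assert set(chromatic) == {"long"}

    def test_same_seed_byte_identical(self):
        a = simulate_clade(SyntheticCladeSpec(n_species=6, seed=9))
        b = simulate_clade(SyntheticCladeSpec(n_species=6, seed=9))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        for pa, pb in zip(a.patches, b.patches):
            assert np.array_equal(pa.spectrum.reflectance, pb.spectrum.reflectance)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticCladeSpec(n_species=2)
        with pytest.raises(ValueError):
            SyntheticCladeSpec(assignment_model="mixed")

    def test_black_patches_are_flagged(self):
        sim = simulate_clade(SyntheticCladeSpec(n_species=10, seed=3))
        blacks = sim.metadata.loc[sim.metadata["true_class"] == "black", "patch_id"]
        by_id = {p.patch_id: p for p in sim.patches}
        assert all(by_id[pid].is_black for pid in blacks)


class TestSimulateTree:
    def test_binary_node_count(self):
        for n in (3, 8, 17):
            tree = simulate_tree(n, seed=0)
            assert len(tree.leaf_nodes()) == n
            assert len(tree.nodes()) == 2 * n - 1

    def test_ultrametric_positive_branches(self):
        tree = simulate_tree(12, seed=5)
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = [l.root_distance for l in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9
        assert all(
            e.length > 0 for e in tree.preorder_edge_iter() if e.length is not None
        )

    def test_deterministic_newick(self):
        a = simulate_tree(10, seed=4).as_string(schema="newick")
        b = simulate_tree(10, seed=4).as_string(schema="newick")
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2)


class TestSimulateBMTraits:
    def test_lambda_zero_gives_iid_with_depth_variance(self):
        tree = simulate_tree(10, seed=1)
        C = bm_covariance(tree)
        depth = float(C.to_numpy()[0, 0])
        ys = np.stack(
            [
                simulate_bm_traits(tree, sigma2=2.0, lambda_true=0.0, seed=i).to_numpy()
                for i in range(3000)
            ]
        )
        cov = np.cov(ys, rowvar=False)
        assert np.allclose(np.diag(cov), 2.0 * depth, rtol=0.15)
        off = cov[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.15 * 2.0 * depth

    def test_lambda_one_recovers_bm_covariance(self):
        # Monte-Carlo covariance over >= 2000 replicates approaches C
        tree = simulate_tree(6, seed=2)
        C = bm_covariance(tree).to_numpy()
        ys = np.stack(
            [
                simulate_bm_traits(tree, sigma2=1.0, lambda_true=1.0, seed=i).to_numpy()
                for i in range(4000)
            ]
        )
        cov = np.cov(ys, rowvar=False)
        assert np.abs(cov - C).max() < 0.12 * C.max()

    def test_deterministic_and_validated(self):
        tree = simulate_tree(5, seed=3)
        a = simulate_bm_traits(tree, seed=1)
        b = simulate_bm_traits(tree, seed=1)
        pd.testing.assert_series_equal(a, b)
        with pytest.raises(ValueError):
            simulate_bm_traits(tree, sigma2=0.0)
        with pytest.raises(ValueError):
            simulate_bm_traits(tree, lambda_true=1.5)
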