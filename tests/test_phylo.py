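import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest

from tetrachroma.phylo import (
    MantelTest,
    PagelsLambda,
    bm_covariance,
    mantel,
    pagels_lambda,
    phylo_distance_matrix,
    signal_table,
    trait_distance_matrix,
)
from tetrachroma.axes import aggregate_scores
from tetrachroma.synth import simulate_bm_traits, simulate_tree


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBmCovariance:
    def test_three_tip_bookkeeping(self):
        C = bm_covariance(_tree("((A:1,B:1):1,C:2);"))
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)
        assert np.allclose(np.diag(C), 2.0)

    def test_star_tree_diagonal(self):
        C = bm_covariance(_tree("(A:3,B:3,C:3,D:3);"))
        assert np.allclose(C.to_numpy(), 3.0 * np.eye(4))

    def test_ultrametric_constant_diagonal(self):
        C = bm_covariance(simulate_tree(10, seed=2))
        assert np.ptp(np.diag(C)) < 1e-9

    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="Ghost"):
            bm_covariance(_tree("((A:1,B:1):1,C:2);"), ["A", "Ghost"])

    def test_pruning_matches_subsetting(self):
        tree = simulate_tree(8, seed=3)
        full = bm_covariance(tree)
        sub = bm_covariance(tree, ["Species_02", "Species_05", "Species_07", "Species_01"])
        assert np.allclose(
            sub.to_numpy(), full.loc[sub.index, sub.columns].to_numpy()
        )


class TestPagelsLambda:
    def test_lambda_zero_reduces_to_iid_likelihood(self):
        tree = simulate_tree(12, seed=4)
        y = simulate_bm_traits(tree, seed=0)
        C = bm_covariance(tree)
        res = pagels_lambda(y, C, n_rand=0)
        # independent iid-normal log likelihood with the GLS-profiled
        # mean/variance, evaluated at lambda = 0 (diagonal covariance)
        yv = y.loc[C.index].to_numpy()
        d = np.diag(C.to_numpy())
        mu = np.sum(yv / d) / np.sum(1 / d)
        sig2 = np.mean((yv - mu) ** 2 / d)
        ll0 = -0.5 * (
            len(yv) * np.log(2 * np.pi * sig2) + np.sum(np.log(d)) + len(yv)
        )
        from tetrachroma.phylo import _lambda_loglik

        assert _lambda_loglik(0.0, yv, C.to_numpy()) == pytest.approx(ll0, abs=1e-6)
        assert res.loglik >= ll0 - 1e-9

    def test_recovery_and_destruction(self):
        tree = simulate_tree(48, seed=5)
        C = bm_covariance(tree)
        rng = np.random.default_rng(0)
        lams, shuf = [], []
        for i in range(12):
            y = simulate_bm_traits(tree, lambda_true=1.0, seed=300 + i)
            lams.append(pagels_lambda(y, C, n_rand=0).lambda_hat)
            ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            shuf.append(pagels_lambda(ys, C, n_rand=0).lambda_hat)
        assert np.median(lams) >= 0.9
        assert np.median(shuf) <= 0.1

    def test_affine_invariance(self):
        tree = simulate_tree(16, seed=6)
        y = simulate_bm_traits(tree, seed=1)
        a = pagels_lambda(y, tree, n_rand=0).lambda_hat
        b = pagels_lambda(3.0 * y + 11.0, tree, n_rand=0).lambda_hat
        assert a == pytest.approx(b, abs=1e-4)

    def test_randomization_seed_determinism(self):
        tree = simulate_tree(16, seed=7)
        y = simulate_bm_traits(tree, seed=2)
        r1 = pagels_lambda(y, tree, n_rand=49, seed=5)
        r2 = pagels_lambda(y, tree, n_rand=49, seed=5)
        assert r1.p_randomization == r2.p_randomization

    def test_star_tree_unidentifiable(self):
        res = pagels_lambda(
            pd.Series([1.0, 2.0, 0.5, 1.5], index=list("ABCD")),
            _tree("(A:3,B:3,C:3,D:3);"),
            n_rand=0,
        )
        assert res.unidentifiable

    def test_zero_variance_flagged(self):
        tree = simulate_tree(5, seed=8)
        y = pd.Series(1.0, index=[f"Species_{i:02d}" for i in range(1, 6)])
        assert pagels_lambda(y, tree, n_rand=0).zero_variance

    def test_matches_phytools_oracle(self, tmp_path):
        # independent implementation: R phytools::phylosig on a frozen fixture
        tree = simulate_tree(24, seed=42)
        y = simulate_bm_traits(tree, lambda_true=0.7, seed=9)
        tree.write(
            path=str(tmp_path / "t.nwk"), schema="newick",
            suppress_rooting=True, unquoted_underscores=True,
        )
        y.to_csv(tmp_path / "y.csv")
        ours = pagels_lambda(y, tree, n_rand=0)
        rscript = textwrap.dedent(
            """
            suppressMessages(library(phytools))
            tree <- read.tree("t.nwk")
            d <- read.csv("y.csv"); y <- setNames(d[[2]], d[[1]])
            r <- phylosig(tree, y, method="lambda")
            cat(sprintf("%.8f %.8f", r$lambda, r$logL))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], cwd=tmp_path, capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        lam_r, ll_r = map(float, out.stdout.split())
        assert ours.lambda_hat == pytest.approx(lam_r, abs=5e-3)
        assert ours.loglik == pytest.approx(ll_r, abs=1e-4)

    def test_estimator_api(self):
        tree = simulate_tree(10, seed=9)
        y = simulate_bm_traits(tree, seed=3)
        est = PagelsLambda(n_rand=19, seed=1).fit(y, tree=tree)
        assert 0.0 <= est.lambda_ <= 1.5
        assert est.p_randomization_ is not None
        assert est.get_params()["n_rand"] == 19


class TestMantel:
    def test_perfect_correlation(self):
        tree = simulate_tree(10, seed=10)
        D = phylo_distance_matrix(tree, [f"Species_{i:02d}" for i in range(1, 11)])
        res = mantel(D.to_numpy(), D.to_numpy(), n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_permutation == pytest.approx(1 / 200)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(3)
        n = 12
        A = rng.uniform(0, 1, (n, n)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = A + rng.uniform(0, 0.3, (n, n)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        ours = mantel(A, B, n_perm=0)
        r_sk = sk_mantel(DistanceMatrix(A), DistanceMatrix(B), permutations=0)[0]
        assert ours.r == pytest.approx(float(r_sk), abs=1e-10)

    def test_joint_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        n = 10
        A = rng.uniform(0, 1, (n, n)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.uniform(0, 1, (n, n)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        perm = rng.permutation(n)
        a = mantel(A, B, n_perm=0).r
        b = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=0).r
        assert a == pytest.approx(b)

    def test_constant_matrix_degenerate(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        B = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        assert mantel(A, B, n_perm=9).degenerate

    def test_estimator_api(self):
        rng = np.random.default_rng(5)
        n = 8
        A = rng.uniform(0, 1, (n, n)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        est = MantelTest(n_perm=99, seed=0).fit(A, A)
        assert est.r_ == pytest.approx(1.0)


class TestSignalTable:
    def _dataset(self, tree, lambda_true=1.0, seed=0):
        rows = []
        for r_i, region in enumerate(["crown", "wing", "tail"]):
            y = simulate_bm_traits(tree, lambda_true=lambda_true, seed=seed + r_i)
            for sp, v in y.items():
                rows.append(
                    {"species": sp, "sex": "M", "region": region,
                     "specimen_id": f"{sp}_s1", "phi": v, "luminance": abs(v) + 1}
                )
        return aggregate_scores(pd.DataFrame(rows))

    def test_bm_dataset_recovers_high_lambda(self):
        tree = simulate_tree(32, seed=11)
        ds = self._dataset(tree, lambda_true=1.0)
        tab = signal_table(ds, tree, n_rand=49, n_perm=99, seed=1)
        color = tab[tab.trait == "color"]
        assert len(color) == 3
        assert color["lambda_hat"].median() >= 0.9

    def test_identical_regions_identical_rows(self):
        tree = simulate_tree(16, seed=12)
        y = simulate_bm_traits(tree, seed=4)
        rows = []
        for region in ["crown", "wing"]:
            for sp, v in y.items():
                rows.append(
                    {"species": sp, "sex": "M", "region": region,
                     "specimen_id": f"{sp}_s1", "phi": v, "luminance": 0.5 + abs(v) / 10}
                )
        ds = aggregate_scores(pd.DataFrame(rows))
        tab = signal_table(ds, tree, n_rand=19, n_perm=49, seed=3)
        color = tab[tab.trait == "color"].set_index("region")
        assert color.loc["crown", "lambda_hat"] == pytest.approx(color.loc["wing", "lambda_hat"])
        assert color.loc["crown", "mantel_r"] == pytest.approx(color.loc["wing", "mantel_r"])

    def test_sparse_region_flagged_insufficient(self):
        tree = simulate_tree(8, seed=13)
        ds = self._dataset(tree, seed=2)
        ds.color.loc[ds.color.index[3:], "tail"] = np.nan
        ds.luminance.loc[ds.luminance.index[3:], "tail"] = np.nan
        tab = signal_table(ds, tree, n_rand=9, n_perm=9, seed=0)
        flagged = tab[(tab.region == "tail")]
        assert (flagged["flag"] == "insufficient").all()
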