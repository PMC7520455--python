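"""Phylogenetic signal in region-wise color and luminance scores.

Two complementary analyses quantify whether related species have similar
scores:

* **Pagel's lambda** — a multiplier on the off-diagonal of the Brownian-motion
  covariance C (C[i,j] = shared root-to-MRCA path length).  lambda = 1 matches
  Brownian evolution on the tree, lambda = 0 means no phylogenetic signal.
  The mean and rate are profiled out by GLS and lambda fit by bounded
  maximum likelihood; significance comes from refitting on tip-label
  permutations (randomization p), with a likelihood-ratio test against
  lambda = 0 as a cross-check.

* **Mantel correlation** — Pearson correlation between the off-diagonal
  entries of a trait distance matrix (|mean_i - mean_j| per region) and the
  patristic phylogenetic distance matrix, with a one-tailed permutation p.

Trees are Newick with branch lengths; tip labels are normalized (stripped,
spaces -> underscores) before matching to species names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .axes import CladeDataset, coefficient_of_variation

__all__ = [
    "LambdaResult",
    "MantelResult",
    "normalize_label",
    "read_tree",
    "bm_covariance",
    "lambda_max_bound",
    "pagels_lambda",
    "mantel",
    "phylo_distance_matrix",
    "trait_distance_matrix",
    "signal_table",
    "PagelsLambda",
    "MantelTest",
]


@dataclass(frozen=True)
class LambdaResult:
    """Maximum-likelihood Pagel's lambda with randomization significance."""

    lambda_hat: float
    loglik: float
    p_randomization: float | None
    n_randomizations: int
    lr_stat: float  # 2 * (loglik - loglik at lambda = 0)
    lr_p: float  # chi-square(1) upper tail, conservative cross-check
    n_species: int
    unidentifiable: bool = False  # star phylogeny: lambda has no effect
    zero_variance: bool = False


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix correlation with permutation significance."""

    r: float
    p_permutation: float | None
    n_permutations: int
    n_species: int
    degenerate: bool = False  # a matrix was constant; r undefined


def normalize_label(label: str) -> str:
    return str(label).strip().replace(" ", "_")


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    _sanitize_branch_lengths(tree)
    return tree


def _sanitize_branch_lengths(tree: dendropy.Tree) -> None:
    """Replace missing/zero internal branch lengths (tiny perturbation)."""
    touched = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < 0:
            raise ValueError("tree has missing or negative branch lengths")
        if edge.length == 0:
            edge.length = 1e-8
            touched = True
    if touched:
        warnings.warn("zero-length branches perturbed by 1e-8", stacklevel=3)


def bm_covariance(tree: dendropy.Tree, species=None) -> pd.DataFrame:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    C[i,i] is the root-to-tip depth; C[i,j] the depth of the most recent
    common ancestor, computed as (d_i + d_j - patristic_ij) / 2.  If
    ``species`` is given the tree is pruned to those tips; species absent
    from the tree raise with the offending names listed.
    """
    tree = tree.clone(depth=1)
    tips = {normalize_label(t.label): t for t in tree.taxon_namespace}
    if species is not None:
        species = [normalize_label(s) for s in species]
        missing = sorted(set(species) - set(tips))
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        keep = [tips[s] for s in species]
        tree.retain_taxa(keep)
        labels = list(species)
    else:
        labels = sorted(tips)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[normalize_label(leaf.taxon.label)] = leaf.root_distance
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {normalize_label(t.label): t for t in tree.taxon_namespace if t in {l.taxon for l in tree.leaf_node_iter()}}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return pd.DataFrame(C, index=labels, columns=labels)


def lambda_max_bound(C: np.ndarray) -> float:
    """Largest lambda keeping the transformed covariance well-conditioned.

    For ultrametric trees this is max depth over max shared path (>= 1);
    never below 1.
    """
    off = C[~np.eye(C.shape[0], dtype=bool)]
    if off.size == 0 or off.max() <= 0:
        return 1.0
    return float(max(1.0, np.min(np.diag(C)) / off.max()))


def _lambda_loglik(lam: float, y: np.ndarray, C: np.ndarray) -> float:
    n = y.size
    Cl = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    # near-duplicate tips on deep trees make C numerically semidefinite
    Cl = Cl + (1e-10 * np.max(np.diag(Cl))) * np.eye(n)
    try:
        cf = linalg.cho_factor(Cl, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    one = np.ones(n)
    iCy = linalg.cho_solve(cf, y, check_finite=False)
    iC1 = linalg.cho_solve(cf, one, check_finite=False)
    mu = one @ iCy / (one @ iC1)
    resid = y - mu
    sig2 = resid @ linalg.cho_solve(cf, resid, check_finite=False) / n
    if sig2 <= 0:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * np.log(2.0 * np.pi * sig2) + logdet + n))


def _fit_lambda(y: np.ndarray, C: np.ndarray, upper: float) -> tuple[float, float]:
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, y, C),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat, ll = float(res.x), float(-res.fun)
    # the bounded optimizer never evaluates the exact endpoints; snap if better
    for edge in (0.0, upper):
        ll_edge = _lambda_loglik(edge, y, C)
        if ll_edge > ll:
            lam_hat, ll = edge, ll_edge
    return lam_hat, ll


def pagels_lambda(
    trait,
    tree: dendropy.Tree | pd.DataFrame,
    n_rand: int = 1000,
    seed: int | None = None,
) -> LambdaResult:
    """ML estimate of Pagel's lambda for one trait vector.

    Parameters
    ----------
    trait : Series (indexed by species) or mapping
        Missing species are pruned.  Needs >= 4 species.
    tree : dendropy.Tree or precomputed BM covariance DataFrame
    n_rand : int
        Tip-label permutations for the randomization p-value
        (p = (1 + #{permuted lambda_hat >= observed}) / (n_rand + 1));
        0 skips it.
    seed : int
        Seeds the permutation stream.
    """
    y = pd.Series(trait).dropna()
    y.index = [normalize_label(s) for s in y.index]
    if len(y) < 4:
        raise ValueError("need >= 4 species with non-missing trait values")
    C_df = tree if isinstance(tree, pd.DataFrame) else bm_covariance(tree, list(y.index))
    C_df = C_df.loc[y.index, y.index]
    C = C_df.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = yv.size
    if np.ptp(yv) == 0:
        return LambdaResult(np.nan, np.nan, None, 0, np.nan, np.nan, n, zero_variance=True)
    offmax = C[~np.eye(n, dtype=bool)].max()
    if offmax <= 1e-12 * np.diag(C).max():
        # star phylogeny: off-diagonal zero, lambda cannot move the likelihood
        ll0 = _lambda_loglik(0.0, yv, C)
        return LambdaResult(np.nan, ll0, None, 0, 0.0, 1.0, n, unidentifiable=True)
    upper = lambda_max_bound(C)
    lam_hat, ll = _fit_lambda(yv, C, upper)
    ll0 = _lambda_loglik(0.0, yv, C)
    lr = max(0.0, 2.0 * (ll - ll0))
    lr_p = float(stats.chi2.sf(lr, df=1))
    p_rand = None
    if n_rand > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_rand):
            perm = rng.permutation(n)
            lam_p, _ = _fit_lambda(yv[perm], C, upper)
            if lam_p >= lam_hat:
                hits += 1
        p_rand = (1 + hits) / (n_rand + 1)
    return LambdaResult(
        lambda_hat=lam_hat,
        loglik=ll,
        p_randomization=p_rand,
        n_randomizations=n_rand,
        lr_stat=lr,
        lr_p=lr_p,
        n_species=n,
    )


def _offdiag(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(D, k=1)
    return D[iu]


def mantel(
    dist_trait,
    dist_phylo,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices.

    r is the Pearson correlation over the upper off-diagonal triangle; the
    permutation p simultaneously permutes rows and columns of the trait
    matrix (one-tailed 'greater' by default, as the hypothesis is that
    related species are similar).
    """
    D1 = np.asarray(dist_trait, dtype=float)
    D2 = np.asarray(dist_phylo, dtype=float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise ValueError("distance matrices must be square and equal shape")
    for D in (D1, D2):
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValueError("distance matrices must have zero diagonal")
    n = D1.shape[0]
    if n < 4:
        raise ValueError("need >= 4 species for a Mantel test")
    v1, v2 = _offdiag(D1), _offdiag(D2)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return MantelResult(np.nan, None, 0, n, degenerate=True)
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r_p = np.corrcoef(_offdiag(D1[np.ix_(perm, perm)]), v2)[0, 1]
            if alternative == "greater":
                extreme = r_p >= r_obs
            elif alternative == "less":
                extreme = r_p <= r_obs
            else:
                extreme = abs(r_p) >= abs(r_obs)
            if extreme:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p_permutation=p, n_permutations=n_perm, n_species=n)


def phylo_distance_matrix(tree: dendropy.Tree, species) -> pd.DataFrame:
    """Patristic distance matrix for the given species (tree pruned)."""
    C = bm_covariance(tree, species)
    d = np.diag(C.to_numpy())
    D = d[:, None] + d[None, :] - 2.0 * C.to_numpy()
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=C.index, columns=C.columns)


def trait_distance_matrix(values: pd.Series) -> pd.DataFrame:
    """|mean_i - mean_j| pairwise trait distances."""
    v = values.to_numpy(dtype=float)
    D = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(D, index=values.index, columns=values.index)


def signal_table(
    dataset: CladeDataset,
    tree: dendropy.Tree,
    n_rand: int = 1000,
    n_perm: int = 999,
    seed: int | None = None,
    min_species: int = 4,
) -> pd.DataFrame:
    """Per-region lambda + Mantel summary for color and luminance scores.

    One row per (region, trait) with lambda_hat, randomization p, Mantel r
    and p, the across-species CV, and the species count.  Regions with too
    few species are flagged ``insufficient`` instead of fitted.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for trait in ("color", "luminance"):
        mat = dataset.color if trait == "color" else dataset.luminance
        mat = mat.copy()
        mat.index = [normalize_label(s) for s in mat.index]
        for region in mat.columns:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            vals = mat[region].dropna()
            row = {"region": region, "trait": trait, "n_species": len(vals)}
            if len(vals) < min_species:
                row.update(
                    lambda_hat=np.nan, p_lambda=np.nan, mantel_r=np.nan,
                    p_mantel=np.nan, cv=np.nan, flag="insufficient",
                )
                rows.append(row)
                continue
            lam = pagels_lambda(vals, tree, n_rand=n_rand, seed=sub_seed)
            Dp = phylo_distance_matrix(tree, list(vals.index))
            Dt = trait_distance_matrix(vals.loc[Dp.index])
            mt = mantel(Dt.to_numpy(), Dp.to_numpy(), n_perm=n_perm, seed=sub_seed)
            try:
                cv = coefficient_of_variation(dataset, trait, region).cv
            except ValueError:
                cv = np.nan
            flag = ""
            if lam.unidentifiable:
                flag = "lambda_unidentifiable"
            elif lam.zero_variance:
                flag = "zero_trait_variance"
            if mt.degenerate:
                flag = (flag + ";" if flag else "") + "mantel_degenerate"
            row.update(
                lambda_hat=lam.lambda_hat,
                p_lambda=lam.p_randomization,
                lr_p=lam.lr_p,
                mantel_r=mt.r,
                p_mantel=mt.p_permutation,
                cv=cv,
                flag=flag,
            )
            rows.append(row)
    return pd.DataFrame(rows)


class PagelsLambda(BaseEstimator):
    """sklearn-style estimator for Pagel's lambda.

    ``fit(trait, tree)`` stores ``lambda_``, ``loglik_``,
    ``p_randomization_``, ``lr_p_`` and the full ``result_``.
    """

    def __init__(self, n_rand: int = 1000, seed: int | None = None):
        self.n_rand = n_rand
        self.seed = seed

    def fit(self, X, y=None, *, tree=None):
        if tree is None:
            raise ValueError("PagelsLambda.fit requires tree=")
        res = pagels_lambda(X, tree, n_rand=self.n_rand, seed=self.seed)
        self.result_ = res
        self.lambda_ = res.lambda_hat
        self.loglik_ = res.loglik
        self.p_randomization_ = res.p_randomization
        self.lr_p_ = res.lr_p
        return self


class MantelTest(BaseEstimator):
    """sklearn-style estimator for the Mantel matrix correlation."""

    def __init__(self, n_perm: int = 999, seed: int | None = None,
                 alternative: str = "greater"):
        self.n_perm = n_perm
        self.seed = seed
        self.alternative = alternative

    def fit(self, X, y=None):
        res = mantel(X, y, n_perm=self.n_perm, seed=self.seed,
                     alternative=self.alternative)
        self.result_ = res
        self.r_ = res.r
        self.p_ = res.p_permutation
        return self
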