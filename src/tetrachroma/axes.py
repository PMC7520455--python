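"""Major chromatic axis, spherical color scores and species x region matrices.

Within each clade the RNL XYZ cloud is strongly linear; PCA on the XYZ
covariance quantifies how much chromatic variance the first major axis
explains.  Converting XYZ (achromatic point at the origin) to spherical
coordinates gives each patch an elevation

    phi = atan2(Z, sqrt(X^2 + Y^2))  in [-pi/2, +pi/2]

used as a one-dimensional color score: colors on opposite sides of the
achromatic point along the elevation axis have phi of opposite sign, the
operational definition of a complementary pair.  The azimuth theta is
retained for diagnostics but not used downstream (azimuthal variance is
comparatively small; the reported azimuthal variance fraction makes that
assumption checkable).

For comparative analyses, patch scores are averaged patch -> specimen ->
species within each body region (specimen-first, so heavily sampled
specimens do not dominate), producing species x region matrices of color
and luminance scores.  Black patches contribute to luminance means only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AxisReport",
    "ColorScore",
    "CladeDataset",
    "CVResult",
    "ChromaticAxis",
    "pca_axis",
    "spherical_scores",
    "spherical_to_xyz",
    "aggregate_scores",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class AxisReport:
    """PCA summary of the XYZ cloud."""

    pc1_loadings: np.ndarray  # unit vector, sign-fixed (Z weight >= 0)
    pc_variance_fractions: np.ndarray  # descending, sums to 1
    centering: np.ndarray  # mean XYZ
    azimuthal_variance_fraction: float  # share of variance in the XY plane
    degenerate: bool = False


class ColorScore(NamedTuple):
    """Spherical coordinates of one patch (phi is the color score)."""

    phi: float
    theta: float
    r_jnd: float


class CVResult(NamedTuple):
    """Coefficient of variation with a zero-mean degeneracy flag."""

    cv: float
    zero_mean: bool


@dataclass
class CladeDataset:
    """Species x region matrices of mean color and luminance scores."""

    color: pd.DataFrame  # mean phi per (species, region); NaN where unmeasured
    luminance: pd.DataFrame
    counts: pd.DataFrame  # number of patches behind each cell
    sex_filter: str = "all"


def pca_axis(xyz, tol: float = 1e-12) -> AxisReport:
    """Eigendecomposition of the XYZ covariance (covariance PCA).

    Coordinates share JND units, so the covariance (not correlation) matrix
    is decomposed.  PC1's sign is fixed so its Z weight is non-negative
    (ties broken on Y then X), making reports reproducible; the orientation
    itself is arbitrary.
    """
    X = _xyz_array(xyz)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 points")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    degenerate = bool(evals[-1] <= tol * max(evals[0], tol))
    if total <= 0:
        raise ValueError("XYZ cloud has zero variance; no axis to report")
    pc1 = evecs[:, 0]
    for comp in (2, 1, 0):  # prefer non-negative Z, then Y, then X
        if abs(pc1[comp]) > 1e-12:
            if pc1[comp] < 0:
                pc1 = -pc1
            break
    var_xy = cov[0, 0] + cov[1, 1]
    return AxisReport(
        pc1_loadings=pc1,
        pc_variance_fractions=evals / total,
        centering=mean,
        azimuthal_variance_fraction=float(var_xy / total),
        degenerate=degenerate,
    )


def _xyz_array(xyz) -> np.ndarray:
    if isinstance(xyz, pd.DataFrame):
        X = xyz[["X", "Y", "Z"]].to_numpy(dtype=float)
    else:
        X = np.asarray(xyz, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("xyz must be (n, 3)")
    return X[~np.isnan(X).any(axis=1)]


class ChromaticAxis(BaseEstimator):
    """sklearn-style estimator wrapping :func:`pca_axis`.

    ``fit`` computes the axis; fitted attributes: ``pc1_loadings_``,
    ``variance_fractions_``, ``mean_``, ``azimuthal_variance_fraction_``.
    ``transform`` projects XYZ onto the principal axes.
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def fit(self, X, y=None):
        rep = pca_axis(X, tol=self.tol)
        self.report_ = rep
        self.pc1_loadings_ = rep.pc1_loadings
        self.variance_fractions_ = rep.pc_variance_fractions
        self.mean_ = rep.centering
        self.azimuthal_variance_fraction_ = rep.azimuthal_variance_fraction
        self.n_features_in_ = 3
        return self

    def transform(self, X):
        X = _xyz_array(X)
        return (X - self.mean_) @ np.column_stack(
            [self.pc1_loadings_, *self._minor_axes()]
        )

    def _minor_axes(self):
        # complete pc1 to an orthonormal basis (minor axes only used for
        # diagnostics; any completion is acceptable)
        v = self.pc1_loadings_
        basis = np.linalg.qr(np.column_stack([v, np.eye(3)]))[0]
        return [basis[:, 1], basis[:, 2]]


def spherical_scores(xyz) -> pd.DataFrame:
    """Elevation phi, azimuth theta and radius for every XYZ row.

    Points exactly at the achromatic origin (and black/NaN rows) get
    missing phi/theta: a stimulus with no chromatic signal has no hue
    direction.
    """
    if isinstance(xyz, pd.DataFrame):
        X = xyz[["X", "Y", "Z"]].to_numpy(dtype=float)
        index = xyz.index
        keep = [c for c in ("species", "sex", "region", "is_black", "luminance") if c in xyz.columns]
        meta = xyz[keep]
    else:
        X = np.atleast_2d(np.asarray(xyz, dtype=float))
        index = pd.RangeIndex(X.shape[0])
        meta = None
    r = np.linalg.norm(X, axis=1)
    with np.errstate(invalid="ignore"):
        phi = np.arctan2(X[:, 2], np.hypot(X[:, 0], X[:, 1]))
        theta = np.arctan2(X[:, 1], X[:, 0])
    at_origin = r == 0
    phi[at_origin] = np.nan
    theta[at_origin] = np.nan
    out = pd.DataFrame({"phi": phi, "theta": theta, "r_jnd": r}, index=index)
    if meta is not None:
        out = pd.concat([meta, out], axis=1)
    return out


def spherical_to_xyz(phi, theta, r) -> np.ndarray:
    """Inverse of :func:`spherical_scores` (for round-trip checks)."""
    phi, theta, r = np.broadcast_arrays(
        np.asarray(phi, float), np.asarray(theta, float), np.asarray(r, float)
    )
    return np.stack(
        [r * np.cos(phi) * np.cos(theta), r * np.cos(phi) * np.sin(theta), r * np.sin(phi)],
        axis=-1,
    )


def aggregate_scores(scores: pd.DataFrame, sex_filter: str = "all") -> CladeDataset:
    """Average patch scores into species x region matrices.

    ``scores`` must carry species, sex, region, specimen (or specimen_id),
    phi and luminance columns.  Averaging nests patch -> specimen ->
    species.  Cells never measured stay missing.  With
    ``sex_filter='male_only'`` species represented only by non-male rows are
    dropped with a warning.
    """
    if sex_filter not in ("all", "male_only"):
        raise ValueError("sex_filter must be 'all' or 'male_only'")
    df = scores.reset_index()
    spec_col = "specimen_id" if "specimen_id" in df.columns else "specimen"
    needed = {"species", "sex", "region", spec_col, "phi", "luminance"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    all_species = sorted(df["species"].unique())
    if sex_filter == "male_only":
        kept = df[df["sex"] == "M"]
        dropped = sorted(set(all_species) - set(kept["species"]))
        if dropped:
            warnings.warn(
                f"male_only filter drops species with no male rows: {dropped}",
                stacklevel=2,
            )
        df = kept
    if df.empty:
        raise ValueError("no rows left after sex filter")
    by_specimen = (
        df.groupby(["species", "region", spec_col])
        .agg(phi=("phi", "mean"), luminance=("luminance", "mean"), n=("phi", "size"))
        .reset_index()
    )
    by_species = by_specimen.groupby(["species", "region"]).agg(
        phi=("phi", "mean"), luminance=("luminance", "mean"), n=("n", "sum")
    )
    color = by_species["phi"].unstack("region")
    lum = by_species["luminance"].unstack("region")
    counts = by_species["n"].unstack("region").fillna(0).astype(int)
    return CladeDataset(color=color, luminance=lum, counts=counts, sex_filter=sex_filter)


def coefficient_of_variation(
    dataset: CladeDataset, trait: str, region: str, zero_tol: float = 1e-12
) -> CVResult:
    """Across-species CV (sample sd / |mean|) of one region's scores.

    A mean within ``zero_tol`` of zero makes the ratio meaningless; the CV
    is then reported missing with the ``zero_mean`` flag set.
    """
    if trait not in ("color", "luminance"):
        raise ValueError("trait must be 'color' or 'luminance'")
    mat = dataset.color if trait == "color" else dataset.luminance
    if region not in mat.columns:
        raise ValueError(f"region {region!r} not in dataset")
    vals = mat[region].dropna().to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(f"need >= 2 species with values in region {region!r}")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if abs(mean) <= zero_tol or (sd > 0 and abs(mean) <= zero_tol * sd):
        return CVResult(np.nan, True)
    return CVResult(float(sd / abs(mean)), False)
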