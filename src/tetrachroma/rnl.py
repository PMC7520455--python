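"""Receptor-noise-limited (RNL) chromatic distances and the isometric XYZ space.

Under the Vorobyev-Osorio receptor-noise model, the discriminability of two
stimuli with von Kries-corrected catches q^a, q^b is

    dS^2 = sum_{i<j} (e_k e_l)^2 (df_i - df_j)^2  /  sum_i (prod_{j != i} e_j)^2

with log-catch contrasts df_i = ln q_i^a - ln q_i^b and per-cone Weber
fractions e_i; dS is measured in just-noticeable differences (JND).

This quadratic form equals the noise-weighted sum of squares of df about its
noise-weighted mean (weights w_i = 1 / e_i^2), which yields an exact 3-D
Cartesian embedding by sequential weighted contrasts of f = ln q:

    X = sqrt(w_m w_l / (w_m + w_l)) * (f_l - f_m)
    Y = sqrt(w_s W_ml / (w_s + W_ml)) * (f_s - wmean(f_m, f_l))
    Z = sqrt(w_u W_sml / (w_u + W_sml)) * (f_u - wmean(f_s, f_m, f_l))

where W denotes the summed weights of the receptors already used.  Euclidean
distance in (X, Y, Z) equals dS exactly; each coordinate is a contrast
(coefficients sum to zero), so a uniform intensity change of the stimulus
leaves the point unchanged and the equal-catch (achromatic) stimulus maps to
the origin.  The orientation is fixed: X opposes l against m, Y brings in s,
and Z carries the u contrast with a positive sign, so u-rich (short-wave)
colors have positive Z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .visual import CONE_LABELS, DEFAULT_WEBER

__all__ = [
    "delta_s",
    "rnl_basis",
    "xyz_from_catches",
    "achromatic_origin",
    "ReceptorNoiseMap",
]


def _validate_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError("catches must have 4 components (u, s, m, l)")
    if np.any(~np.isfinite(q)) or np.any(q <= 0):
        raise ValueError(
            "catches must be finite and strictly positive; black patches must "
            "be excluded before the receptor-noise model"
        )
    return q


def delta_s(catch_a, catch_b, weber=DEFAULT_WEBER) -> float:
    """Chromatic distance dS (JND) between two catch quadruples.

    Direct evaluation of the tetrachromatic receptor-noise quadratic form;
    symmetric in its arguments.
    """
    qa = _validate_q(catch_a)
    qb = _validate_q(catch_b)
    e = np.asarray(weber, dtype=float)
    if e.shape != (4,) or np.any(e <= 0):
        raise ValueError("weber must be 4 positive fractions")
    df = np.log(qa) - np.log(qb)
    num = 0.0
    idx = range(4)
    for i in idx:
        for j in idx:
            if i < j:
                k, l = [c for c in idx if c not in (i, j)]
                num += (e[k] * e[l]) ** 2 * (df[i] - df[j]) ** 2
    den = sum(np.prod(np.delete(e, i) ** 2) for i in idx)
    return float(np.sqrt(num / den))


def rnl_basis(weber=DEFAULT_WEBER) -> np.ndarray:
    """The 3x4 contrast matrix A with (X, Y, Z) = A @ ln(q).

    Rows are zero-sum contrasts; ``A.T @ A`` equals the receptor-noise
    quadratic form, so Euclidean distances in the image equal dS.
    """
    e = np.asarray(weber, dtype=float)
    if e.shape != (4,) or np.any(e <= 0):
        raise ValueError("weber must be 4 positive fractions")
    w = 1.0 / e**2  # order u, s, m, l
    wu, ws, wm, wl = w
    A = np.zeros((3, 4))
    # X: l vs m
    cx = np.sqrt(wm * wl / (wm + wl))
    A[0, 3] = cx
    A[0, 2] = -cx
    # Y: s vs weighted mean of (m, l)
    W_ml = wm + wl
    cy = np.sqrt(ws * W_ml / (ws + W_ml))
    A[1, 1] = cy
    A[1, 2] = -cy * wm / W_ml
    A[1, 3] = -cy * wl / W_ml
    # Z: u vs weighted mean of (s, m, l); positive u coefficient
    W_sml = ws + wm + wl
    cz = np.sqrt(wu * W_sml / (wu + W_sml))
    A[2, 0] = cz
    A[2, 1] = -cz * ws / W_sml
    A[2, 2] = -cz * wm / W_sml
    A[2, 3] = -cz * wl / W_sml
    return A


def xyz_from_catches(catches, weber=DEFAULT_WEBER):
    """Map catches to RNL XYZ coordinates (JND units).

    ``catches`` is an (n, 4) array of positive catches, or a catch table
    (DataFrame with u, s, m, l columns; black/NaN rows propagate NaN).
    Relative and absolute catches give identical coordinates: a per-stimulus
    scale factor adds a constant to every f_i, which every zero-sum contrast
    annihilates.
    """
    if isinstance(catches, pd.DataFrame):
        sub = catches[list(CONE_LABELS)].to_numpy(dtype=float)
        out = np.full((sub.shape[0], 3), np.nan)
        mask = ~np.isnan(sub).any(axis=1)
        if mask.any():
            out[mask] = xyz_from_catches(sub[mask], weber)
        df = pd.DataFrame(out, index=catches.index, columns=["X", "Y", "Z"])
        keep = [c for c in ("species", "sex", "region", "is_black", "luminance") if c in catches.columns]
        return pd.concat([catches[keep], df], axis=1)
    q = _validate_q(np.atleast_2d(catches))
    A = rnl_basis(weber)
    xyz = np.log(q) @ A.T
    return xyz if np.asarray(catches).ndim == 2 else xyz[0]


def achromatic_origin(xyz, weber=DEFAULT_WEBER):
    """Express XYZ relative to the image of the equal-catch stimulus.

    With the contrast construction the achromatic stimulus already maps to
    (0, 0, 0), so this is a no-op translation; it is kept explicit so the
    choice of origin is visible and testable (idempotent, distance
    preserving).
    """
    offset = xyz_from_catches(np.ones(4), weber)
    if isinstance(xyz, pd.DataFrame):
        out = xyz.copy()
        out[["X", "Y", "Z"]] = out[["X", "Y", "Z"]].to_numpy() - offset
        return out
    return np.asarray(xyz, dtype=float) - offset


class ReceptorNoiseMap(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: catch quadruples -> RNL XYZ (JND).

    Composes after :class:`~tetrachroma.visual.ConeCatchTransform` in an
    sklearn Pipeline (the first four output columns of that transform are
    valid input here).
    """

    def __init__(self, weber=None):
        self.weber = weber

    def _weber(self):
        return DEFAULT_WEBER if self.weber is None else np.asarray(self.weber, float)

    def fit(self, X=None, y=None):
        self.basis_ = rnl_basis(self._weber())
        self.n_features_in_ = 4
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 4:
            raise ValueError("X must be (n, 4) catches (extra columns ignored)")
        return achromatic_origin(
            xyz_from_catches(X[:, :4], self._weber()), self._weber()
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["X", "Y", "Z"], dtype=object)
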