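"""Avian visual-system models: cone sensitivities and photon (quantum) catches.

Cone spectral sensitivities are built from the Govardovskii A1 visual-pigment
nomogram (alpha + beta band) at configurable peak wavelengths for the two
average avian tuning classes:

* UVS (ultraviolet-sensitive): peaks at 372, 456, 544, 609 nm
* VS  (violet-sensitive):      peaks at 418, 478, 542, 607 nm

The quantum catch of cone *i* for a reflectance spectrum R under illuminant I
is ``Q_i = integral R(l) S_i(l) I(l) dl`` (trapezoidal on the canonical grid),
and the von Kries correction normalizes by the catch of the illuminant itself,
``q_i = Q_i / integral S_i(l) I(l) dl``, modelling chromatic adaptation.
Relative catches ``rel_i = q_i / sum_j q_j`` are the coordinates fed to the
tetrahedral color space.  Luminance is the von Kries-normalized catch of the
double cone (blue-tit-like, nomogram at 563 nm by default), so a flat
spectrum of reflectance k scores k.

Weber fractions (per-cone noise) default to a Leiothrix-like set derived from
relative cone densities 1:2:2:4 (u:s:m:l) with the most abundant cone at
e_l = 0.1, giving e = (0.2, 0.1414, 0.1414, 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import CANONICAL_GRID, PatchRecord, ReflectanceSpectrum

__all__ = [
    "CONE_LABELS",
    "DEFAULT_LAMBDA_MAX",
    "DEFAULT_DOUBLE_CONE_LAMBDA_MAX",
    "DEFAULT_WEBER",
    "cone_sensitivity",
    "weber_from_densities",
    "VisualSystem",
    "ConeCatch",
    "build_visual_system",
    "quantum_catch",
    "double_cone_catch",
    "catch_table",
    "ConeCatchTransform",
]

CONE_LABELS = ("u", "s", "m", "l")

#: Default cone peak wavelengths (nm) for the two average avian classes.
DEFAULT_LAMBDA_MAX = {
    "UVS": (372.0, 456.0, 544.0, 609.0),
    "VS": (418.0, 478.0, 542.0, 607.0),
}

DEFAULT_DOUBLE_CONE_LAMBDA_MAX = 563.0


def weber_from_densities(densities=(1.0, 2.0, 2.0, 4.0), e_max_abundance: float = 0.1) -> np.ndarray:
    """Weber fractions from relative cone densities.

    ``e_i = e_ref * sqrt(n_ref / n_i)`` where the reference is the most
    abundant cone class; noise falls with the square root of cone abundance.
    """
    n = np.asarray(densities, dtype=float)
    if np.any(n <= 0):
        raise ValueError("cone densities must be positive")
    return e_max_abundance * np.sqrt(n.max() / n)


DEFAULT_WEBER = weber_from_densities()


def cone_sensitivity(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii A1 pigment template (alpha + beta band), unit peak.

    The alpha band is ``1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)``
    with x = lambda_max / lambda, A=69.7, B=28, C=-14.9, D=0.674,
    b=0.922, c=1.104 and a = 0.8795 + 0.0459 exp(-(lambda_max-300)^2/11940);
    the beta band is a Gaussian with amplitude 0.26.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


@dataclass(frozen=True)
class VisualSystem:
    """Four cone sensitivities + double cone + illuminant + Weber fractions."""

    system: str
    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (4, n_wl), rows in u, s, m, l order
    double_cone: np.ndarray  # (n_wl,)
    illuminant: np.ndarray  # (n_wl,)
    weber: np.ndarray  # (4,)
    lambda_max: tuple = ()

    def __post_init__(self) -> None:
        if self.sensitivities.shape != (4, self.wavelengths.size):
            raise ValueError("sensitivities must be (4, n_wavelengths)")
        if np.any(self.sensitivities < 0) or np.any(self.double_cone < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(np.asarray(self.weber) <= 0):
            raise ValueError("Weber fractions must be positive")


@dataclass(frozen=True)
class ConeCatch:
    """Quantum catches of one patch: raw, von Kries-corrected, relative."""

    Q: np.ndarray  # raw catches, arbitrary units
    q: np.ndarray  # von Kries-corrected
    rel: np.ndarray  # relative catches, sum 1
    luminance: float  # double-cone catch in [0, 1] under idealized light


def build_visual_system(
    system: str = "UVS",
    weber: np.ndarray | None = None,
    lambda_max: tuple | None = None,
    double_cone_lambda_max: float = DEFAULT_DOUBLE_CONE_LAMBDA_MAX,
    illuminant: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    sensitivity_table: pd.DataFrame | None = None,
) -> VisualSystem:
    """Build a VisualSystem on the canonical grid.

    Parameters
    ----------
    system : {"UVS", "VS"}
        Average avian tuning class; sets default cone peak wavelengths.
    weber : array of 4 floats, optional
        Per-cone Weber fractions (u, s, m, l); defaults to the
        Leiothrix-like set (0.2, 0.1414, 0.1414, 0.1).
    lambda_max : 4-tuple, optional
        Override cone peaks (nm), in u, s, m, l order.
    illuminant : array, optional
        Illuminant spectrum on the grid; default idealized uniform light.
    sensitivity_table : DataFrame, optional
        Tabulated curves instead of the nomogram: columns
        wavelength, u, s, m, l, d.
    """
    if system not in DEFAULT_LAMBDA_MAX:
        raise ValueError(f"unknown visual system {system!r}; expected 'UVS' or 'VS'")
    wl = CANONICAL_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if sensitivity_table is not None:
        tab = sensitivity_table
        need = {"wavelength", "u", "s", "m", "l", "d"}
        if not need.issubset(tab.columns):
            raise ValueError(f"sensitivity table needs columns {sorted(need)}")
        sens = np.vstack(
            [np.interp(wl, tab["wavelength"], tab[c]) for c in CONE_LABELS]
        )
        dbl = np.interp(wl, tab["wavelength"], tab["d"])
        sens = sens / sens.max(axis=1, keepdims=True)
        dbl = dbl / dbl.max()
        lmax = tuple(float(wl[np.argmax(sens[i])]) for i in range(4))
    else:
        lmax = DEFAULT_LAMBDA_MAX[system] if lambda_max is None else tuple(lambda_max)
        if len(lmax) != 4:
            raise ValueError("lambda_max must have 4 entries (u, s, m, l)")
        sens = np.vstack([cone_sensitivity(wl, lm) for lm in lmax])
        dbl = cone_sensitivity(wl, double_cone_lambda_max)
    illum = np.ones_like(wl) if illuminant is None else np.asarray(illuminant, dtype=float)
    if illum.shape != wl.shape:
        raise ValueError("illuminant must be tabulated on the same grid")
    w = DEFAULT_WEBER if weber is None else np.asarray(weber, dtype=float)
    return VisualSystem(
        system=system,
        wavelengths=wl,
        sensitivities=sens,
        double_cone=dbl,
        illuminant=illum,
        weber=w,
        lambda_max=lmax,
    )


def _as_reflectance_array(spectrum, vs: VisualSystem) -> np.ndarray:
    if isinstance(spectrum, ReflectanceSpectrum):
        if not np.array_equal(spectrum.wavelengths, vs.wavelengths):
            raise ValueError("spectrum is not on the visual system's grid; resample first")
        return spectrum.reflectance
    r = np.asarray(spectrum, dtype=float)
    if r.shape != vs.wavelengths.shape:
        raise ValueError("reflectance array does not match the visual-system grid")
    return r


def quantum_catch(spectrum, vs: VisualSystem) -> ConeCatch:
    """Quantum catches of the four single cones with von Kries correction.

    Raises for an all-zero spectrum: black patches carry no chromatic signal
    and must be routed through black-patch handling (see
    :func:`catch_table`), not through the chromatic model.
    """
    r = _as_reflectance_array(spectrum, vs)
    if not np.any(r > 0):
        raise ValueError(
            "all-zero spectrum has no chromatic signal; "
            "handle it as a black patch (luminance only)"
        )
    wl = vs.wavelengths
    stim = vs.sensitivities * vs.illuminant  # (4, n)
    Q = np.trapezoid(r * stim, wl, axis=1)
    norm = np.trapezoid(stim, wl, axis=1)
    q = Q / norm
    rel = q / q.sum()
    lum = double_cone_catch(r, vs)
    return ConeCatch(Q=Q, q=q, rel=rel, luminance=lum)


def double_cone_catch(spectrum, vs: VisualSystem) -> float:
    """von Kries-normalized double-cone catch (the luminance score).

    Linear in reflectance: a flat spectrum of reflectance k scores k under
    the idealized illuminant.  Black (all-zero) patches score 0.
    """
    r = _as_reflectance_array(spectrum, vs)
    wl = vs.wavelengths
    stim = vs.double_cone * vs.illuminant
    return float(np.trapezoid(r * stim, wl) / np.trapezoid(stim, wl))


def catch_table(patches: list[PatchRecord], vs: VisualSystem) -> pd.DataFrame:
    """Per-patch catch table: metadata + relative catches + luminance.

    Black-flagged patches keep their luminance but their chromatic columns
    are set to NaN (the achromatic sentinel); they must never enter the
    receptor-noise model, where a zero catch has no logarithm.
    """
    systems = {p.extra.get("visual_system") for p in patches if p.extra.get("visual_system")}
    clades = {p.clade for p in patches if p.clade is not None}
    if len(systems) > 1:
        raise ValueError(
            f"patches span clades configured with different visual systems {sorted(systems)}; "
            "run each clade separately"
        )
    if systems and next(iter(systems)) != vs.system:
        raise ValueError(
            f"patches are configured for {next(iter(systems))} but a {vs.system} model was supplied"
        )
    rows = []
    for p in patches:
        if p.spectrum is None:
            raise ValueError(f"patch {p.patch_id} has no spectrum")
        base = {
            "patch_id": p.patch_id,
            "specimen_id": p.specimen_id,
            "species": p.species,
            "sex": p.sex,
            "region": p.region,
            "clade": p.clade if p.clade is not None else (next(iter(clades)) if len(clades) == 1 else None),
            "is_black": bool(p.is_black),
        }
        if p.is_black or not np.any(p.spectrum.reflectance > 0):
            base.update({c: np.nan for c in CONE_LABELS})
            base.update({f"q_{c}": np.nan for c in CONE_LABELS})
            base["luminance"] = double_cone_catch(p.spectrum, vs)
        else:
            cc = quantum_catch(p.spectrum, vs)
            base.update(dict(zip(CONE_LABELS, cc.rel)))
            base.update({f"q_{c}": v for c, v in zip(CONE_LABELS, cc.q)})
            base["luminance"] = cc.luminance
        rows.append(base)
    return pd.DataFrame(rows).set_index("patch_id")


class ConeCatchTransform(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: reflectance rows -> cone catches.

    Input X is ``(n_patches, 401)`` reflectance on the canonical grid; the
    output is ``(n_patches, 5)``: relative catches u, s, m, l and the
    double-cone luminance.  ``fit`` only builds/validates the visual system.
    """

    def __init__(self, system: str = "UVS", weber=None, lambda_max=None,
                 double_cone_lambda_max: float = DEFAULT_DOUBLE_CONE_LAMBDA_MAX):
        self.system = system
        self.weber = weber
        self.lambda_max = lambda_max
        self.double_cone_lambda_max = double_cone_lambda_max

    def fit(self, X=None, y=None):
        self.visual_system_ = build_visual_system(
            system=self.system,
            weber=self.weber,
            lambda_max=self.lambda_max,
            double_cone_lambda_max=self.double_cone_lambda_max,
        )
        self.n_features_in_ = CANONICAL_GRID.size
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "visual_system_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n_patches, {self.n_features_in_})")
        out = np.empty((X.shape[0], 5))
        for i, r in enumerate(X):
            cc = quantum_catch(r, self.visual_system_)
            out[i, :4] = cc.rel
            out[i, 4] = cc.luminance
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray([*CONE_LABELS, "luminance"], dtype=object)
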