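"""Synthetic reflectance spectra, clades and phylogenies with known truth.

Real plumage spectra fall into a few phenomenological classes, which the
generator emulates with five templates:

* ``long_pass_sigmoid`` — carotenoid-like red/orange: a logistic step from a
  low baseline up to a plateau above an inflection wavelength.
* ``short_wave_gaussian`` — structural blue/UV: a Gaussian peak at short
  wavelengths over a low baseline.
* ``flat_low`` — melanin-like brown/gray: low reflectance with a gentle
  long-pass tilt (browns reflect more at long wavelengths).
* ``flat_high`` — white: high flat reflectance.
* ``near_zero`` — black: constant baseline near zero.

A synthetic clade plants a complementary pair (one long-wave, one
short-wave template) across body regions of each species.  Under the
``redistributed`` assignment every species carries at least one region of
each class (the complementary-color hypothesis); under ``one_sided`` only
the long-wave class is present and the remaining regions are filled with
melanin-brown and black patches (a sandgrouse-like clade whose chromatic
scores all sit on one side of the achromatic point — a noise-perturbed
flat white patch would sit at the origin with a random hue sign, so whites
are not used in one-sided clades).

Species-level template parameters (inflection/peak wavelength) drift either
independently (``star``) or by Brownian motion along a simulated Yule tree
(``brownian``); measurement noise is multiplicative Gaussian, clipped to
[0, 1].  All randomness flows from a single seed through deterministic
substreams.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .spectra import (
    CANONICAL_GRID,
    EXTENDED_REGIONS,
    PatchRecord,
    ReflectanceSpectrum,
    flag_black,
)

__all__ = [
    "SpectrumTemplate",
    "SyntheticCladeSpec",
    "CladeSim",
    "CAROTENOID_RED",
    "STRUCTURAL_BLUE",
    "MELANIN_BROWN",
    "WHITE",
    "BLACK",
    "make_spectrum",
    "simulate_clade",
    "simulate_tree",
    "simulate_bm_traits",
]

_FAMILIES = (
    "long_pass_sigmoid",
    "short_wave_gaussian",
    "flat_low",
    "flat_high",
    "near_zero",
)


@dataclass(frozen=True)
class SpectrumTemplate:
    """Parametric template for one spectral class."""

    family: str
    wavelength: float = 550.0  # inflection (sigmoid) or peak (gaussian), nm
    width: float = 30.0  # logistic scale or gaussian sd, nm
    plateau: float = 0.9  # top reflectance, proportion
    baseline: float = 0.02  # bottom reflectance, proportion

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown template family {self.family!r}")
        if not (0.0 <= self.baseline <= 1.0 and 0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau and baseline must be proportions in [0, 1]")
        if self.width <= 0:
            raise ValueError("width must be positive")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Noise-free template reflectance on an arbitrary grid."""
        wl = np.asarray(wavelengths, dtype=float)
        lo, hi, w0, width = self.baseline, self.plateau, self.wavelength, self.width
        if self.family == "long_pass_sigmoid":
            r = lo + (hi - lo) / (1.0 + np.exp(-(wl - w0) / width))
        elif self.family == "short_wave_gaussian":
            r = lo + (hi - lo) * np.exp(-((wl - w0) ** 2) / (2.0 * width**2))
        elif self.family == "flat_low":
            # gentle long-pass tilt from baseline up to plateau (brown)
            r = lo + (hi - lo) / (1.0 + np.exp(-(wl - w0) / max(width, 60.0)))
        elif self.family == "flat_high":
            r = np.full_like(wl, hi)
        else:  # near_zero
            r = np.full_like(wl, lo)
        return np.clip(r, 0.0, 1.0)


# Canonical templates for the planted complementary pair and backgrounds.
CAROTENOID_RED = SpectrumTemplate("long_pass_sigmoid", 575.0, 25.0, 0.85, 0.03)
STRUCTURAL_BLUE = SpectrumTemplate("short_wave_gaussian", 410.0, 45.0, 0.65, 0.02)
MELANIN_BROWN = SpectrumTemplate("flat_low", 560.0, 80.0, 0.30, 0.08)
WHITE = SpectrumTemplate("flat_high", plateau=0.90, baseline=0.90)
BLACK = SpectrumTemplate("near_zero", plateau=0.01, baseline=0.01)


def make_spectrum(
    template: SpectrumTemplate,
    grid: np.ndarray | None = None,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> ReflectanceSpectrum:
    """Instantiate a template as a spectrum, with multiplicative noise.

    Noise is per-wavelength Gaussian, scale ``noise_sd``, multiplicative
    (R -> R * (1 + eps)) and clipped to [0, 1] so spectra stay physical.
    Deterministic given ``seed``.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 300.0 - 1e-9 or grid[-1] > 700.0 + 1e-9:
        raise ValueError("grid outside the supported 300-700 nm range")
    r = template.evaluate(grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = np.clip(r * (1.0 + rng.normal(0.0, noise_sd, grid.size)), 0.0, 1.0)
    return ReflectanceSpectrum(grid, r)


@dataclass(frozen=True)
class SyntheticCladeSpec:
    """Ground-truth recipe for a synthetic clade."""

    n_species: int = 27
    n_regions: int = 7
    complementary_pair: tuple = (CAROTENOID_RED, STRUCTURAL_BLUE)
    assignment_model: str = "redistributed"  # or "one_sided"
    trait_evolution: str = "star"  # or "brownian"
    noise_sd: float = 0.02
    wavelength_drift_sd: float = 12.0  # species-level peak drift, nm
    n_specimens: int = 2
    dimorphic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if not (2 <= self.n_regions <= len(EXTENDED_REGIONS)):
            raise ValueError(f"n_regions must be in [2, {len(EXTENDED_REGIONS)}]")
        if self.assignment_model not in ("redistributed", "one_sided"):
            raise ValueError("assignment_model must be 'redistributed' or 'one_sided'")
        if self.trait_evolution not in ("star", "brownian"):
            raise ValueError("trait_evolution must be 'star' or 'brownian'")
        long_t, short_t = self.complementary_pair
        if long_t.family != "long_pass_sigmoid" or short_t.family != "short_wave_gaussian":
            raise ValueError(
                "complementary_pair must be (long_pass_sigmoid, short_wave_gaussian)"
            )


@dataclass
class CladeSim:
    """Output of :func:`simulate_clade`: patches, truth and the tree."""

    metadata: pd.DataFrame  # specimen_id, species, sex, region, patch_id, clade
    patches: list  # list[PatchRecord], resampled + black-flagged
    true_class: pd.Series  # patch_id -> {"long", "short", "brown", "white", "black"}
    tree: dendropy.Tree
    spec: SyntheticCladeSpec


def simulate_tree(n_tips: int, model: str = "yule", seed: int | None = None) -> dendropy.Tree:
    """Simulate an ultrametric binary Yule tree with labelled tips.

    Tip labels are Species_01 ... Species_NN; deterministic given seed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the process stops exactly at the n-th speciation, leaving the two
    # youngest tips with zero branches; hang all tips for the exponential
    # waiting time to the (unrealized) next event to keep lengths positive
    hang = rng.expovariate(n_tips * 1.0)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"Species_{i:02d}"
        leaf.edge.length += hang
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    seed: int | None = None,
    mean: float = 0.0,
) -> pd.Series:
    """Draw tip traits from the lambda-transformed Brownian covariance.

    Traits follow MVN(mean, sigma2 * C_lambda) where C is the BM covariance
    of the tree and C_lambda scales its off-diagonal by ``lambda_true``
    (lambda 0 = independent tips with variance sigma2 * depth; lambda 1 =
    Brownian motion).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    from .phylo import bm_covariance

    C_df = bm_covariance(tree)
    C = C_df.to_numpy(dtype=float)
    Cl = lambda_true * C + (1.0 - lambda_true) * np.diag(np.diag(C))
    # tiny ridge: deep Yule trees give numerically semidefinite covariances
    ridge = 1e-10 * np.max(np.diag(Cl))
    L = np.linalg.cholesky(sigma2 * Cl + ridge * np.eye(C.shape[0]))
    rng = np.random.default_rng(seed)
    y = mean + L @ rng.standard_normal(C.shape[0])
    return pd.Series(y, index=C_df.index)


def _species_assignments(spec: SyntheticCladeSpec, rng: np.random.Generator, regions):
    """Per-species mapping region -> class label, honouring the model."""
    n_r = len(regions)
    assignments = {}
    one_sided_backgrounds = ["brown", "black"]
    redistributed_backgrounds = ["brown", "white", "black"]
    for i in range(spec.n_species):
        labels = [None] * n_r
        slots = list(rng.permutation(n_r))
        if spec.assignment_model == "redistributed":
            # guarantee one region of each chromatic class, then fill freely
            labels[slots.pop()] = "long"
            labels[slots.pop()] = "short"
            pool = ["long", "short", *redistributed_backgrounds]
        else:
            labels[slots.pop()] = "long"
            pool = ["long", *one_sided_backgrounds]
        for s in slots:
            labels[s] = pool[rng.integers(len(pool))]
        assignments[f"Species_{i + 1:02d}"] = dict(zip(regions, labels))
    return assignments


def simulate_clade(spec: SyntheticCladeSpec) -> CladeSim:
    """Generate a full synthetic clade: metadata, spectra, truth, tree.

    Reproducible: the same spec (including seed) yields byte-identical
    tables and spectra.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_assign, s_tree, s_drift, s_noise = ss.spawn(4)
    rng_assign = np.random.default_rng(s_assign)
    regions = list(EXTENDED_REGIONS[: spec.n_regions])
    species = [f"Species_{i + 1:02d}" for i in range(spec.n_species)]
    assignments = _species_assignments(spec, rng_assign, regions)

    tree = simulate_tree(
        spec.n_species, seed=int(s_tree.generate_state(1)[0] % (2**31))
    )
    # species-level wavelength drift of the chromatic templates
    if spec.trait_evolution == "brownian":
        depth = max(
            leaf.root_distance
            for leaf in _with_root_distances(tree).leaf_node_iter()
        )
        drift_long = simulate_bm_traits(
            tree, sigma2=spec.wavelength_drift_sd**2 / depth, lambda_true=1.0,
            seed=int(s_drift.generate_state(2)[0] % (2**31)),
        )
        drift_short = simulate_bm_traits(
            tree, sigma2=spec.wavelength_drift_sd**2 / depth, lambda_true=1.0,
            seed=int(s_drift.generate_state(2)[1] % (2**31)),
        )
    else:
        rng_drift = np.random.default_rng(s_drift)
        drift_long = pd.Series(
            rng_drift.normal(0.0, spec.wavelength_drift_sd, spec.n_species), index=species
        )
        drift_short = pd.Series(
            rng_drift.normal(0.0, spec.wavelength_drift_sd, spec.n_species), index=species
        )

    long_t, short_t = spec.complementary_pair
    templates = {
        "brown": MELANIN_BROWN,
        "white": WHITE,
        "black": BLACK,
    }
    rows, patches, truth = [], [], {}
    noise_root = np.random.default_rng(s_noise)
    sexes = ("M", "F") if spec.dimorphic else ("M",)
    for sp in species:
        t_long = replace(
            long_t, wavelength=float(np.clip(long_t.wavelength + drift_long[sp], 480.0, 640.0))
        )
        t_short = replace(
            short_t, wavelength=float(np.clip(short_t.wavelength + drift_short[sp], 340.0, 520.0))
        )
        sp_templates = {**templates, "long": t_long, "short": t_short}
        for k in range(1, spec.n_specimens + 1):
            sex = sexes[(k - 1) % len(sexes)]
            specimen = f"{sp}_spec{k}"
            for region in regions:
                label = assignments[sp][region]
                patch_id = f"{sp}_{region}_{k}"
                spectrum = make_spectrum(
                    sp_templates[label],
                    seed=int(noise_root.integers(2**31)),
                    noise_sd=spec.noise_sd,
                )
                rec = PatchRecord(
                    specimen_id=specimen,
                    species=sp,
                    sex=sex,
                    region=region,
                    patch_id=patch_id,
                    spectrum=spectrum,
                    is_black=flag_black(spectrum),
                    clade="synthetic",
                )
                patches.append(rec)
                truth[patch_id] = label
                rows.append(
                    {
                        "specimen_id": specimen,
                        "species": sp,
                        "sex": sex,
                        "region": region,
                        "patch_id": patch_id,
                        "clade": "synthetic",
                        "true_class": label,
                    }
                )
    metadata = pd.DataFrame(rows)
    return CladeSim(
        metadata=metadata,
        patches=patches,
        true_class=pd.Series(truth, name="true_class"),
        tree=tree,
        spec=spec,
    )


def _with_root_distances(tree: dendropy.Tree) -> dendropy.Tree:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return tree


def write_clade(sim: CladeSim, outdir) -> dict:
    """Write a simulated clade to disk in the formats the readers consume.

    Returns the paths written: metadata CSV (with spectrum_path column),
    one two-column CSV per patch, the Newick tree, and the truth table.
    """
    from pathlib import Path

    from .spectra import write_spectrum

    outdir = Path(outdir)
    specdir = outdir / "spectra"
    specdir.mkdir(parents=True, exist_ok=True)
    meta = sim.metadata.copy()
    paths = []
    for rec in sim.patches:
        p = specdir / f"{rec.patch_id}.csv"
        write_spectrum(rec.spectrum, p)
        paths.append(str(p.relative_to(outdir)))
    meta["spectrum_path"] = paths
    meta_path = outdir / "metadata.csv"
    meta.drop(columns=["true_class"]).to_csv(meta_path, index=False)
    truth_path = outdir / "true_classes.csv"
    sim.true_class.rename_axis("patch_id").to_csv(truth_path)
    tree_path = outdir / "tree.nwk"
    sim.tree.write(
        path=str(tree_path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )
    return {
        "metadata": str(meta_path),
        "tree": str(tree_path),
        "truth": str(truth_path),
        "spectra_dir": str(specdir),
    }
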