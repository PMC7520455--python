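"""Complementary-color tests: do taxa hold colors on both sides of gray?

For each distinct taxon the maximum and minimum patch-level color score
(elevation phi) are collected over all its patches (both sexes, matching how
the score histograms are built).  Three tests then ask whether a clade's
colors straddle the achromatic point:

* one-sample t-tests of the maxima and of the minima against a mean of 0,
* a paired two-sample t-test of maxima against minima,

all two-sided, all with n_taxa - 1 degrees of freedom.  A clade whose taxa
each combine a positive-phi and a negative-phi patch (a complementary pair)
shows fraction_opposite = 1 and strongly significant tests of both extremes
on opposite sides of zero; a clade confined to one side of the achromatic
point shows maxima and minima of the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComplementaryReport",
    "extreme_scores",
    "complementary_tests",
    "score_histograms",
]


@dataclass(frozen=True)
class ComplementaryReport:
    """t-test battery over per-taxon extreme color scores."""

    n_taxa: int
    dF: int
    fraction_opposite: float
    t_max: float
    p_max: float
    t_min: float
    p_min: float
    t_paired: float
    p_paired: float
    exact_tie: bool  # any test had zero variance (t infinite, p -> 0)

    def to_dict(self) -> dict:
        return asdict(self)


def extreme_scores(scores: pd.DataFrame, taxon_col: str = "species") -> pd.DataFrame:
    """Per-taxon (max_phi, min_phi) over patch-level scores.

    Taxa whose patches are all achromatic (phi missing throughout, e.g.
    all-black plumage) are dropped with a warning: they have no position in
    chromatic space.
    """
    if scores.empty:
        raise ValueError("empty score table")
    if taxon_col not in scores.columns:
        raise ValueError(f"no {taxon_col!r} column in score table")
    if "phi" not in scores.columns:
        raise ValueError("no 'phi' column in score table")
    grouped = scores.groupby(taxon_col)["phi"]
    out = pd.DataFrame({"max_phi": grouped.max(), "min_phi": grouped.min()})
    dropped = out.index[out["max_phi"].isna()].tolist()
    if dropped:
        warnings.warn(
            f"taxa with no chromatic patches dropped: {dropped}", stacklevel=2
        )
        out = out.dropna()
    if out.empty:
        raise ValueError("no taxon has a chromatic patch")
    return out


def _one_sample_t(x: np.ndarray) -> tuple[float, float, bool]:
    sd = x.std(ddof=1)
    if sd == 0.0:
        mean = x.mean()
        t = np.inf if mean > 0 else (-np.inf if mean < 0 else np.nan)
        return t, 0.0 if mean != 0 else np.nan, True
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue), False


def complementary_tests(extremes: pd.DataFrame) -> ComplementaryReport:
    """Run the three t-tests on a per-taxon extremes table.

    Zero-variance vectors (every taxon with the identical extreme) give an
    infinite t with the ``exact_tie`` flag instead of an exception.
    """
    if not {"max_phi", "min_phi"}.issubset(extremes.columns):
        raise ValueError("extremes table needs max_phi and min_phi columns")
    n = len(extremes)
    if n < 3:
        raise ValueError("need at least 3 taxa for the t-test battery")
    mx = extremes["max_phi"].to_numpy(dtype=float)
    mn = extremes["min_phi"].to_numpy(dtype=float)
    if np.any(mx < mn):
        raise ValueError("max_phi < min_phi for some taxon")
    t_max, p_max, tie1 = _one_sample_t(mx)
    t_min, p_min, tie2 = _one_sample_t(mn)
    t_pair, p_pair, tie3 = _one_sample_t(mx - mn)
    frac = float(np.mean((mx > 0) & (mn < 0)))
    return ComplementaryReport(
        n_taxa=n,
        dF=n - 1,
        fraction_opposite=frac,
        t_max=t_max,
        p_max=p_max,
        t_min=t_min,
        p_min=p_min,
        t_paired=t_pair,
        p_paired=p_pair,
        exact_tie=tie1 or tie2 or tie3,
    )


def score_histograms(extremes: pd.DataFrame, bin_width: float = 0.2) -> pd.DataFrame:
    """Binned counts of per-taxon max and min scores over [-pi/2, +pi/2].

    Bin edges are anchored at 0 so no bin straddles the achromatic point
    (with bin_width = pi the two bins are exactly the sign counts).  Empty
    bins are retained with count 0; each column sums to the number of taxa.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    half = np.pi / 2
    k = int(np.ceil(half / bin_width - 1e-12))
    edges = np.arange(-k, k + 1) * bin_width
    mx = extremes["max_phi"].to_numpy(dtype=float)
    mn = extremes["min_phi"].to_numpy(dtype=float)
    cmax, _ = np.histogram(np.clip(mx, edges[0], edges[-1]), bins=edges)
    cmin, _ = np.histogram(np.clip(mn, edges[0], edges[-1]), bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count_max": cmax,
            "count_min": cmin,
        }
    )
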