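"""Goldsmith's tetrahedral color space and convex-hull color volumes.

Relative quantum catches (u, s, m, l; non-negative, summing to 1) are mapped
into a regular tetrahedron whose vertices are the pure-cone stimuli, all at
distance 0.75 from the centroid, and whose centroid (the achromatic point,
where all cones are excited equally) is the origin:

    x = ((1 - 2s - m - u) / 2) * sqrt(3/2)
    y = (-1 + 3m + u) / (2 * sqrt(2))
    z = u - 1/4

The distance r from the origin measures saturation; the hue direction is
summarized by the azimuth theta_h = atan2(y, x) and elevation
phi_h = asin(z / r).  Color-space occupancy of a group of patches is the
volume of their 3-D convex hull, reported as a percentage of a reference
volume (by default the full tetrahedron, a^3/(6 sqrt 2) ~ 0.2165064 for edge
a = 0.75 sqrt(8/3); a published total-avian-plumage volume may be supplied
instead to mirror the literature convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TETRA_VERTEX_RADIUS",
    "TETRAHEDRON_VOLUME",
    "TetraPoint",
    "VolumeReport",
    "to_tetra",
    "tetra_table",
    "hull_volume",
    "group_volumes",
]

#: Distance of each pure-cone vertex from the achromatic origin.
TETRA_VERTEX_RADIUS = 0.75

#: Volume of the full tetrahedron (edge a = 0.75*sqrt(8/3)): a^3 / (6 sqrt 2).
TETRAHEDRON_VOLUME = (TETRA_VERTEX_RADIUS * np.sqrt(8.0 / 3.0)) ** 3 / (6.0 * np.sqrt(2.0))

#: Degeneracy tolerance: hulls thinner than this volume are reported as flat.
DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class TetraPoint:
    """Cartesian tetrahedral coordinates plus polar hue/saturation summary."""

    x: float
    y: float
    z: float
    r: float
    theta_h: float
    phi_h: float


@dataclass(frozen=True)
class VolumeReport:
    """Convex-hull occupancy of a point cloud in tetrahedral space."""

    hull_volume: float
    reference_volume: float
    pct_of_reference: float
    n_points: int
    degenerate: bool
    reference_label: str = "full tetrahedron"


def to_tetra(rel) -> TetraPoint:
    """Map relative catches (u, s, m, l) to a point in tetrahedral space."""
    rel = np.asarray(rel, dtype=float)
    if rel.shape != (4,):
        raise ValueError("rel must be a length-4 vector (u, s, m, l)")
    if np.any(rel < -1e-12):
        raise ValueError("relative catches must be non-negative")
    if abs(rel.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative catches must sum to 1 (got {rel.sum():.6g})")
    u, s, m, _l = rel
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(1.5)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    r = float(np.sqrt(x * x + y * y + z * z))
    if r > 0:
        theta = float(np.arctan2(y, x))
        phi = float(np.arcsin(z / r))
    else:
        theta = np.nan
        phi = np.nan
    return TetraPoint(float(x), float(y), float(z), r, theta, phi)


def tetra_table(catches: pd.DataFrame) -> pd.DataFrame:
    """Tetrahedral coordinates for every non-black row of a catch table.

    Black rows (NaN relative catches) are kept with NaN coordinates so the
    output aligns row-for-row with the input.
    """
    cols = ["x", "y", "z", "r", "theta_h", "phi_h"]
    out = pd.DataFrame(np.nan, index=catches.index, columns=cols)
    mask = catches[["u", "s", "m", "l"]].notna().all(axis=1)
    for pid, row in catches.loc[mask, ["u", "s", "m", "l"]].iterrows():
        p = to_tetra(row.to_numpy())
        out.loc[pid] = (p.x, p.y, p.z, p.r, p.theta_h, p.phi_h)
    keep = [c for c in ("species", "sex", "region", "is_black") if c in catches.columns]
    return pd.concat([catches[keep], out], axis=1)


def hull_volume(
    points,
    reference_volume: float = TETRAHEDRON_VOLUME,
    reference_label: str = "full tetrahedron",
) -> VolumeReport:
    """Convex-hull volume of a set of (x, y, z) points.

    Fewer than 4 points, or a cloud coplanar within tolerance, yields volume
    0 with the ``degenerate`` flag rather than an exception: a clade whose
    colors sit on a line or plane occupies no volume.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    pts = pts[~np.isnan(pts).any(axis=1)]
    pts = np.unique(pts, axis=0)
    n = pts.shape[0]
    if n < 4:
        return VolumeReport(0.0, reference_volume, 0.0, n, True, reference_label)
    try:
        vol = float(ConvexHull(pts).volume)
    except QhullError:
        vol = 0.0
    degenerate = vol <= DEGENERACY_TOL
    if degenerate:
        vol = 0.0
    pct = 100.0 * vol / reference_volume
    return VolumeReport(vol, reference_volume, pct, n, degenerate, reference_label)


def group_volumes(
    tetra: pd.DataFrame,
    by,
    reference_volume: float = TETRAHEDRON_VOLUME,
    reference_label: str = "full tetrahedron",
) -> pd.DataFrame:
    """One VolumeReport row per group (e.g. per genus or per sex).

    ``by`` is a column name or list of column names present in the
    tetrahedral table.
    """
    by = [by] if isinstance(by, str) else list(by)
    for c in by:
        if c not in tetra.columns:
            raise ValueError(f"grouping column {c!r} not in table")
    rows = []
    for key, grp in tetra.groupby(by, sort=True, dropna=False):
        rep = hull_volume(
            grp[["x", "y", "z"]].to_numpy(), reference_volume, reference_label
        )
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(by, key)),
                "hull_volume": rep.hull_volume,
                "reference_volume": rep.reference_volume,
                "pct_of_reference": rep.pct_of_reference,
                "n_points": rep.n_points,
                "degenerate": rep.degenerate,
                "reference": rep.reference_label,
            }
        )
    return pd.DataFrame(rows)
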