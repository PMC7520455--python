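"""Reading, validation and resampling of plumage reflectance spectra.

Spectra are two-column delimited text files (wavelength in nm, reflectance
either as a proportion 0-1 or percent 0-100; units are inferred unless a hint
is given).  All downstream computation happens on the canonical 300-700 nm,
1 nm grid spanning the avian-visible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "STANDARD_REGIONS",
    "EXTENDED_REGIONS",
    "ReflectanceSpectrum",
    "PatchRecord",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "flag_black",
    "read_metadata",
    "load_patches",
]

#: 300-700 nm at 1 nm: 401 samples.
CANONICAL_GRID = np.arange(300.0, 701.0)

#: The seven body regions used to partition a bird's plumage.
STANDARD_REGIONS = (
    "crown",
    "cheek",
    "throat",
    "upperparts",
    "wing",
    "tail",
    "underparts",
)

#: Parakeet-style layouts additionally allow the undertail.
EXTENDED_REGIONS = STANDARD_REGIONS + ("undertail",)

#: Mean-reflectance threshold under which a patch is treated as black.
DEFAULT_BLACK_THRESHOLD = 0.02


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files or metadata tables."""


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A reflectance spectrum for one plumage patch.

    Attributes
    ----------
    wavelengths : ndarray
        Strictly increasing wavelengths in nm.
    reflectance : ndarray
        Reflectance as proportions in [0, 1], same length as ``wavelengths``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or r.ndim != 1 or wl.size != r.size:
            raise SpectrumFormatError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise SpectrumFormatError("reflectance contains non-finite values")
        if np.any(r < 0):
            raise SpectrumFormatError("reflectance contains negative values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)

    @property
    def on_canonical_grid(self) -> bool:
        return self.wavelengths.size == CANONICAL_GRID.size and np.array_equal(
            self.wavelengths, CANONICAL_GRID
        )

    def mean_reflectance(self) -> float:
        return float(np.mean(self.reflectance))


@dataclass
class PatchRecord:
    """One measured color patch with its provenance metadata."""

    specimen_id: str
    species: str
    sex: str
    region: str
    patch_id: str
    spectrum: ReflectanceSpectrum | None = None
    is_black: bool = False
    clade: str | None = None
    extra: dict = field(default_factory=dict)


def _parse_two_columns(path) -> np.ndarray:
    """Parse a two-column numeric text file, tolerating an optional header."""
    text = Path(path).read_text()
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").replace(";", " ").replace("\t", " ").split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}: line {lineno} has fewer than 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1 and not rows:
                continue  # header line
            raise SpectrumFormatError(
                f"{path}: non-numeric value on line {lineno}: {line!r}"
            ) from None
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 numeric samples")
    return np.asarray(rows, dtype=float)


def read_spectrum(path, unit_hint: str = "auto") -> ReflectanceSpectrum:
    """Read a two-column (wavelength, reflectance) text file.

    Parameters
    ----------
    path : path-like
        Delimited text file; comma, semicolon, tab or whitespace separated,
        optional single header line, ``#`` comments ignored.
    unit_hint : {"auto", "percent", "proportion"}
        ``auto`` infers percent when the maximum value exceeds 1.5 and
        divides by 100; the other values force the interpretation.

    Returns
    -------
    ReflectanceSpectrum
        Proportions in [0, 1], wavelengths sorted ascending, duplicate
        wavelengths averaged.
    """
    if unit_hint not in ("auto", "percent", "proportion"):
        raise ValueError(f"unknown unit_hint {unit_hint!r}")
    data = _parse_two_columns(path)
    order = np.argsort(data[:, 0], kind="stable")
    wl, r = data[order, 0], data[order, 1]
    if np.any(r < 0):
        raise SpectrumFormatError(f"{path}: negative reflectance values")
    # average duplicated wavelengths
    uniq, inv = np.unique(wl, return_inverse=True)
    if uniq.size != wl.size:
        sums = np.bincount(inv, weights=r)
        counts = np.bincount(inv)
        wl, r = uniq, sums / counts
    if unit_hint == "percent" or (unit_hint == "auto" and np.max(r) > 1.5):
        r = r / 100.0
    if np.any(r > 1.0 + 1e-9):
        raise SpectrumFormatError(
            f"{path}: reflectance exceeds 1 after unit inference (max {np.max(r):.3g}); "
            "pass unit_hint='percent' if the file is in percent"
        )
    return ReflectanceSpectrum(wl, np.clip(r, 0.0, 1.0))


def write_spectrum(spectrum: ReflectanceSpectrum, path) -> None:
    """Write a spectrum as two-column CSV with a header (proportions)."""
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "reflectance": spectrum.reflectance}
    )
    df.to_csv(path, index=False, float_format="%.8g")


def resample(
    spectrum: ReflectanceSpectrum,
    grid: np.ndarray | None = None,
    margin: float = 5.0,
) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto a uniform grid (default canonical).

    The spectrum must cover the grid within ``margin`` nm at each end; the
    uncovered edge (at most ``margin`` nm) is filled by holding the nearest
    measured value.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 300.0 - 1e-9 or grid[-1] > 700.0 + 1e-9:
        raise ValueError("grid outside the supported 300-700 nm range")
    wl = spectrum.wavelengths
    lo_gap = wl[0] - grid[0]
    hi_gap = grid[-1] - wl[-1]
    if lo_gap > margin or hi_gap > margin:
        missing = []
        if lo_gap > margin:
            missing.append(f"{grid[0]:g}-{wl[0]:g} nm")
        if hi_gap > margin:
            missing.append(f"{wl[-1]:g}-{grid[-1]:g} nm")
        raise SpectrumFormatError(
            "spectrum does not cover the target grid; missing " + ", ".join(missing)
        )
    # np.interp holds edge values, implementing the edge-hold margin fill
    r = np.interp(grid, wl, spectrum.reflectance)
    return ReflectanceSpectrum(grid, r)


def flag_black(spectrum: ReflectanceSpectrum, threshold: float = DEFAULT_BLACK_THRESHOLD) -> bool:
    """True iff mean reflectance over the grid is below ``threshold``.

    Black patches carry essentially no chromatic information and museum-skin
    noise can inflate their relative catches, so they are special-cased
    downstream (excluded from chromatic space, kept for luminance).
    """
    return spectrum.mean_reflectance() < threshold


_REQUIRED_COLUMNS = ("specimen_id", "species", "sex", "region", "patch_id")


def read_metadata(path, allow_undertail: bool = False) -> pd.DataFrame:
    """Read a patch-metadata table (CSV/TSV).

    Required columns: specimen_id, species, sex, region, patch_id; optional:
    spectrum_path, clade.  Unknown extra columns are preserved.  Regions must
    come from the seven standard regions (plus ``undertail`` when
    ``allow_undertail``).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=str.strip)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"metadata missing required columns: {missing}")
    allowed = set(EXTENDED_REGIONS if allow_undertail else STANDARD_REGIONS)
    bad = sorted(set(df["region"]) - allowed)
    if bad:
        raise SpectrumFormatError(
            f"unknown body regions {bad}; allowed: {sorted(allowed)}"
        )
    bad_sex = sorted(set(df["sex"]) - {"M", "F", "U"})
    if bad_sex:
        raise SpectrumFormatError(f"sex must be M, F or U; got {bad_sex}")
    if df["patch_id"].duplicated().any():
        dups = df.loc[df["patch_id"].duplicated(), "patch_id"].tolist()
        raise SpectrumFormatError(f"duplicate patch_id values: {dups[:5]}")
    return df


def load_patches(
    metadata: pd.DataFrame,
    base_dir=None,
    unit_hint: str = "auto",
    black_threshold: float = DEFAULT_BLACK_THRESHOLD,
) -> list[PatchRecord]:
    """Materialize PatchRecords from a metadata table with spectrum_path column.

    Spectra are read, resampled to the canonical grid and black-flagged.
    """
    if "spectrum_path" not in metadata.columns:
        raise SpectrumFormatError("metadata has no spectrum_path column")
    base = Path(base_dir) if base_dir is not None else Path(".")
    records = []
    for row in metadata.itertuples(index=False):
        spath = Path(row.spectrum_path)
        if not spath.is_absolute():
            spath = base / spath
        spec = resample(read_spectrum(spath, unit_hint=unit_hint))
        records.append(
            PatchRecord(
                specimen_id=row.specimen_id,
                species=row.species,
                sex=row.sex,
                region=row.region,
                patch_id=row.patch_id,
                spectrum=spec,
                is_black=flag_black(spec, black_threshold),
                clade=getattr(row, "clade", None),
            )
        )
    return records
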