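"""End-to-end orchestration: spectra -> catches -> color spaces -> reports.

A single :class:`RunConfig` drives all stages in order

    io -> catches -> tetra -> rnl -> axis -> complementary -> phylo

writing plain CSV/JSON artifacts per stage plus a run manifest (parameters,
seeds, package version, SHA-256 checksums of every output).  The phylo
stage is skipped with an explicit notice when no tree is configured; reruns
with the same config and seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import axes as axes_mod
from . import complementary as comp_mod
from . import phylo as phylo_mod
from . import rnl as rnl_mod
from . import spectra as spectra_mod
from . import tetra as tetra_mod
from . import visual as visual_mod

__all__ = ["RunConfig", "StageError", "run_all", "report"]

log = logging.getLogger("tetrachroma")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a full run needs, with documented defaults."""

    clade: str = "clade"
    metadata: str | None = None  # patch metadata CSV (with spectrum_path)
    spectra_dir: str | None = None  # base dir for relative spectrum paths
    tree: str | None = None  # Newick; phylo stage skipped if absent
    output_dir: str = "tetrachroma_run"
    visual_system: str = "UVS"
    weber: list | None = None  # default Leiothrix-like
    black_threshold: float = spectra_mod.DEFAULT_BLACK_THRESHOLD
    reference_volume: float = tetra_mod.TETRAHEDRON_VOLUME
    reference_label: str = "full tetrahedron"
    group_by: list = field(default_factory=lambda: ["sex"])  # volume grouping
    taxon_col: str = "species"  # grouping for extreme scores
    sex_filter: str = "male_only"  # for the clade dataset / phylo stage
    allow_undertail: bool = False
    unit_hint: str = "auto"
    n_rand: int = 1000  # lambda randomizations
    n_perm: int = 999  # Mantel permutations
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and np.isnan(x):
        return None
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_all(config: RunConfig, patches=None, tree=None) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    ``patches`` (list of PatchRecord) and ``tree`` may be passed in memory,
    e.g. straight from the synthetic generator; otherwise they are read
    from the configured paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "tetrachroma",
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
    }
    t_start = time.perf_counter()

    def _finish(stage: str, files: dict) -> None:
        manifest["stages"].append(stage)
        for name, p in files.items():
            manifest["outputs"][name] = {
                "path": str(p),
                "sha256": _sha256(Path(p)),
            }
        log.info("stage %-13s done (%.2fs)", stage, time.perf_counter() - t_start)

    # --- io ----------------------------------------------------------------
    try:
        if patches is None:
            if config.metadata is None:
                raise ValueError("no metadata path configured and no patches supplied")
            meta = spectra_mod.read_metadata(
                config.metadata, allow_undertail=config.allow_undertail
            )
            patches = spectra_mod.load_patches(
                meta,
                base_dir=config.spectra_dir or Path(config.metadata).parent,
                unit_hint=config.unit_hint,
                black_threshold=config.black_threshold,
            )
        patch_df = pd.DataFrame(
            [
                {
                    "patch_id": p.patch_id,
                    "specimen_id": p.specimen_id,
                    "species": p.species,
                    "sex": p.sex,
                    "region": p.region,
                    "clade": p.clade,
                    "is_black": p.is_black,
                    "mean_reflectance": p.spectrum.mean_reflectance(),
                }
                for p in patches
            ]
        ).set_index("patch_id")
        f = outdir / "patches.csv"
        _write_csv(patch_df, f)
        _finish("io", {"patches": f})
    except StageError:
        raise
    except Exception as e:
        raise StageError("io", str(e)) from e

    # --- catches -----------------------------------------------------------
    try:
        vs = visual_mod.build_visual_system(
            system=config.visual_system, weber=config.weber
        )
        catches = visual_mod.catch_table(patches, vs)
        f = outdir / "catches.csv"
        _write_csv(catches, f)
        _finish("catches", {"catches": f})
    except Exception as e:
        raise StageError("catches", str(e)) from e

    # --- tetra -------------------------------------------------------------
    try:
        tetra = tetra_mod.tetra_table(catches)
        vols = tetra_mod.group_volumes(
            tetra.dropna(subset=["x"]),
            by=[c for c in config.group_by if c in tetra.columns] or ["species"],
            reference_volume=config.reference_volume,
            reference_label=config.reference_label,
        )
        overall = tetra_mod.hull_volume(
            tetra[["x", "y", "z"]].to_numpy(),
            config.reference_volume,
            config.reference_label,
        )
        f1, f2 = outdir / "tetra.csv", outdir / "volumes.csv"
        _write_csv(tetra, f1)
        _write_csv(vols, f2, index=False)
        f3 = outdir / "volume_overall.json"
        _write_json(dataclasses.asdict(overall), f3)
        _finish("tetra", {"tetra": f1, "volumes": f2, "volume_overall": f3})
    except Exception as e:
        raise StageError("tetra", str(e)) from e

    # --- rnl ---------------------------------------------------------------
    try:
        weber = np.asarray(config.weber, float) if config.weber else visual_mod.DEFAULT_WEBER
        xyz = rnl_mod.xyz_from_catches(catches, weber)
        xyz = rnl_mod.achromatic_origin(xyz, weber)
        f = outdir / "xyz.csv"
        _write_csv(xyz, f)
        _finish("rnl", {"xyz": f})
    except Exception as e:
        raise StageError("rnl", str(e)) from e

    # --- axis --------------------------------------------------------------
    try:
        axis = axes_mod.pca_axis(xyz.dropna(subset=["X"]))
        scores = axes_mod.spherical_scores(xyz)
        scores["specimen_id"] = catches["specimen_id"]
        dataset = axes_mod.aggregate_scores(scores, sex_filter=config.sex_filter)
        f1 = outdir / "axis_report.json"
        _write_json(
            {
                "pc1_loadings": axis.pc1_loadings,
                "pc_variance_fractions": axis.pc_variance_fractions,
                "centering": axis.centering,
                "azimuthal_variance_fraction": axis.azimuthal_variance_fraction,
                "degenerate": axis.degenerate,
            },
            f1,
        )
        f2 = outdir / "scores.csv"
        _write_csv(scores, f2)
        files = {"axis_report": f1, "scores": f2}
        for name, df in (
            ("clade_color", dataset.color),
            ("clade_luminance", dataset.luminance),
            ("clade_counts", dataset.counts),
        ):
            p = outdir / f"{name}.csv"
            _write_csv(df, p)
            files[name] = p
        _finish("axis", files)
    except Exception as e:
        raise StageError("axis", str(e)) from e

    # --- complementary -----------------------------------------------------
    try:
        extremes = comp_mod.extreme_scores(scores, taxon_col=config.taxon_col)
        ctests = comp_mod.complementary_tests(extremes)
        hist = comp_mod.score_histograms(extremes)
        f1, f2, f3 = (
            outdir / "extreme_scores.csv",
            outdir / "complementary_tests.json",
            outdir / "score_histograms.csv",
        )
        _write_csv(extremes, f1)
        _write_json(ctests.to_dict(), f2)
        _write_csv(hist, f3, index=False)
        _finish(
            "complementary",
            {"extreme_scores": f1, "complementary_tests": f2, "score_histograms": f3},
        )
    except Exception as e:
        raise StageError("complementary", str(e)) from e

    # --- phylo -------------------------------------------------------------
    if tree is None and config.tree is None:
        manifest["stages"].append("phylo:skipped")
        manifest["notices"] = ["phylo stage skipped: no tree configured"]
        log.info("stage phylo skipped (no tree)")
    else:
        try:
            if tree is None:
                tree = phylo_mod.read_tree(config.tree)
            table = phylo_mod.signal_table(
                dataset,
                tree,
                n_rand=config.n_rand,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            f = outdir / "signal_table.csv"
            _write_csv(table, f, index=False)
            _finish("phylo", {"signal_table": f})
        except Exception as e:
            raise StageError("phylo", str(e)) from e

    mpath = outdir / "manifest.json"
    _write_json(manifest, mpath)
    return manifest


def report(output_dir) -> str:
    """Human-readable per-clade summary from run_all outputs."""
    outdir = Path(output_dir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    cfg = manifest["config"]
    lines = [
        f"tetrachroma {manifest['version']} — clade report: {cfg['clade']}",
        f"visual system: {cfg['visual_system']}, seed {cfg['seed']}",
        "",
    ]
    overall = json.loads((outdir / "volume_overall.json").read_text())
    lines += [
        "[color-volume occupancy]",
        f"  hull volume {overall['hull_volume']:.6f} tetra-units "
        f"= {overall['pct_of_reference']:.2f}% of {overall['reference_label']} "
        f"({overall['n_points']} points)",
    ]
    vols = pd.read_csv(outdir / "volumes.csv")
    for _, r in vols.iterrows():
        key = " ".join(
            str(r[c]) for c in vols.columns
            if c not in ("hull_volume", "reference_volume", "pct_of_reference",
                         "n_points", "degenerate", "reference")
        )
        lines.append(
            f"  group {key}: {r['pct_of_reference']:.2f}% ({int(r['n_points'])} points)"
            + (" [degenerate]" if r["degenerate"] else "")
        )
    axis = json.loads((outdir / "axis_report.json").read_text())
    pc1 = axis["pc_variance_fractions"][0]
    lines += [
        "",
        "[major chromatic axis]",
        f"  PC1 explains {100 * pc1:.1f}% of chromatic variance; "
        f"loadings (X, Y, Z) = ({', '.join(f'{v:.3f}' for v in axis['pc1_loadings'])})",
        f"  azimuthal (XY) variance fraction: {axis['azimuthal_variance_fraction']:.3f}",
    ]
    scores = pd.read_csv(outdir / "scores.csv")
    phi = scores["phi"].dropna()
    lines += [
        "",
        "[color scores]",
        f"  elevation phi spans {phi.min():+.2f} to {phi.max():+.2f} rad "
        f"over {len(phi)} chromatic patches",
    ]
    ct = json.loads((outdir / "complementary_tests.json").read_text())
    lines += [
        "",
        "[complementary-color tests]",
        f"  {ct['n_taxa']} taxa (dF={ct['dF']}); fraction with opposite-sign "
        f"extremes: {ct['fraction_opposite']:.2f}",
        f"  one-sample t (max vs 0): t={ct['t_max']:.2f}, P={ct['p_max']:.3g}",
        f"  one-sample t (min vs 0): t={ct['t_min']:.2f}, P={ct['p_min']:.3g}",
        f"  paired t (max vs min):   t={ct['t_paired']:.2f}, P={ct['p_paired']:.3g}",
    ]
    lines += ["", "[phylogenetic signal]"]
    sig_path = outdir / "signal_table.csv"
    if "phylo" in manifest["stages"] and sig_path.exists():
        sig = pd.read_csv(sig_path)
        for _, r in sig.iterrows():
            if r.get("flag") == "insufficient":
                lines.append(f"  {r['trait']:9s} {r['region']:11s} insufficient species")
                continue
            lines.append(
                f"  {r['trait']:9s} {r['region']:11s} lambda={r['lambda_hat']:.3f} "
                f"(P={r['p_lambda']:.3g})  Mantel r={r['mantel_r']:+.3f} "
                f"(P={r['p_mantel']:.3g})  CV={r['cv']:.2f}  n={int(r['n_species'])}"
            )
    else:
        lines.append("  not run (no tree configured)")
    return "\n".join(lines) + "\n"
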