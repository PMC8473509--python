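"""Volume and table I/O, study configuration, end-to-end protocol runner.

Volumes travel as NIfTI-1 files (mm units, RAS-like axes) with a JSON
sidecar carrying provenance (phantom spec, acquisition/reconstruction
settings, seeds).  Sinograms are NIfTI arrays with axes (view, bin-row,
bin-col) and the view angles in the sidecar.  Tables are plain UTF-8 CSV
with a header row, '.' decimals and LF endings; RC/Q/COV columns render
with two decimals and p-values with three, matching the report style.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionConfig, EnergyWindowModel, ProjectionSet
from .phantom import PhantomSpec, VoxelPhantom, build_phantom
from .projector import PSFModel
from .recon import ReconConfig, ReconVolume

log = logging.getLogger("spectiq")

_TWO_DP = ("RC", "Q", "COV", "rc", "contrast", "cov")
_THREE_DP = ("p", "pvalue", "r_pvalue", "ttest_p")


class FormatError(ValueError):
    """Malformed or unsupported volume file."""


def _affine(voxel_size) -> np.ndarray:
    a = np.diag([*voxel_size, 1.0])
    return a


def write_volume(path: str | Path, values: np.ndarray, voxel_size, sidecar: dict | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(voxel_size))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    if sidecar is not None:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=_jsonable) + "\n"
        )
    return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], dict]:
    """Load a NIfTI volume: (values, voxel size in mm, sidecar dict).

    Raises FormatError for non-3-D data or non-finite voxel sizes.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as e:  # nibabel raises several header error types
        raise FormatError(f"cannot read {path}: {e}") from e
    if values.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {values.ndim}-D in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(zooms)) or any(z <= 0 for z in zooms):
        raise FormatError(f"bad voxel sizes {zooms} in {path}")
    sidecar = {}
    sc = path.with_suffix("").with_suffix(".json")
    if sc.exists():
        sidecar = json.loads(sc.read_text())
    return values, zooms, sidecar


def write_phantom(phantom: VoxelPhantom, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = phantom.spec.voxel_size
    sidecar = {"phantom_spec": phantom.spec.to_dict()}
    write_volume(out / "activity.nii", phantom.activity, vs, sidecar)
    write_volume(out / "mu.nii", phantom.mu_map, vs)
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), _affine(vs))
    nib.save(img, str(out / "labels.nii"))
    return out


def read_phantom(in_dir: str | Path) -> VoxelPhantom:
    in_dir = Path(in_dir)
    activity, vs, sidecar = read_volume(in_dir / "activity.nii")
    mu, _, _ = read_volume(in_dir / "mu.nii")
    labels = np.asarray(nib.load(str(in_dir / "labels.nii")).dataobj).astype(np.int16)
    spec = PhantomSpec.from_dict(sidecar["phantom_spec"])
    return VoxelPhantom(activity=activity, mu_map=mu, labels=labels, spec=spec)


def write_projections(proj: ProjectionSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = proj.config
    sidecar = {
        "view_angles": proj.view_angles.tolist(),
        "config": dataclasses.asdict(cfg),
    }
    vs = (cfg.bin_size, cfg.bin_size, cfg.bin_size)
    write_volume(out / "photopeak.nii", proj.photopeak_counts, vs, sidecar)
    write_volume(out / "scatterwin.nii", proj.scatterwin_counts, vs)
    return out


def read_projections(in_dir: str | Path) -> ProjectionSet:
    in_dir = Path(in_dir)
    pp, _, sidecar = read_volume(in_dir / "photopeak.nii")
    sw, _, _ = read_volume(in_dir / "scatterwin.nii")
    c = sidecar["config"]
    window = EnergyWindowModel(
        **{
            **c["window"],
            "scatter_fraction_by_window": {
                float(k): v for k, v in c["window"]["scatter_fraction_by_window"].items()
            },
        }
    )
    cfg = AcquisitionConfig(
        n_views=c["n_views"],
        arc_deg=c["arc_deg"],
        time_per_frame=c["time_per_frame"],
        matrix=c["matrix"],
        bin_size=c["bin_size"],
        sensitivity=c["sensitivity"],
        psf_model=PSFModel(**c["psf_model"]),
        scatter_kernel_sigma=c["scatter_kernel_sigma"],
        scatterwin_to_photopeak_ratio=c["scatterwin_to_photopeak_ratio"],
        window=window,
        seed=c["seed"],
    )
    return ProjectionSet(
        photopeak_counts=pp.astype(np.int64),
        scatterwin_counts=sw.astype(np.int64),
        view_angles=np.asarray(sidecar["view_angles"]),
        config=cfg,
    )


def write_recon(vol: ReconVolume, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"recon_config": dataclasses.asdict(vol.recon_config)}
    if vol.acquisition is not None:
        sidecar["acquisition"] = dataclasses.asdict(vol.acquisition)
    write_volume(out / "recon.nii", vol.values, vol.voxel_size, sidecar)
    return out


def _format_value(col: str, v) -> str:
    if isinstance(v, (float, np.floating)):
        if col in _THREE_DP or col.endswith("_p") or col.endswith("pvalue"):
            return f"{v:.3f}"
        if col in _TWO_DP or col in ("mean", "sd"):
            return f"{v:.2f}"
        if col in ("slope", "intercept", "pearson_r"):
            return f"{v:.4f}"
        return repr(float(v))
    return str(v)


def write_tables(records: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Deterministic CSV: fixed column order, fixed precision, LF endings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame.from_records(records)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(map(str, records.columns)) + "\n")
        for _, row in records.iterrows():
            fh.write(",".join(_format_value(c, row[c]) for c in records.columns) + "\n")
    return path


@dataclass
class StudyConfig:
    """Whole-protocol configuration; YAML-round-trippable."""

    tb_ratios: tuple[float, ...] = (32.0, 4.0)
    global_seed: int = 0
    out_dir: str = "study_out"
    voxel_mm: float = 5.5
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    iterations_grid: tuple[int, ...] = (1, 2, 5, 10, 20, 35, 50, 70, 90)
    subsets_grid: tuple[int, ...] = (2, 6, 10, 20, 30)
    fwhm_grid: tuple[float, ...] = (0.7, 2.0, 4.0, 6.0, 6.99)
    corrections_grid: tuple[str, ...] = ("AC+SC+RR", "AC+RR", "AC+SC")
    window_grid: tuple[float, ...] = (0.075, 0.10)
    time_grid: tuple[float, ...] = (5.0, 10.0, 40.0, 120.0)
    n_seeds: int = 1
    verbosity: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text)
        for k in (
            "tb_ratios",
            "iterations_grid",
            "subsets_grid",
            "fwhm_grid",
            "corrections_grid",
            "window_grid",
            "time_grid",
            "grid_shape",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def run_study(config: StudyConfig) -> dict[str, Path]:
    """Execute the six-step sequential protocol end to end.

    Each step sweeps one parameter with the previous steps' optima frozen,
    logs the chosen optimum, and writes its records/statistics CSVs.  The
    run is deterministic for a given (config, global_seed).
    """
    from .sweep import PROTOCOL_START, SweepConfig, SweepResult, run_sweep, report_tables

    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = tuple(
        int(s) % (2**31)
        for s in np.random.SeedSequence(config.global_seed).generate_state(config.n_seeds)
    )
    fixed = dict(PROTOCOL_START)
    desk_kwargs = dict(voxel_mm=config.voxel_mm, grid_shape=config.grid_shape)
    steps = [
        ("iterations", config.iterations_grid),
        ("subsets", config.subsets_grid),
        ("fwhm", config.fwhm_grid),
        ("corrections", config.corrections_grid),
        ("window", config.window_grid),
        ("time", config.time_grid),
    ]
    sweeps: dict[str, SweepResult] = {}
    manifest = {"global_seed": config.global_seed, "seeds": list(seeds), "steps": {}}
    for name, grid in steps:
        log.info("step %s: grid=%s fixed=%s seeds=%s", name, grid, fixed, seeds)
        sc = SweepConfig(
            parameter=name,
            grid=tuple(grid),
            tb_ratios=config.tb_ratios,
            seeds=seeds,
            fixed=dict(fixed),
        )
        sw = run_sweep(sc, desk_kwargs=desk_kwargs)
        sweeps[name] = sw
        opt = _choose_optimum(name, sw, fixed)
        if opt is not None:
            fixed[name] = opt
        manifest["steps"][name] = {"grid": list(grid), "optimum": opt, "fixed": dict(fixed)}
        log.info("step %s: optimum=%s", name, opt)
    files = report_tables(sweeps, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")
    return {"out_dir": out, "files": files, "manifest": out / "manifest.json"}


def _choose_optimum(name: str, sweep, fixed: dict):
    """Mean-RC-closest-to-100 optimum per step; no filter wins the fwhm step
    (a post-filter only ever lowers RC)."""
    rec = sweep.records
    if name == "fwhm":
        return None
    mean_rc = rec.groupby("value")["RC"].mean()
    err = (mean_rc - 100.0).abs()
    return err.idxmin()
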