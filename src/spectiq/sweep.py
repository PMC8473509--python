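"""Sequential parameter-sweep protocol and its statistics.

The study protocol evaluates one acquisition/reconstruction parameter at a
time — iterations, subsets, post-filter FWHM, correction combination,
photopeak energy window, acquisition time per frame — with every other
parameter frozen (starting point: 6 subsets, no filter, AC+SC+RR, 120
s/frame, 15% window), picking an optimum at each step before moving on.
``run_sweep`` executes simulate -> reconstruct -> quantify over one such
grid, reusing the simulated projections wherever the swept parameter allows
it, and attaches per-sphere correlation/regression statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .acquisition import AcquisitionConfig, ProjectionSet, rebin_time, simulate
from .phantom import FILL_CONCENTRATIONS, PhantomSpec, VoxelPhantom, build_phantom, desk_spec
from .quantify import place_background_rois, quantify
from .recon import OSEMModel, ReconConfig, ReconVolume, gaussian_postfilter

SWEEPABLE = ("iterations", "subsets", "fwhm", "corrections", "window", "time")

#: Protocol starting point: the fixed context before any step's optimum is frozen.
PROTOCOL_START = dict(
    iterations=35,
    subsets=6,
    fwhm=None,
    corrections="AC+SC+RR",
    window=0.075,
    time=120.0,
)


@dataclass
class SweepConfig:
    """One sweep step: which parameter, over which grid, in which context."""

    parameter: str
    grid: tuple
    tb_ratios: tuple[float, ...] = (32.0,)
    seeds: tuple[int, ...] = (0,)
    fixed: dict = field(default_factory=lambda: dict(PROTOCOL_START))
    phantom_builder: object = desk_spec  # callable(tb_ratio, sphere_concentration)
    noise: bool = True
    scatter: bool = True
    convergence_window: int = 10
    convergence_tol: float = 1.0  # percentage points

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if len(self.grid) == 0:
            raise ValueError("empty sweep grid")
        missing = set(PROTOCOL_START) - set(self.fixed)
        if missing:
            raise ValueError(f"fixed context incomplete, missing {sorted(missing)}")


@dataclass
class SweepResult:
    """Long-format RC records plus per-(ratio, sphere) statistics."""

    config: SweepConfig
    records: pd.DataFrame  # tb_ratio, sphere_mm, value, seed, RC, Q, COV, mean, sd
    stats: pd.DataFrame | None  # tb_ratio, sphere_mm, pearson_r, r_pvalue, slope, intercept

    def rc_curve(self, tb_ratio: float, sphere_mm: float, seed: int | None = None) -> pd.DataFrame:
        r = self.records
        m = (r.tb_ratio == tb_ratio) & (r.sphere_mm == sphere_mm)
        if seed is not None:
            m &= r.seed == seed
        return r[m].sort_values("value")[["value", "RC"]]


def _base_recon_config(fixed: dict) -> ReconConfig:
    return ReconConfig.with_corrections(
        fixed["corrections"],
        iterations=int(fixed["iterations"]),
        subsets=int(fixed["subsets"]),
        post_filter_fwhm=fixed["fwhm"],
    )


def _base_acq_config(fixed: dict, seed: int) -> AcquisitionConfig:
    acq = AcquisitionConfig(seed=seed)
    acq = dataclasses.replace(
        acq,
        time_per_frame=float(fixed["time"]),
        window=acq.window.with_width(float(fixed["window"])),
    )
    return acq


def _simulate(phantom: VoxelPhantom, acq: AcquisitionConfig, cfg: SweepConfig) -> ProjectionSet:
    return simulate(phantom, acq, noise=cfg.noise, scatter=cfg.scatter)


def _quant_rows(
    volume: ReconVolume | np.ndarray,
    phantom: VoxelPhantom,
    rois,
    tb_ratio: float,
    value,
    seed: int,
) -> list[dict]:
    q = quantify(volume, phantom, rois=rois)
    rows = []
    for _, r in q.rows.iterrows():
        rows.append(
            dict(
                tb_ratio=tb_ratio,
                sphere_mm=r["diameter_mm"],
                value=value,
                seed=seed,
                RC=r["RC"],
                Q=r["Q"],
                COV=r["COV"],
                mean=r["mean"],
                sd=r["sd"],
            )
        )
    return rows


def run_sweep(config: SweepConfig, desk_kwargs: dict | None = None) -> SweepResult:
    """Execute one sweep step over its grid for every T/B ratio and seed.

    Shared work is cached per (ratio, seed): the iterations sweep runs one
    reconstruction and records the recovery curve with a per-iteration
    callback; the fwhm sweep filters one unfiltered reconstruction; the time
    sweep thins one full-length acquisition.
    """
    desk_kwargs = desk_kwargs or {}
    records: list[dict] = []
    for tb in config.tb_ratios:
        conc = FILL_CONCENTRATIONS.get(float(tb), 0.20 / (tb / 32.0))
        spec: PhantomSpec = config.phantom_builder(tb, conc, **desk_kwargs)
        phantom = build_phantom(spec)
        rois = place_background_rois(phantom)
        for seed in config.seeds:
            records.extend(
                _run_one(phantom, rois, tb, seed, config)
            )
    rec = pd.DataFrame.from_records(records)
    stats_df = None
    if config.parameter in ("iterations", "subsets", "fwhm", "time"):
        stats_df = sweep_statistics(rec)
    return SweepResult(config=config, records=rec, stats=stats_df)


def _run_one(phantom, rois, tb, seed, cfg: SweepConfig) -> list[dict]:
    fixed = cfg.fixed
    base_recon = _base_recon_config(fixed)
    param = cfg.parameter
    rows: list[dict] = []

    def recon_rows(projections, rcfg, value):
        model = OSEMModel(projections, phantom.mu_map, rcfg, phantom.spec.voxel_size)
        vol = model.fit().volume
        return _quant_rows(vol, phantom, rois, tb, value, seed)

    if param == "iterations":
        acq = _base_acq_config(fixed, seed)
        proj = _simulate(phantom, acq, cfg)
        grid = sorted(int(g) for g in cfg.grid)
        rcfg = dataclasses.replace(base_recon, iterations=max(grid))
        model = OSEMModel(proj, phantom.mu_map, rcfg, phantom.spec.voxel_size)
        it_counter = {"n": 0}
        wanted = set(grid)

        def cb(x):
            it_counter["n"] += 1
            if it_counter["n"] in wanted:
                vol = ReconVolume(x.copy(), phantom.spec.voxel_size, rcfg, proj.config)
                if fixed["fwhm"]:
                    vol = gaussian_postfilter(vol, fixed["fwhm"])
                rows.extend(_quant_rows(vol, phantom, rois, tb, it_counter["n"], seed))

        model.fit(callback=cb)
    elif param == "subsets":
        acq = _base_acq_config(fixed, seed)
        proj = _simulate(phantom, acq, cfg)
        for nsub in cfg.grid:
            rcfg = dataclasses.replace(base_recon, subsets=int(nsub))
            rows.extend(recon_rows(proj, rcfg, int(nsub)))
    elif param == "fwhm":
        acq = _base_acq_config(fixed, seed)
        proj = _simulate(phantom, acq, cfg)
        rcfg = dataclasses.replace(base_recon, post_filter_fwhm=None)
        model = OSEMModel(proj, phantom.mu_map, rcfg, phantom.spec.voxel_size)
        unfiltered = model.fit().volume
        for f in cfg.grid:
            vol = gaussian_postfilter(unfiltered, float(f))
            rows.extend(_quant_rows(vol, phantom, rois, tb, float(f), seed))
    elif param == "corrections":
        acq = _base_acq_config(fixed, seed)
        proj = _simulate(phantom, acq, cfg)
        for combo in cfg.grid:
            rcfg = ReconConfig.with_corrections(
                combo,
                iterations=base_recon.iterations,
                subsets=base_recon.subsets,
                post_filter_fwhm=base_recon.post_filter_fwhm,
            )
            rows.extend(recon_rows(proj, rcfg, combo))
    elif param == "window":
        for w in cfg.grid:
            acq = _base_acq_config({**fixed, "window": float(w)}, seed)
            proj = _simulate(phantom, acq, cfg)
            rows.extend(recon_rows(proj, base_recon, float(w)))
    elif param == "time":
        full_fixed = {**fixed, "time": 120.0}
        acq = _base_acq_config(full_fixed, seed)
        proj_full = _simulate(phantom, acq, cfg)
        ss = np.random.SeedSequence([seed, 0xB1]).generate_state(len(cfg.grid))
        for t, child in zip(cfg.grid, ss):
            t = float(t)
            proj = proj_full if t == 120.0 else rebin_time(proj_full, t, int(child))
            rows.extend(recon_rows(proj, base_recon, t))
    return rows


def sweep_statistics(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and regression slope of mean RC vs parameter value, per
    (tb_ratio, sphere); RC is averaged over seeds at each grid point."""
    out = []
    for (tb, mm), g in records.groupby(["tb_ratio", "sphere_mm"]):
        m = g.groupby("value", as_index=False)["RC"].mean().sort_values("value")
        x, y = m["value"].to_numpy(float), m["RC"].to_numpy(float)
        try:
            r, p = st.pearson_correlation(x, y)
        except ValueError:  # flat curve: correlation undefined, slope still 0
            r = p = np.nan
        try:
            slope, intercept = st.linear_regression(x, y)
        except ValueError:
            slope = intercept = np.nan
        out.append(
            dict(tb_ratio=tb, sphere_mm=mm, pearson_r=r, r_pvalue=p, slope=slope, intercept=intercept)
        )
    return pd.DataFrame(out).sort_values(["tb_ratio", "sphere_mm"], ascending=[False, False]).reset_index(drop=True)


def segmented_iteration_stats(
    sweep: SweepResult, boundary: int = 35, upper: int = 90
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation/regression separately on iteration ranges [1, boundary]
    and [boundary, upper]; the boundary iteration belongs to both ranges."""
    if sweep.config.parameter != "iterations":
        raise ValueError("segmented stats require an iterations sweep")
    rec = sweep.records
    early = rec[rec.value <= boundary]
    late = rec[(rec.value >= boundary) & (rec.value <= upper)]
    if early.empty or late.empty:
        raise ValueError("iteration sweep does not cover both segments")
    return sweep_statistics(early), sweep_statistics(late)


def convergence_by_sphere(
    sweep: SweepResult, tb_ratio: float, window: int | None = None, tol: float | None = None
) -> dict[float, int | None]:
    """Convergence iteration per sphere from an iterations sweep (seed-mean curve).

    Only valid when the sweep grid is a dense 1..N iteration range.
    """
    window = window or sweep.config.convergence_window
    tol = tol if tol is not None else sweep.config.convergence_tol
    out = {}
    rec = sweep.records[sweep.records.tb_ratio == tb_ratio]
    for mm, g in rec.groupby("sphere_mm"):
        curve = g.groupby("value")["RC"].mean().sort_index().to_numpy()
        out[float(mm)] = st.convergence_iteration(curve, window=window, tol=tol)
    return out


def report_tables(sweeps: dict[str, SweepResult], out_dir: str | Path) -> list[Path]:
    """Emit the CSV report bundle: one records+stats file pair per sweep."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, sw in sweeps.items():
        p = out_dir / f"sweep_{name}_records.csv"
        from .io import write_tables

        write_tables(sw.records, p)
        written.append(p)
        if sw.stats is not None:
            p2 = out_dir / f"sweep_{name}_stats.csv"
            write_tables(sw.stats, p2)
            written.append(p2)
    return written
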