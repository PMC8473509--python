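"""Synthetic SPECT acquisition: energy windows, projections, scatter, noise.

Emulates a 360-degree step-and-shoot acquisition (60 views at 6 degrees,
128 x 128 matrix at full scale) of a Tc-99m filled phantom on a
CZT-detector system.  Photopeak counts are the attenuated, depth-blurred
line integrals of the activity plus a broad stationary-Gaussian scatter
component; a lower scatter energy window (120 keV +/- 5%) records a scaled
copy of that scatter for dual-energy-window correction downstream.  Counting
noise is Poisson; list-mode re-framing to shorter acquisition times is
emulated by binomial thinning of the recorded counts.

The scatter the simulator injects (stationary Gaussian kernel) is
deliberately a different model from the dual-energy-window estimate the
reconstruction uses to remove it, so correction studies are not an inverse
crime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .phantom import VoxelPhantom
from .projector import FWHM_TO_SIGMA, PSFModel, RotationProjector


@dataclass(frozen=True)
class EnergyWindowModel:
    """Photopeak + scatter energy windows and a Gaussian detector response.

    The detector records a Gaussian photopeak centered on the emission line;
    window efficiency is the Gaussian mass inside the window bounds.  Scatter
    fractions (scatter / total accepted events in the photopeak window) are a
    model input per window width, wider windows accepting more scatter.
    """

    photopeak_center: float = 140.0  # keV
    photopeak_halfwidth_frac: float = 0.075  # 15% window
    scatter_center: float = 120.0  # keV
    scatter_halfwidth_frac: float = 0.05
    energy_resolution_fwhm_frac: float = 0.06  # CZT-like, at 140 keV
    scatter_fraction_by_window: dict[float, float] = field(
        default_factory=lambda: {0.075: 0.25, 0.10: 0.32}
    )

    def __post_init__(self) -> None:
        fracs = [
            self.photopeak_halfwidth_frac,
            self.scatter_halfwidth_frac,
            self.energy_resolution_fwhm_frac,
            *self.scatter_fraction_by_window.values(),
        ]
        if not all(0 < f < 1 for f in fracs):
            raise ValueError("all window fractions must lie in (0, 1)")
        sf = self.scatter_fraction_by_window
        keys = sorted(sf)
        if any(sf[a] >= sf[b] for a, b in zip(keys, keys[1:])):
            raise ValueError("scatter fraction must increase with window width")

    @property
    def photopeak_width_kev(self) -> float:
        return 2.0 * self.photopeak_halfwidth_frac * self.photopeak_center

    @property
    def scatter_width_kev(self) -> float:
        return 2.0 * self.scatter_halfwidth_frac * self.scatter_center

    @property
    def scatter_fraction(self) -> float:
        try:
            return self.scatter_fraction_by_window[self.photopeak_halfwidth_frac]
        except KeyError:
            raise KeyError(
                f"no scatter fraction configured for +/-{self.photopeak_halfwidth_frac:.3%} window"
            ) from None

    def with_width(self, halfwidth_frac: float) -> "EnergyWindowModel":
        return dataclasses.replace(self, photopeak_halfwidth_frac=halfwidth_frac)


def window_efficiency(window: EnergyWindowModel, which: str = "photopeak") -> float:
    """Fraction of the Gaussian photopeak accepted by an energy window.

    The photopeak is Gaussian at ``photopeak_center`` with FWHM equal to
    ``energy_resolution_fwhm_frac`` of the center energy; the efficiency is
    the Gaussian CDF mass between the window bounds.
    """
    mu = window.photopeak_center
    sigma = window.energy_resolution_fwhm_frac * mu * FWHM_TO_SIGMA
    if which == "photopeak":
        lo = mu * (1.0 - window.photopeak_halfwidth_frac)
        hi = mu * (1.0 + window.photopeak_halfwidth_frac)
    elif which == "scatter":
        lo = window.scatter_center * (1.0 - window.scatter_halfwidth_frac)
        hi = window.scatter_center * (1.0 + window.scatter_halfwidth_frac)
    else:
        raise ValueError(f"unknown window {which!r}")
    z = lambda e: (e - mu) / (sigma * np.sqrt(2.0))
    return float(0.5 * (erf(z(hi)) - erf(z(lo))))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Step-and-shoot acquisition protocol and system calibration."""

    n_views: int = 60
    arc_deg: float = 360.0
    time_per_frame: float = 120.0  # s, 1..120
    matrix: int = 128  # detector bins per row at full scale (informational)
    bin_size: float = 3.3  # mm; defaults to the phantom voxel pitch
    sensitivity: float = 140.0  # counts s^-1 MBq^-1
    psf_model: PSFModel = field(default_factory=PSFModel)
    scatter_kernel_sigma: float = 30.0  # mm
    scatterwin_to_photopeak_ratio: float = 1.1
    window: EnergyWindowModel = field(default_factory=EnergyWindowModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.time_per_frame <= 120.0:
            raise ValueError("time_per_frame must be in (0, 120] s (protocol range 1-120)")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.n_views <= 0 or self.arc_deg <= 0:
            raise ValueError("n_views and arc must be positive")

    @property
    def view_angles(self) -> np.ndarray:
        return np.arange(self.n_views) * (self.arc_deg / self.n_views)


@dataclass
class ProjectionSet:
    """Per-view count sinograms for both energy windows plus metadata."""

    photopeak_counts: np.ndarray  # (views, nx, nz) nonneg ints
    scatterwin_counts: np.ndarray
    view_angles: np.ndarray  # degrees, strictly increasing in [0, 360)
    config: AcquisitionConfig
    truth: np.ndarray | None = None  # noiseless primary, for tests

    def __post_init__(self) -> None:
        if self.photopeak_counts.shape != self.scatterwin_counts.shape:
            raise ValueError("photopeak and scatter-window shapes differ")
        if np.any(self.photopeak_counts < 0) or np.any(self.scatterwin_counts < 0):
            raise ValueError("counts must be nonnegative")


def count_scale(phantom: VoxelPhantom, config: AcquisitionConfig) -> float:
    """Counts per (MBq/ml voxel line-sum): voxel volume x sensitivity x time x efficiency."""
    eff = window_efficiency(config.window, "photopeak")
    return phantom.spec.voxel_volume_ml * config.sensitivity * config.time_per_frame * eff


def make_projector(
    phantom: VoxelPhantom,
    config: AcquisitionConfig,
    with_attenuation: bool = True,
    with_psf: bool = True,
) -> RotationProjector:
    return RotationProjector(
        grid_shape=phantom.grid_shape,
        voxel_size=phantom.spec.voxel_size,
        angles_deg=config.view_angles,
        mu_map=phantom.mu_map if with_attenuation else None,
        attenuation=with_attenuation,
        psf=config.psf_model if with_psf else None,
    )


def forward_project(
    phantom: VoxelPhantom,
    config: AcquisitionConfig,
    with_attenuation: bool = True,
    with_psf: bool = True,
    projector: RotationProjector | None = None,
) -> np.ndarray:
    """Noiseless primary-photon sinogram: expected photopeak counts per bin."""
    if projector is None:
        projector = make_projector(phantom, config, with_attenuation, with_psf)
    return projector.forward(phantom.activity) * count_scale(phantom, config)


def simulate_scatter(
    primary: np.ndarray, config: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected scatter counts in the photopeak and scatter windows.

    Scatter is a broad stationary Gaussian blur of the primary sinogram,
    globally scaled so scatter/(scatter+primary) equals the configured
    scatter fraction for the active photopeak window; the scatter-window
    counts are a further scaled copy.
    """
    if np.any(primary < 0):
        raise ValueError("primary sinogram must be nonnegative")
    f = config.window.scatter_fraction
    if f == 0 or primary.sum() == 0:
        z = np.zeros_like(primary)
        return z, z.copy()
    sigma_vox = config.scatter_kernel_sigma / config.bin_size
    broad = np.stack(
        [gaussian_filter(p, sigma=sigma_vox, mode="constant") for p in primary]
    )
    # s_total / (s_total + p_total) = f  =>  s_total = p_total * f/(1-f)
    target = primary.sum() * f / (1.0 - f)
    scatter_pp = broad * (target / broad.sum())
    scatter_win = scatter_pp * config.scatterwin_to_photopeak_ratio
    return scatter_pp, scatter_win


def add_poisson(expected: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per bin, reproducible for a given seed."""
    if np.any(expected < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.int64)


def simulate(
    phantom: VoxelPhantom,
    config: AcquisitionConfig,
    noise: bool = True,
    scatter: bool = True,
) -> ProjectionSet:
    """Full acquisition: primary + scatter expectations, then Poisson noise.

    Energy windows are drawn as independent Poisson realizations of their
    expectations (child seeds derived deterministically from ``config.seed``).
    """
    primary = forward_project(phantom, config, with_attenuation=True, with_psf=True)
    if scatter:
        scatter_pp, scatter_win = simulate_scatter(primary, config)
    else:
        scatter_pp = np.zeros_like(primary)
        scatter_win = np.zeros_like(primary)
    expected_pp = primary + scatter_pp
    if noise:
        ss = np.random.SeedSequence(config.seed).spawn(2)
        pp = add_poisson(expected_pp, ss[0].generate_state(1)[0])
        sw = add_poisson(scatter_win, ss[1].generate_state(1)[0])
    else:
        pp = expected_pp
        sw = scatter_win
    return ProjectionSet(
        photopeak_counts=pp,
        scatterwin_counts=sw,
        view_angles=config.view_angles,
        config=config,
        truth=primary,
    )


def rebin_time(full: ProjectionSet, target_time: float, seed: int) -> ProjectionSet:
    """List-mode-style re-framing: binomial thinning of the recorded counts.

    Keeping each recorded event independently with probability
    target_time/full_time emulates re-histogramming the same event stream
    into a shorter frame; it is not an independent re-acquisition.
    """
    t_full = full.config.time_per_frame
    if target_time > t_full:
        raise ValueError(f"target time {target_time} exceeds acquired {t_full}")
    if target_time < 0:
        raise ValueError("target time must be >= 0")
    p = target_time / t_full
    rng = np.random.default_rng(seed)
    pp = rng.binomial(full.photopeak_counts.astype(np.int64), p)
    sw = rng.binomial(full.scatterwin_counts.astype(np.int64), p)
    if target_time > 0:
        cfg = dataclasses.replace(full.config, time_per_frame=target_time)
    else:  # degenerate all-zero frame; keep the parent calibration metadata
        cfg = full.config
    truth = None if full.truth is None else full.truth * p
    return ProjectionSet(
        photopeak_counts=pp,
        scatterwin_counts=sw,
        view_angles=full.view_angles,
        config=cfg,
        truth=truth,
    )
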