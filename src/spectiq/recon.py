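"""OSEM reconstruction with switchable AC / SC / RR and Gaussian post-filter.

The reconstruction problem is maximum-likelihood estimation of a Poisson
model: recorded photopeak counts y ~ Poisson(A x + s), where A is the
system operator (attenuation included when AC is on, depth-dependent PSF
when RR is on) and s is a known additive scatter term (the dual-energy-
window estimate when SC is on, zero otherwise).  MLEM applies the
multiplicative update

    x <- x / (A^T 1) * A^T( y / (A x + s) )

which is monotone in the Poisson log-likelihood and preserves
nonnegativity; OSEM cycles the same update over angular subsets of views.
Exposed statsmodels-style: build an :class:`OSEMModel` from a
:class:`~spectiq.acquisition.ProjectionSet`, call ``fit()``, get an
:class:`OSEMResults` holding the volume, per-iteration diagnostics and a
``summary()``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import fourier_gaussian

from .acquisition import AcquisitionConfig, ProjectionSet, count_scale, window_efficiency
from .phantom import VoxelPhantom
from .projector import FWHM_TO_SIGMA, RotationProjector

CORRECTIONS = ("AC", "SC", "RR")


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> sigma: fwhm / (2 sqrt(2 ln 2))."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    return fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class ReconConfig:
    """Iterations, subsets, correction set and post-filter for one reconstruction."""

    iterations: int = 35
    subsets: int = 20
    corrections: frozenset[str] = frozenset({"AC", "SC", "RR"})
    post_filter_fwhm: float | None = None  # mm, 0.7-6.99 in the study protocol
    dew_k: float = 0.5
    initial_value: float = 1.0
    presubtract_scatter: bool = False  # older DEW practice: y - s clipped at 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1 (1 = MLEM)")
        unknown = set(self.corrections) - set(CORRECTIONS)
        if unknown:
            raise ValueError(f"unknown corrections {sorted(unknown)}")
        if self.post_filter_fwhm is not None and self.post_filter_fwhm <= 0:
            raise ValueError("post_filter_fwhm must be > 0 when set")
        if self.initial_value <= 0:
            raise ValueError("initial_value must be > 0")

    @classmethod
    def with_corrections(cls, spec: str, **kw) -> "ReconConfig":
        """Build from a string like ``"AC+SC+RR"`` or ``"AC,RR"``."""
        tokens = [t for t in spec.replace("+", ",").split(",") if t.strip()]
        return cls(corrections=frozenset(t.strip().upper() for t in tokens), **kw)

    @property
    def corrections_tag(self) -> str:
        return "+".join(c for c in CORRECTIONS if c in self.corrections)


@dataclass
class ReconVolume:
    """Reconstructed activity-concentration volume with provenance."""

    values: np.ndarray  # MBq/ml, >= 0
    voxel_size: tuple[float, float, float]
    recon_config: ReconConfig
    acquisition: AcquisitionConfig | None = None


@dataclass
class ScatterEstimate:
    """Per-view expected photopeak-window scatter counts (DEW method)."""

    values: np.ndarray
    k: float
    width_ratio: float
    method: str = "DEW"


def dew_scatter_estimate(
    scatterwin_counts: np.ndarray,
    k: float,
    photopeak_width_kev: float,
    scatterwin_width_kev: float,
) -> ScatterEstimate:
    """Dual-energy-window scatter estimate: k * (W_pp / W_sc) * C_sc per bin."""
    if scatterwin_width_kev <= 0 or photopeak_width_kev <= 0:
        raise ValueError("window widths must be > 0")
    if np.any(scatterwin_counts < 0):
        raise ValueError("scatter-window counts must be nonnegative")
    ratio = photopeak_width_kev / scatterwin_width_kev
    return ScatterEstimate(
        values=k * ratio * np.asarray(scatterwin_counts, dtype=float),
        k=k,
        width_ratio=ratio,
    )


def subset_views(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Stride assignment: subset k gets views k, k+n_subsets, ... (maximally
    spread angles; sizes differ by at most one when n_subsets does not divide
    n_views)."""
    if n_subsets > n_views:
        raise ValueError("more subsets than views")
    return [np.arange(k, n_views, n_subsets) for k in range(n_subsets)]


def gaussian_postfilter(volume: ReconVolume, fwhm: float) -> ReconVolume:
    """Isotropic 3-D Gaussian post-filter, parameterized by FWHM in mm.

    Applied in the Fourier domain (exact Gaussian transfer function), which
    preserves the volume mean and is strictly contractive on every non-DC
    frequency for any fwhm > 0 — including sub-voxel FWHM values where a
    truncated spatial kernel would collapse to the identity.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma_vox = [fwhm_to_sigma(fwhm) / v for v in volume.voxel_size]
    f = np.fft.rfftn(volume.values)
    f = fourier_gaussian(f, sigma=sigma_vox, n=volume.values.shape[-1])
    smoothed = np.fft.irfftn(f, s=volume.values.shape, axes=(0, 1, 2))
    smoothed = np.maximum(smoothed, 0.0)
    cfg = dataclasses.replace(volume.recon_config, post_filter_fwhm=fwhm)
    return ReconVolume(
        values=smoothed,
        voxel_size=volume.voxel_size,
        recon_config=cfg,
        acquisition=volume.acquisition,
    )


class SystemOperator:
    """Minimal interface OSEM needs: forward/adjoint over view subsets.

    ``MatrixOperator`` (below) adapts an explicit matrix for toy systems;
    ``ProjectorOperator`` wraps the rotation projector for real geometry.
    """

    n_views: int

    def forward(self, x: np.ndarray, views: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjoint(self, y: np.ndarray, views: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MatrixOperator(SystemOperator):
    """Dense system matrix (n_bins x n_voxels); each 'view' is one bin row."""

    def __init__(self, matrix: np.ndarray):
        self.A = np.asarray(matrix, dtype=float)
        self.n_views = self.A.shape[0]

    def forward(self, x, views):
        return self.A[views] @ x

    def adjoint(self, y, views):
        return self.A[views].T @ y


class ProjectorOperator(SystemOperator):
    """Rotation projector + count calibration as an OSEM system operator."""

    def __init__(self, projector: RotationProjector, scale: float):
        self.projector = projector
        self.scale = scale
        self.n_views = len(projector.angles_deg)

    def forward(self, x, views):
        return self.projector.forward(x, views) * self.scale

    def adjoint(self, y, views):
        return self.projector.adjoint(y, views) * self.scale


def poisson_loglik(y: np.ndarray, mean: np.ndarray) -> float:
    """Poisson log-likelihood up to the data-only constant: sum(y log m - m)."""
    m = np.asarray(mean, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(np.where(m > 0, m, 1.0)), 0.0)
    t = np.where((y > 0) & (m == 0), -np.inf, t)
    return float(np.sum(t - m))


def osem(
    y: np.ndarray,
    op: SystemOperator,
    n_iterations: int,
    n_subsets: int,
    scatter: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    support: np.ndarray | None = None,
    callback=None,
    track_loglik: bool = False,
) -> tuple[np.ndarray, list[float]]:
    """Core OSEM loop on an abstract system operator.

    ``y`` is indexed by view along its first axis.  With ``n_subsets=1`` this
    is exactly MLEM.  Voxels with subset sensitivity below 1e-8 of its
    maximum are frozen; bins where the forward model is zero contribute a
    zero ratio.
    """
    subsets = subset_views(op.n_views, n_subsets)
    if x0 is None:
        raise ValueError("x0 required")
    x = np.array(x0, dtype=float)
    if support is not None:
        x = x * support
    if scatter is None:
        scatter = np.zeros_like(np.asarray(y, dtype=float))
    sens = []
    for views in subsets:
        ones = np.ones_like(np.asarray(y, dtype=float)[views])
        s_img = op.adjoint(ones, views)
        mask = s_img > 1e-8 * s_img.max() if s_img.max() > 0 else s_img > 0
        sens.append((s_img, mask))
    loglik: list[float] = []
    for _ in range(n_iterations):
        for views, (s_img, mask) in zip(subsets, sens):
            fp = op.forward(x, views) + scatter[views]
            ratio = np.divide(
                y[views], fp, out=np.zeros_like(fp, dtype=float), where=fp > 0
            )
            bp = op.adjoint(ratio, views)
            upd = np.divide(bp, s_img, out=np.ones_like(bp), where=mask)
            x = np.where(mask, x * upd, x)
        if track_loglik:
            full = np.arange(op.n_views)
            loglik.append(poisson_loglik(y, op.forward(x, full) + scatter))
        if callback is not None:
            callback(x)
    return x, loglik


class OSEMModel:
    """OSEM reconstruction model for a simulated (or loaded) acquisition.

    Parameters
    ----------
    projections : ProjectionSet
        Photopeak and scatter-window count sinograms plus acquisition config.
    mu_map : ndarray
        Attenuation volume (cm^-1); used when ``AC`` is in the corrections.
    config : ReconConfig
    voxel_size : (3,) mm; defaults to the acquisition bin size, isotropic.
    """

    def __init__(
        self,
        projections: ProjectionSet,
        mu_map: np.ndarray,
        config: ReconConfig = ReconConfig(),
        voxel_size: tuple[float, float, float] | None = None,
    ):
        self.projections = projections
        self.mu_map = np.asarray(mu_map, dtype=float)
        self.config = config
        acq = projections.config
        if voxel_size is None:
            voxel_size = (acq.bin_size,) * 3
        self.voxel_size = voxel_size
        n_views, nx, nz = projections.photopeak_counts.shape
        ny = self.mu_map.shape[1]
        if self.mu_map.shape != (nx, ny, nz):
            raise ValueError(
                f"mu_map shape {self.mu_map.shape} incompatible with sinogram ({n_views},{nx},{nz})"
            )
        use_ac = "AC" in config.corrections
        use_rr = "RR" in config.corrections
        self._projector = RotationProjector(
            grid_shape=self.mu_map.shape,
            voxel_size=voxel_size,
            angles_deg=projections.view_angles,
            mu_map=self.mu_map if use_ac else None,
            attenuation=use_ac,
            psf=acq.psf_model if use_rr else None,
        )
        vol_ml = float(np.prod(voxel_size)) / 1000.0
        eff = window_efficiency(acq.window, "photopeak")
        self._scale = vol_ml * acq.sensitivity * acq.time_per_frame * eff
        self._op = ProjectorOperator(self._projector, self._scale)

    def scatter_estimate(self) -> ScatterEstimate:
        w = self.projections.config.window
        return dew_scatter_estimate(
            self.projections.scatterwin_counts,
            k=self.config.dew_k,
            photopeak_width_kev=w.photopeak_width_kev,
            scatterwin_width_kev=w.scatter_width_kev,
        )

    def fit(self, callback=None, track_loglik: bool = False) -> "OSEMResults":
        """Run the configured OSEM iterations and return results.

        ``callback(volume_mbq_ml)`` is invoked after every full iteration with
        the current estimate already converted to MBq/ml — used by sweeps to
        record per-iteration recovery curves without refitting.
        """
        cfg = self.config
        y = self.projections.photopeak_counts.astype(float)
        scatter = None
        if "SC" in cfg.corrections:
            est = self.scatter_estimate().values
            if cfg.presubtract_scatter:
                y = np.maximum(y - est, 0.0)
            else:
                scatter = est
        support = (self.mu_map > 0).astype(float)
        if not support.any() or "AC" not in cfg.corrections:
            support = np.ones_like(self.mu_map)
        x0 = np.full(self.mu_map.shape, cfg.initial_value)
        cb = None
        if callback is not None:
            cb = lambda x: callback(x)  # x is already in MBq/ml (scale in A)
        x, loglik = osem(
            y,
            self._op,
            n_iterations=cfg.iterations,
            n_subsets=cfg.subsets,
            scatter=scatter,
            x0=x0,
            support=support,
            callback=cb,
            track_loglik=track_loglik,
        )
        volume = ReconVolume(
            values=x,
            voxel_size=self.voxel_size,
            recon_config=cfg,
            acquisition=self.projections.config,
        )
        if cfg.post_filter_fwhm is not None:
            volume = gaussian_postfilter(volume, cfg.post_filter_fwhm)
        return OSEMResults(model=self, volume=volume, loglik_trace=loglik)


@dataclass
class OSEMResults:
    """Fitted reconstruction: volume plus diagnostics."""

    model: OSEMModel
    volume: ReconVolume
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    def summary(self) -> str:
        cfg = self.volume.recon_config
        acq = self.volume.acquisition
        lines = [
            "OSEM reconstruction results",
            "===========================",
            f"grid:            {self.values.shape} @ {self.volume.voxel_size} mm",
            f"iterations:      {cfg.iterations}  subsets: {cfg.subsets}",
            f"corrections:     {cfg.corrections_tag or 'none'}",
            f"post-filter:     {cfg.post_filter_fwhm or 'none'} mm FWHM",
            f"time/frame:      {acq.time_per_frame if acq else '?'} s",
            f"volume total:    {self.values.sum():.4g} (MBq/ml voxel sum)",
            f"volume max:      {self.values.max():.4g} MBq/ml",
        ]
        if self.loglik_trace:
            lines.append(f"final loglik:    {self.loglik_trace[-1]:.6g}")
        return "\n".join(lines)


def osem_reconstruct(
    projections: ProjectionSet,
    mu_map: np.ndarray,
    config: ReconConfig,
    voxel_size: tuple[float, float, float] | None = None,
) -> ReconVolume:
    """Functional wrapper: build the model, fit, return the volume."""
    return OSEMModel(projections, mu_map, config, voxel_size).fit().volume


def reconstruct_phantom(
    phantom: VoxelPhantom, projections: ProjectionSet, config: ReconConfig
) -> ReconVolume:
    return osem_reconstruct(
        projections, phantom.mu_map, config, voxel_size=phantom.spec.voxel_size
    )
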