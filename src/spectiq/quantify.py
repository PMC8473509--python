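"""NEMA-style quantification metrics: RC, percent contrast, COV.

Per hot sphere j the three headline numbers are

    RC_j   = 100 * C_H,j / a_H                    (recovery coefficient, %)
    Q_H,j  = 100 * (C_H,j/C_B,j - 1)/(a_H/a_B - 1)  (percent contrast, %)
    N_j    = 100 * SD_j / C_B,j                   (background COV, %)

where C_H,j is the mean reconstructed concentration in the sphere VOI, a_H
and a_B the true hot/background concentrations, C_B,j and SD_j the mean and
standard deviation of background ROI means for sphere-size-j ROIs placed per
the NEMA NU 2 layout (12 in-plane positions replicated on the central slice
and the slices +/-1 and +/-2 cm around it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom, voi_masks
from .recon import ReconVolume


@dataclass(frozen=True)
class VOIStats:
    label: int
    mean_uptake: float  # C_H,j
    sd: float  # voxel-wise SD within the VOI (n-1 denominator)
    n_voxels: int
    volume_ml: float


@dataclass(frozen=True)
class BackgroundStats:
    """Per-sphere-size background ROI summary (C_B,j, SD_j)."""

    sphere_label: int
    mean: float  # C_B,j: average of the ROI means
    sd: float  # SD_j: SD of the ROI means
    n_rois: int


@dataclass
class QuantResult:
    """Per-sphere RC / percent contrast / COV for one reconstruction."""

    rows: pd.DataFrame  # columns: label, diameter_mm, mean, sd, n_voxels, C_B, SD_B, RC, Q, COV
    a_hot: float
    a_bkg: float
    provenance: dict = field(default_factory=dict)

    def rc_by_diameter(self) -> dict[float, float]:
        return dict(zip(self.rows["diameter_mm"], self.rows["RC"]))

    def summary(self) -> str:
        hdr = [
            "Quantification results",
            "======================",
            f"a_H = {self.a_hot:.4g} MBq/ml   a_B = {self.a_bkg:.4g} MBq/ml   "
            f"T/B = {self.a_hot / self.a_bkg:.3g}",
        ]
        table = self.rows[["diameter_mm", "RC", "Q", "COV", "mean", "sd"]].to_string(
            index=False, float_format=lambda v: f"{v:.2f}"
        )
        return "\n".join(hdr) + "\n" + table


class PlacementError(ValueError):
    """Background ROIs cannot be placed without violating margins/overlaps."""


def measure_voi(volume: ReconVolume | np.ndarray, mask: np.ndarray, voxel_volume_ml: float | None = None, label: int = 0) -> VOIStats:
    """Mean and (n-1)-SD of a volume over a boolean mask."""
    values = volume.values if isinstance(volume, ReconVolume) else np.asarray(volume)
    if mask.shape != values.shape:
        raise ValueError("mask and volume grids differ")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty VOI mask")
    vals = values[mask]
    if voxel_volume_ml is None:
        if isinstance(volume, ReconVolume):
            voxel_volume_ml = float(np.prod(volume.voxel_size)) / 1000.0
        else:
            voxel_volume_ml = float("nan")
    return VOIStats(
        label=label,
        mean_uptake=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if n > 1 else 0.0,
        n_voxels=n,
        volume_ml=n * voxel_volume_ml,
    )


def recovery_coefficient(measured: float, actual: float) -> float:
    """RC (%) = 100 * measured / actual."""
    if actual <= 0:
        raise ValueError("actual concentration must be > 0")
    if measured < 0:
        raise ValueError("measured concentration must be >= 0")
    return 100.0 * measured / actual


def percent_contrast(c_hot: float, c_bkg: float, a_hot: float, a_bkg: float) -> float:
    """Q_H (%) = 100 * (C_H/C_B - 1) / (a_H/a_B - 1)."""
    if c_bkg <= 0:
        raise ValueError("background mean must be > 0")
    if a_bkg <= 0 or a_hot == a_bkg:
        raise ValueError("contrast undefined for a_H == a_B")
    return 100.0 * (c_hot / c_bkg - 1.0) / (a_hot / a_bkg - 1.0)


def background_cov(sd: float, c_bkg: float) -> float:
    """N (%) = 100 * SD / C_B."""
    if c_bkg <= 0:
        raise ValueError("background mean must be > 0")
    return 100.0 * sd / c_bkg


#: Default in-plane background ROI centers: 12 positions on a 100 mm radius
#: ring, clear of the sphere cluster (r = 57.2 + 18.5 mm) and of the body
#: edge for every sphere-size ROI.
DEFAULT_ROI_ANGLES_DEG = tuple(range(0, 360, 30))
DEFAULT_ROI_RADIUS_MM = 100.0
DEFAULT_SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)
EDGE_MARGIN_MM = 15.0


def place_background_rois(
    phantom: VoxelPhantom,
    roi_radius_mm: float = DEFAULT_ROI_RADIUS_MM,
    angles_deg: tuple[float, ...] = DEFAULT_ROI_ANGLES_DEG,
    slice_offsets_mm: tuple[float, ...] = DEFAULT_SLICE_OFFSETS_MM,
) -> dict[int, list[np.ndarray]]:
    """Circular background ROI masks per sphere label (NEMA NU 2 layout).

    For each sphere size, one circular ROI of that sphere's diameter is drawn
    at each (angle, slice) position: 12 positions x 5 slices = 60 ROIs.
    Every ROI must lie in the background compartment with >= 15 mm margin
    from the body edge and must not overlap any sphere (checked in-plane).

    Raises
    ------
    PlacementError
        Listing each infeasible (sphere, position) pair.
    """
    spec = phantom.spec
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_size
    xc = (np.arange(nx) - (nx - 1) / 2.0) * vx
    yc = (np.arange(ny) - (ny - 1) / 2.0) * vy
    zc = (np.arange(nz) - (nz - 1) / 2.0) * vz
    z0 = spec.spheres[0].center[2] if spec.spheres else 0.0
    conflicts = []
    rois: dict[int, list[np.ndarray]] = {}
    for s in spec.spheres:
        r_roi = s.radius
        masks = []
        for ang in angles_deg:
            cx = roi_radius_mm * np.cos(np.deg2rad(ang))
            cy = roi_radius_mm * np.sin(np.deg2rad(ang))
            # margin check: ROI disc grown by the edge margin must stay inside
            probe_r = r_roi + EDGE_MARGIN_MM
            probes_ok = all(
                spec.body_outline.contains(
                    np.atleast_1d(cx + probe_r * np.cos(t)),
                    np.atleast_1d(cy + probe_r * np.sin(t)),
                    np.atleast_1d(z0),
                )[0]
                for t in np.linspace(0, 2 * np.pi, 16, endpoint=False)
            )
            if not probes_ok:
                conflicts.append((s.label, ang, "edge margin"))
                continue
            for other in spec.spheres:
                d_inplane = np.hypot(cx - other.center[0], cy - other.center[1])
                if d_inplane < r_roi + other.radius:
                    conflicts.append((s.label, ang, f"overlaps sphere {other.label}"))
                    break
            else:
                disc = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2 <= r_roi**2
                for dz in slice_offsets_mm:
                    iz = int(np.argmin(np.abs(zc - (z0 + dz))))
                    m = np.zeros(spec.grid_shape, dtype=bool)
                    m[:, :, iz] = disc & (phantom.labels[:, :, iz] == 1)
                    if m.any():
                        masks.append(m)
                    else:
                        conflicts.append((s.label, ang, f"empty ROI at slice {dz}"))
        rois[s.label] = masks
    if conflicts:
        raise PlacementError(f"infeasible background ROI placements: {conflicts}")
    return rois


def background_stats(
    volume: ReconVolume | np.ndarray, rois: dict[int, list[np.ndarray]]
) -> dict[int, BackgroundStats]:
    values = volume.values if isinstance(volume, ReconVolume) else np.asarray(volume)
    out = {}
    for label, masks in rois.items():
        means = np.array([values[m].mean() for m in masks])
        if means.size == 0:
            raise PlacementError(f"no background ROIs for sphere {label}")
        out[label] = BackgroundStats(
            sphere_label=label,
            mean=float(means.mean()),
            sd=float(means.std(ddof=1)) if means.size > 1 else 0.0,
            n_rois=len(masks),
        )
    return out


def quantify(
    volume: ReconVolume | np.ndarray,
    phantom: VoxelPhantom,
    rois: dict[int, list[np.ndarray]] | None = None,
) -> QuantResult:
    """Assemble per-sphere RC, percent contrast and COV for one volume.

    ``rois`` may be passed to reuse a precomputed background layout across
    many reconstructions of the same phantom.
    """
    values = volume.values if isinstance(volume, ReconVolume) else np.asarray(volume)
    if values.shape != phantom.grid_shape:
        raise ValueError("volume and phantom grids differ")
    spec = phantom.spec
    a_h, a_b = spec.sphere_concentration, spec.background_concentration
    masks = voi_masks(phantom)
    if rois is None:
        rois = place_background_rois(phantom)
    bstats = background_stats(values, rois)
    vox_ml = spec.voxel_volume_ml
    recs = []
    for s in spec.spheres:
        v = measure_voi(values, masks[s.label], vox_ml, label=s.label)
        b = bstats[s.label]
        recs.append(
            {
                "label": s.label,
                "diameter_mm": s.diameter,
                "mean": v.mean_uptake,
                "sd": v.sd,
                "n_voxels": v.n_voxels,
                "C_B": b.mean,
                "SD_B": b.sd,
                "RC": recovery_coefficient(v.mean_uptake, a_h),
                "Q": percent_contrast(v.mean_uptake, b.mean, a_h, a_b),
                "COV": background_cov(b.sd, b.mean),
            }
        )
    prov = {}
    if isinstance(volume, ReconVolume):
        cfg = volume.recon_config
        prov = {
            "iterations": cfg.iterations,
            "subsets": cfg.subsets,
            "corrections": cfg.corrections_tag,
            "post_filter_fwhm": cfg.post_filter_fwhm,
        }
    return QuantResult(rows=pd.DataFrame(recs), a_hot=a_h, a_bkg=a_b, provenance=prov)
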