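"""Rotation-based parallel-hole projector with exact adjoint.

For each view the image volume is rotated in-plane (about the axial z axis)
so the rays run along the +y grid axis, optionally attenuated with the
co-rotated mu-map (Beer-Lambert along the remaining path to the detector),
optionally blurred plane-by-plane with a depth-dependent Gaussian
(collimator-detector response), and summed along y onto a (x, z) detector
grid.

Each in-plane rotation is a precomputed sparse bilinear-interpolation matrix,
so the backprojector is the exact transpose of the forward projector — the
matched operator pair OSEM requires.  Gaussian plane blurs use zero-padded
convolution, which is self-adjoint for a symmetric kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _rotation_matrix(
    nx: int, ny: int, angle_deg: float, normalize: bool = False
) -> sparse.csr_matrix:
    """Sparse (nx*ny, nx*ny) bilinear in-plane rotation about the grid center.

    Row i = voxel of the rotated frame; columns = source voxels.  Voxels whose
    inverse-rotated position falls outside the grid receive zero.  With
    ``normalize`` each column is scaled to unit sum, making the transport
    exactly mass-preserving (every source voxel deposits its full content),
    which is what the activity projector needs for count conservation; the
    plain interpolating form is kept for resampling the mu-map.
    """
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # inverse rotation of output coordinates into the source frame
    x = c * (ii - cx) - s * (jj - cy) + cx
    y = s * (ii - cx) + c * (jj - cy) + cy
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = x - x0
    fy = y - y0
    rows, cols, vals = [], [], []
    out_idx = (ii * ny + jj).ravel()
    for dx, dy, w in [
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ]:
        xs, ys = x0 + dx, y0 + dy
        ok = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny) & (w > 0)
        rows.append(out_idx[ok.ravel()])
        cols.append((xs * ny + ys)[ok].ravel())
        vals.append(w[ok].ravel())
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    ).tocsr()
    if normalize:
        colsum = np.asarray(m.sum(axis=0)).ravel()
        scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
        m = m @ sparse.diags(scale)
    return m


@dataclass(frozen=True)
class PSFModel:
    """Depth-dependent collimator-detector response FWHM(d) = intercept + slope*d.

    ``d`` is the distance (mm) from the detector face to the image plane.
    """

    fwhm_intercept: float = 4.0  # mm
    fwhm_slope: float = 0.045  # mm per mm depth

    def sigma_mm(self, depth_mm: float) -> float:
        fwhm = self.fwhm_intercept + self.fwhm_slope * max(depth_mm, 0.0)
        return fwhm * FWHM_TO_SIGMA


class RotationProjector:
    """Matched forward/backprojector for a set of view angles.

    Parameters
    ----------
    grid_shape : (nx, ny, nz) voxel grid, z the rotation axis.
    voxel_size : (vx, vy, vz) in mm; vx must equal vy (in-plane rotation).
    angles_deg : view angles; detector bins are (nx, nz) at the voxel pitch.
    mu_map : attenuation volume (cm^-1) used when ``attenuation`` is on.
    psf : PSFModel used when ``psf`` is on.
    detector_radius_mm : distance of detector face from rotation axis;
        defaults to half the in-plane field of view.
    """

    def __init__(
        self,
        grid_shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float],
        angles_deg: np.ndarray,
        mu_map: np.ndarray | None = None,
        attenuation: bool = False,
        psf: PSFModel | None = None,
        detector_radius_mm: float | None = None,
        n_psf_groups: int = 16,
    ):
        nx, ny, nz = grid_shape
        vx, vy, vz = voxel_size
        if abs(vx - vy) > 1e-9:
            raise ValueError("in-plane voxel size must be isotropic for rotation")
        if attenuation and mu_map is None:
            raise ValueError("attenuation requested but no mu_map given")
        if attenuation and mu_map.shape != tuple(grid_shape):
            raise ValueError(f"mu_map shape {mu_map.shape} != grid {grid_shape}")
        self.grid_shape = (nx, ny, nz)
        self.voxel_size = (vx, vy, vz)
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.attenuation = attenuation
        self.psf = psf
        if detector_radius_mm is None:
            detector_radius_mm = ny * vy / 2.0
        self.detector_radius_mm = detector_radius_mm

        self._rot = [_rotation_matrix(nx, ny, a, normalize=True) for a in self.angles_deg]
        # depth of each y-plane from the detector face (detector at +y)
        ycoord = (np.arange(ny) - (ny - 1) / 2.0) * vy
        self._depths_mm = detector_radius_mm - ycoord
        if psf is not None:
            # Planes are grouped by quantized depth and share one blur kernel;
            # summing a group's planes before blurring is then exact and cuts
            # the per-view filter count from ny to n_psf_groups.
            groups = np.minimum(
                (np.arange(ny) * n_psf_groups) // ny, n_psf_groups - 1
            )
            self._psf_groups = []
            for g in range(n_psf_groups):
                ys = np.flatnonzero(groups == g)
                if ys.size == 0:
                    continue
                d = float(np.mean(self._depths_mm[ys]))
                self._psf_groups.append(
                    (slice(ys[0], ys[-1] + 1), (psf.sigma_mm(d) / vx, psf.sigma_mm(d) / vz))
                )
        self._att = None
        if attenuation:
            # mu is resampled with the plain interpolating rotation (values,
            # not mass, are what matter for the Beer-Lambert path integral)
            self._att = [
                self._attenuation_volume(_rotation_matrix(nx, ny, a), mu_map)
                for a in self.angles_deg
            ]

    def _rotate(self, vol: np.ndarray, iview: int) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        return (self._rot[iview] @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def _rotate_adj(self, vol: np.ndarray, iview: int) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        return (self._rot[iview].T @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def _attenuation_volume(self, R: sparse.csr_matrix, mu_map: np.ndarray) -> np.ndarray:
        """exp(-integral of rotated mu from voxel center to the detector)."""
        nx, ny, nz = self.grid_shape
        mu_r = (R @ mu_map.reshape(nx * ny, nz)).reshape(nx, ny, nz)
        dl_cm = self.voxel_size[1] / 10.0
        # path beyond the voxel (exclusive) plus half of the voxel itself
        beyond = np.flip(np.cumsum(np.flip(mu_r, axis=1), axis=1), axis=1) - mu_r
        return np.exp(-dl_cm * (beyond + 0.5 * mu_r)).astype(np.float64)

    def forward_view(self, vol: np.ndarray, iview: int) -> np.ndarray:
        """Project one view: (nx, nz) array of line sums (voxel units)."""
        a = self._rotate(vol, iview)
        if self._att is not None:
            a = a * self._att[iview]
        if self.psf is not None:
            out = np.zeros((self.grid_shape[0], self.grid_shape[2]))
            for ys, sig in self._psf_groups:
                out += gaussian_filter(
                    a[:, ys, :].sum(axis=1), sigma=sig, mode="constant", truncate=3.0
                )
            return out
        return a.sum(axis=1)

    def adjoint_view(self, proj: np.ndarray, iview: int) -> np.ndarray:
        """Exact transpose of :meth:`forward_view`."""
        nx, ny, nz = self.grid_shape
        b = np.empty((nx, ny, nz))
        if self.psf is not None:
            for ys, sig in self._psf_groups:
                b[:, ys, :] = gaussian_filter(
                    proj, sigma=sig, mode="constant", truncate=3.0
                )[:, None, :]
        else:
            b[:] = proj[:, None, :]
        if self._att is not None:
            b = b * self._att[iview]
        return self._rotate_adj(b, iview)

    def forward(self, vol: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        """Project all (or a subset of) views: (n_views, nx, nz)."""
        if views is None:
            views = range(len(self.angles_deg))
        return np.stack([self.forward_view(vol, i) for i in views])

    def adjoint(self, projs: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        if views is None:
            views = range(len(self.angles_deg))
        out = np.zeros(self.grid_shape)
        for p, i in zip(projs, views):
            out += self.adjoint_view(p, i)
        return out
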