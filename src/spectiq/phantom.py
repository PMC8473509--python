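"""Voxelized NEMA IEC body phantom.

The NEMA/IEC 2001 image-quality phantom is a D-shaped water-filled torso
shell holding six fillable spheres (37, 28, 22, 17, 13 and 10 mm inner
diameter) whose centers sit on a 114.4 mm diameter circle in a single
transverse plane.  This module builds co-registered activity (MBq/ml),
attenuation (cm^-1) and integer label volumes for any hot-sphere
concentration and target-to-background (T/B) ratio, plus radioactive-decay
calibration of concentrations to acquisition time.

Geometry convention: right-handed voxel-centered coordinates in mm, origin
at the grid center; the z axis is the scanner rotation (axial) axis.  The
D-shaped interior cross-section is a half-disc of radius ``half_radius``
(y >= 0) on top of a ``straight_depth``-tall slab with rounded bottom
corners of radius ``corner_radius`` — 300 x 230 mm overall, about 10 L over
the 180 mm axial extent, matching the published standard within the
tolerance of a shell-less model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Inner diameters (mm) of the six standard hot spheres, largest first.
DEFAULT_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: Diameter (mm) of the circle the sphere centers sit on.
SPHERE_CIRCLE_DIAMETER_MM = 114.4

#: Tc-99m physical half-life (hours).
TC99M_HALF_LIFE_H = 6.0058

#: Linear attenuation coefficient of water at 140 keV (cm^-1).
MU_WATER_140KEV = 0.154


class GeometryError(ValueError):
    """A phantom geometry constraint is violated (sphere outside body, overlap...)."""


@dataclass(frozen=True)
class SphereSpec:
    """One fillable hot sphere."""

    diameter: float  # mm
    center: tuple[float, float, float]  # mm, phantom frame
    label: int

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"sphere diameter must be > 0, got {self.diameter}")
        if self.label < 2:
            raise GeometryError("sphere labels start at 2 (0=outside, 1=background)")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume_ml(self) -> float:
        """Analytic volume in ml (diameter in mm)."""
        return (4.0 / 3.0) * np.pi * (self.radius / 10.0) ** 3


@dataclass(frozen=True)
class BodyOutline:
    """D-shaped interior cross-section and axial extent, all in mm."""

    half_radius: float = 150.0  # top half-disc radius
    straight_depth: float = 80.0  # flat-sided slab below y=0
    corner_radius: float = 80.0  # rounded bottom corners
    axial_length: float = 180.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Voxel-center-inside test for point arrays in the phantom frame."""
        inside_axial = np.abs(z) <= self.axial_length / 2.0
        r = self.half_radius
        d = self.straight_depth
        c = self.corner_radius
        top = (y >= 0) & (x * x + y * y <= r * r)
        slab = (y < 0) & (y >= -d) & (np.abs(x) <= r)
        # below the slab: band of height c between the corner-arc centers
        cx = r - c  # corner centers at (+-cx, -d)
        bottom_mid = (y < -d) & (y >= -d - c) & (np.abs(x) <= cx)
        dxc = np.abs(x) - cx
        bottom_corner = (y < -d) & (dxc > 0) & (dxc * dxc + (y + d) ** 2 <= c * c)
        return inside_axial & (top | slab | bottom_mid | bottom_corner)

    def cross_section_area_mm2(self) -> float:
        r, d, c = self.half_radius, self.straight_depth, self.corner_radius
        half_disc = np.pi * r * r / 2.0
        slab = 2.0 * r * d
        bottom = 2.0 * (r - c) * c + np.pi * c * c / 2.0
        return half_disc + slab + bottom


def default_sphere_specs(
    diameters: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS_MM,
    circle_diameter: float = SPHERE_CIRCLE_DIAMETER_MM,
    plane_z: float = 0.0,
    first_angle_deg: float = 0.0,
) -> tuple[SphereSpec, ...]:
    """Place spheres at 60 degree spacing on the standard circle, labels 2..7."""
    rho = circle_diameter / 2.0
    specs = []
    for i, dia in enumerate(diameters):
        ang = np.deg2rad(first_angle_deg + 60.0 * i)
        specs.append(
            SphereSpec(
                diameter=dia,
                center=(rho * np.cos(ang), rho * np.sin(ang), plane_z),
                label=i + 2,
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for a voxelized phantom fill."""

    sphere_concentration: float  # a_H, MBq/ml
    tb_ratio: float  # a_H / a_B
    spheres: tuple[SphereSpec, ...] = field(default_factory=default_sphere_specs)
    body_outline: BodyOutline = field(default_factory=BodyOutline)
    mu_fill: float = MU_WATER_140KEV  # cm^-1
    voxel_size: tuple[float, float, float] = (3.3, 3.3, 3.3)  # mm
    grid_shape: tuple[int, int, int] = (128, 128, 64)

    def __post_init__(self) -> None:
        if self.sphere_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.tb_ratio <= 0:
            raise ValueError("tb_ratio must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be > 0")
        labels = [s.label for s in self.spheres]
        if len(labels) != len(set(labels)):
            raise GeometryError("sphere labels must be unique")

    @property
    def background_concentration(self) -> float:
        """a_B = a_H / (T/B); exact by construction."""
        return self.sphere_concentration / self.tb_ratio

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_concentration"] = self.background_concentration
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d.pop("background_concentration", None)
        d["spheres"] = tuple(
            SphereSpec(s["diameter"], tuple(s["center"]), s["label"])
            for s in d["spheres"]
        )
        d["body_outline"] = BodyOutline(**d["body_outline"])
        d["voxel_size"] = tuple(d["voxel_size"])
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class VoxelPhantom:
    """Co-registered activity, attenuation and label volumes."""

    activity: np.ndarray  # MBq/ml
    mu_map: np.ndarray  # cm^-1
    labels: np.ndarray  # int: 0 outside, 1 background, >=2 spheres
    spec: PhantomSpec

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.activity.shape

    def total_activity_mbq(self) -> float:
        return float(self.activity.sum() * self.spec.voxel_volume_ml)

    def compartment_volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label) * self.spec.voxel_volume_ml)


def grid_coordinates(
    grid_shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinate axes (mm), origin at the grid center."""
    axes = []
    for n, v in zip(grid_shape, voxel_size):
        axes.append((np.arange(n) - (n - 1) / 2.0) * v)
    # sparse axes broadcast in all the membership tests; full grids would
    # cost 3 x 8 bytes/voxel at the 1 mm reference resolution
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def build_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Voxelize a PhantomSpec by voxel-center-inside-surface membership.

    Raises
    ------
    GeometryError
        If any sphere pokes outside the body outline or two spheres overlap.
    """
    for i, a in enumerate(spec.spheres):
        for b in spec.spheres[i + 1 :]:
            gap = np.linalg.norm(np.subtract(a.center, b.center))
            if gap < a.radius + b.radius:
                raise GeometryError(f"spheres {a.label} and {b.label} overlap")
    # sphere extremal points must lie inside the body
    for s in spec.spheres:
        cx, cy, cz = s.center
        for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            p = np.array([cx + dx * s.radius, cy + dy * s.radius, cz + dz * s.radius])
            if not spec.body_outline.contains(*(np.atleast_1d(v) for v in p))[0]:
                raise GeometryError(f"sphere {s.label} extends outside the body outline")

    X, Y, Z = grid_coordinates(spec.grid_shape, spec.voxel_size)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[spec.body_outline.contains(X, Y, Z)] = 1
    for s in spec.spheres:
        cx, cy, cz = s.center
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= s.radius**2
        labels[inside] = s.label

    activity = np.zeros(spec.grid_shape, dtype=np.float64)
    activity[labels == 1] = spec.background_concentration
    activity[labels >= 2] = spec.sphere_concentration
    mu_map = np.where(labels > 0, spec.mu_fill, 0.0)
    return VoxelPhantom(activity=activity, mu_map=mu_map, labels=labels, spec=spec)


def decay_correct(concentration: float, elapsed: float, half_life: float = TC99M_HALF_LIFE_H) -> float:
    """Decay a concentration over ``elapsed`` hours: c * 2**(-elapsed/half_life)."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return concentration * 2.0 ** (-elapsed / half_life)


def voi_masks(phantom: VoxelPhantom) -> dict[int, np.ndarray]:
    """Ground-truth sphere VOI masks keyed by sphere label.

    Emulates CT-guided inner-edge delineation: the mask is exactly the voxel
    set labeled as the sphere.  Masks are disjoint and their union is
    ``labels >= 2``.
    """
    return {
        int(s.label): phantom.labels == s.label for s in phantom.spec.spheres
    }


def desk_spec(
    tb_ratio: float = 32.0,
    sphere_concentration: float = 0.20,
    voxel_mm: float = 5.5,
    grid_shape: tuple[int, int, int] = (64, 64, 32),
) -> PhantomSpec:
    """Reduced-resolution study profile used by the simulation sweeps.

    64 x 64 x 32 at 5.5 mm spans 352 x 352 x 176 mm, enough for the 300 x 230
    mm cross-section; the axial body extent is trimmed to 160 mm so the body
    stays inside the axial field of view.
    """
    return PhantomSpec(
        sphere_concentration=sphere_concentration,
        tb_ratio=tb_ratio,
        body_outline=BodyOutline(axial_length=160.0),
        voxel_size=(voxel_mm, voxel_mm, voxel_mm),
        grid_shape=grid_shape,
    )


#: Hot-sphere concentrations (MBq/ml) used for each T/B fill at acquisition time.
FILL_CONCENTRATIONS = {32.0: 0.20, 16.0: 0.11, 8.0: 0.06, 4.0: 0.03}
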