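"""Digital inter-comparison phantom.

Voxelised models of the elliptical body phantom (lung and spine inserts,
water fill) and of the dual-compartment concentric "shell sphere" source:
a hot inner sphere surrounded by a lower-concentration outer shell, filled
at a nominal 15:1 concentration ratio.  The phantom provides activity
(MBq/ml), density (g/ml) and linear-attenuation (cm^-1) maps plus exact
truth masks for every compartment.

Coordinate convention: voxel-centre sampling on a regular grid, axes aligned
with the phantom axes, origin at the phantom centre, spacing in mm.  Axis 0
and 1 span the transaxial (x, y) plane; axis 2 is the axial (z) direction,
which is also the rotation axis of the simulated camera orbit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "VoxelImage",
    "ShellSourceSpec",
    "BodyPhantomSpec",
    "GeometryError",
    "PlacementError",
    "make_shell_source",
    "make_body_phantom",
    "make_sphere_source",
    "make_disc_source",
    "mask_volume",
    "mu_map_from_density",
    "surface_depth",
    "NOMINAL_INNER_DIAMETER_MM",
    "NOMINAL_SHELL_THICKNESS_MM",
    "SHELL_SOURCE_VOLUMES_ML",
    "WATER_MASS_ATTENUATION_CM2_G",
]

# Nominal shell-sphere geometry (manufacturer specification).
NOMINAL_INNER_DIAMETER_MM = 36.0
NOMINAL_SHELL_THICKNESS_MM = 11.0

#: Measured (inner, outer-shell) volumes in ml of the six shell sources,
#: keyed by the site that received each one (H4 and H5 shared a source).
SHELL_SOURCE_VOLUMES_ML = {
    "H1": (26.1, 80.8),
    "H2": (26.0, 81.3),
    "H3": (26.3, 80.8),
    "H4": (26.7, 79.3),
    "H5": (26.7, 79.3),
    "H6": (26.0, 81.6),
    "H7": (27.2, 80.7),
}

#: Mass attenuation coefficient of water (cm^2/g) at the two main
#: Lu-177 gamma emissions, 113 keV (6%) and 208 keV (10%).
WATER_MASS_ATTENUATION_CM2_G = {113: 0.165, 208: 0.136}

_ROLES = frozenset({"activity", "mu", "density", "counts", "mask"})


class GeometryError(ValueError):
    """Non-physical phantom geometry (e.g. outer radius <= inner radius)."""


class PlacementError(ValueError):
    """Source placement intersecting an insert or leaving the body."""


@dataclass
class VoxelImage:
    """A 3-D scalar grid with physical spacing and origin.

    ``values[i, j, k]`` samples the field at the voxel centre
    ``origin + (i, j, k) * spacing`` (mm).  ``role`` tags the physical
    meaning: activity concentration (MBq/ml), attenuation mu (cm^-1),
    density (g/ml), reconstructed count rate (cps/voxel) or a binary mask.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "activity"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelImage requires a 3-D array")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "mask":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask images may contain only {0, 1}")
        elif self.role in ("activity", "density", "counts"):
            if np.any(self.values < 0):
                raise ValueError(f"{self.role} values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def coords(self):
        """Voxel-centre physical coordinates, one 1-D array per axis (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_grid(self, other: "VoxelImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, role: str | None = None) -> "VoxelImage":
        return VoxelImage(values, self.spacing, self.origin, role or self.role)

    # ---- NIfTI round trip ------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0]).astype(float)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, role: str = "activity") -> "VoxelImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
        origin = tuple(float(v) for v in affine[:3, 3])
        values = np.asarray(img.dataobj, dtype=float)
        if role == "mask":
            values = (values > 0.5).astype(np.uint8)
        return cls(values, spacing, origin, role)


def _centred_grid(n_xy: int, n_z: int, spacing: float):
    """Origin so that the grid of voxel centres is centred on (0, 0, 0)."""
    ox = -spacing * (n_xy - 1) / 2.0
    oz = -spacing * (n_z - 1) / 2.0
    return (ox, ox, oz)


def empty_grid(n_xy: int, n_z: int, spacing: float, role: str = "activity") -> VoxelImage:
    """An all-zero grid centred on the phantom origin (square in-plane)."""
    dtype = np.uint8 if role == "mask" else float
    return VoxelImage(
        np.zeros((n_xy, n_xy, n_z), dtype=dtype),
        (spacing, spacing, spacing),
        _centred_grid(n_xy, n_z, spacing),
        role,
    )


@dataclass(frozen=True)
class ShellSourceSpec:
    """Dual-compartment concentric sphere source.

    Radii are derived from the measured compartment volumes, not the nominal
    36-mm diameter: r_in = (3 V_in / 4 pi)^(1/3) and r_out solves
    (4 pi / 3)(r_out^3 - r_in^3) = V_out.  Compartment walls are modelled as
    zero thickness.
    """

    inner_volume_ml: float = 26.1
    outer_volume_ml: float = 80.8
    inner_concentration: float = 2.0  # MBq/ml
    outer_concentration: float = 2.0 / 15.0
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.inner_volume_ml <= 0 or self.outer_volume_ml <= 0:
            raise GeometryError("compartment volumes must be positive")
        if self.inner_concentration < 0 or self.outer_concentration < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.outer_radius_mm <= self.inner_radius_mm:
            raise GeometryError("outer radius must exceed inner radius")

    @property
    def inner_radius_mm(self) -> float:
        return (3.0 * self.inner_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def outer_radius_mm(self) -> float:
        total_mm3 = (self.inner_volume_ml + self.outer_volume_ml) * 1000.0
        return (3.0 * total_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def concentration_ratio(self) -> float:
        if self.outer_concentration == 0:
            return np.inf if self.inner_concentration > 0 else np.nan
        return self.inner_concentration / self.outer_concentration

    @classmethod
    def for_site(cls, site: str, inner_concentration: float = 2.0,
                 ratio: float = 15.0, **kw) -> "ShellSourceSpec":
        """The source shipped to a given site, filled at concentration ``ratio``."""
        v_in, v_out = SHELL_SOURCE_VOLUMES_ML[site]
        return cls(v_in, v_out, inner_concentration, inner_concentration / ratio, **kw)


@dataclass(frozen=True)
class BodyPhantomSpec:
    """Elliptical body phantom with lung and spine inserts.

    The body is an elliptical cylinder (internal axes 305 x 221 mm, height
    186 mm) filled with water; the lungs are low-density inserts (Styrofoam
    beads in water, ~0.3 g/ml) and the spine a bone-equivalent solution.
    Contour rings and the couch are not voxelised.
    """

    major_axis_mm: float = 305.0
    minor_axis_mm: float = 221.0
    height_mm: float = 186.0
    lung_density: float = 0.3
    lung_volumes_ml: tuple[float, float] = (900.0, 1100.0)  # (left, right)
    spine_inner_diameter_mm: float = 38.0
    spine_length_mm: float = 152.0
    spine_material_density: float = 1.33  # ~100 g K2HPO4 in 67 g water
    water_density: float = 1.0
    lung_centres_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (-78.0, 45.0),
        (78.0, 45.0),
    )
    spine_centre_mm: tuple[float, float] = (0.0, -72.0)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(_listify(data)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BodyPhantomSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**{k: _tuplify(v) for k, v in data.items()})


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    return obj


def _radius2_from(centre, grid: VoxelImage):
    x, y, z = grid.coords()
    dx = x - centre[0]
    dy = y - centre[1]
    dz = z - centre[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )


def make_shell_source(spec: ShellSourceSpec, spacing: float,
                      grid: VoxelImage | None = None) -> VoxelImage:
    """Voxelise the dual-compartment source as an activity map (MBq/ml).

    Voxels whose centre lies within r_in get the inner concentration, those
    in [r_in, r_out) the outer concentration, all others 0.  ``spacing`` must
    be <= 2 mm so that the geometry is resolved; pass ``grid`` to voxelise
    onto an existing grid instead of an automatically sized one.
    """
    if grid is None:
        if spacing > 2.0:
            raise ValueError("spacing must be <= 2 mm to resolve the shell source")
        r_out = spec.outer_radius_mm
        n = int(np.ceil(2 * (r_out + 2 * spacing) / spacing))
        grid = empty_grid(n, n, spacing)
        grid = VoxelImage(
            grid.values,
            grid.spacing,
            tuple(o + c for o, c in zip(grid.origin, spec.centre_mm)),
            "activity",
        )
    r2 = _radius2_from(spec.centre_mm, grid)
    values = np.zeros(grid.shape)
    values[r2 < spec.inner_radius_mm ** 2] = spec.inner_concentration
    shell = (r2 >= spec.inner_radius_mm ** 2) & (r2 < spec.outer_radius_mm ** 2)
    values[shell] = spec.outer_concentration
    return grid.with_values(values, "activity")


def shell_source_masks(spec: ShellSourceSpec, grid: VoxelImage) -> dict[str, VoxelImage]:
    """Exact truth masks (inner, outer shell) of the source on ``grid``."""
    r2 = _radius2_from(spec.centre_mm, grid)
    inner = (r2 < spec.inner_radius_mm ** 2).astype(np.uint8)
    outer = (
        (r2 >= spec.inner_radius_mm ** 2) & (r2 < spec.outer_radius_mm ** 2)
    ).astype(np.uint8)
    return {
        "inner": grid.with_values(inner, "mask"),
        "outer": grid.with_values(outer, "mask"),
    }


def _ellipse_mask(grid: VoxelImage, centre_xy, semi_x, semi_y, half_height):
    x, y, z = grid.coords()
    in_plane = (
        ((x[:, None] - centre_xy[0]) / semi_x) ** 2
        + ((y[None, :] - centre_xy[1]) / semi_y) ** 2
    ) <= 1.0
    in_z = np.abs(z) <= half_height
    return in_plane[:, :, None] & in_z[None, None, :]


def make_body_phantom(
    spec: BodyPhantomSpec,
    source: ShellSourceSpec,
    spacing: float,
    n_xy: int | None = None,
    n_z: int | None = None,
):
    """Build activity, density and truth-mask maps of the filled phantom.

    Returns ``(activity, density, masks)`` where ``masks`` holds binary
    truth masks for ``inner``, ``outer`` (shell), ``lungs``, ``spine`` and
    ``body``.  The source must fit inside the water compartment without
    touching the lung or spine inserts.
    """
    if n_xy is None:
        n_xy = int(np.ceil((spec.major_axis_mm + 2 * spacing) / spacing))
    if n_z is None:
        n_z = int(np.ceil((spec.height_mm + 2 * spacing) / spacing))
    grid = empty_grid(n_xy, n_z, spacing)

    a = spec.major_axis_mm / 2.0
    b = spec.minor_axis_mm / 2.0
    hh = spec.height_mm / 2.0
    body = _ellipse_mask(grid, (0.0, 0.0), a, b, hh)

    # Lungs: vertical elliptical cylinders (2:1 in-plane aspect) of the
    # specified volumes, spanning a fixed fraction of the body height.
    lung_height = 0.85 * spec.height_mm
    lungs = np.zeros(grid.shape, dtype=bool)
    for (cx, cy), vol_ml in zip(spec.lung_centres_mm, spec.lung_volumes_ml):
        area_mm2 = vol_ml * 1000.0 / lung_height
        semi_minor = np.sqrt(area_mm2 / (2.0 * np.pi))
        lungs |= _ellipse_mask(grid, (cx, cy), 2.0 * semi_minor, semi_minor,
                               lung_height / 2.0)
    lungs &= body

    sx, sy = spec.spine_centre_mm
    spine = _ellipse_mask(
        grid, (sx, sy),
        spec.spine_inner_diameter_mm / 2.0,
        spec.spine_inner_diameter_mm / 2.0,
        spec.spine_length_mm / 2.0,
    )
    spine &= body

    # Source placement checks: inside the body, clear of the inserts.
    r2 = _radius2_from(source.centre_mm, grid)
    source_region = r2 < source.outer_radius_mm ** 2
    if np.any(source_region & ~body):
        raise PlacementError("shell source extends outside the body phantom")
    if np.any(source_region & (lungs | spine)):
        raise PlacementError("shell source overlaps a lung or spine insert")

    density = np.zeros(grid.shape)
    density[body] = spec.water_density
    density[lungs] = spec.lung_density
    density[spine] = spec.spine_material_density

    activity = make_shell_source(source, spacing, grid=grid)

    masks = shell_source_masks(source, grid)
    masks["lungs"] = grid.with_values(lungs.astype(np.uint8), "mask")
    masks["spine"] = grid.with_values(spine.astype(np.uint8), "mask")
    masks["body"] = grid.with_values(body.astype(np.uint8), "mask")
    return activity, grid.with_values(density, "density"), masks


def make_sphere_source(
    volume_ml: float,
    concentration: float,
    grid: VoxelImage,
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
):
    """Uniform sphere of given volume on an existing grid.

    Returns ``(activity, mask)``.  Used for calibration geometries
    (16-ml calibration spheres, the 130-ml bottle, recovery-curve spheres).
    """
    if volume_ml <= 0:
        raise GeometryError("sphere volume must be positive")
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r2 = _radius2_from(centre_mm, grid)
    mask = r2 < radius ** 2
    activity = np.where(mask, concentration, 0.0)
    return (
        grid.with_values(activity, "activity"),
        grid.with_values(mask.astype(np.uint8), "mask"),
    )


def make_disc_source(
    activity_mbq: float,
    diameter_mm: float,
    grid: VoxelImage,
    thickness_mm: float | None = None,
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelImage:
    """Thin disc source (petri dish) for planar calibration imaging.

    The disc lies in the (x, z) plane so it faces the detector of a planar
    acquisition along the y axis.  Total activity equals ``activity_mbq``
    exactly (concentration set from the voxelised disc volume).
    """
    if activity_mbq < 0:
        raise ValueError("activity must be nonnegative")
    if thickness_mm is None:
        thickness_mm = grid.spacing[1]
    x, y, z = grid.coords()
    in_plane = (
        (x[:, None] - centre_mm[0]) ** 2 + (z[None, :] - centre_mm[2]) ** 2
    ) <= (diameter_mm / 2.0) ** 2
    in_y = np.abs(y - centre_mm[1]) <= thickness_mm / 2.0
    mask = in_plane[:, None, :] & in_y[None, :, None]
    n = int(mask.sum())
    if n == 0:
        raise GeometryError("disc not resolved on this grid")
    conc = activity_mbq / (n * grid.voxel_volume_ml)
    return grid.with_values(np.where(mask, conc, 0.0), "activity")


def mask_volume(mask: VoxelImage) -> float:
    """Volume of a binary mask in ml (count of 1-voxels x voxel volume)."""
    if mask.role != "mask":
        raise ValueError("mask_volume requires a mask-role image")
    return float(mask.values.sum()) * mask.voxel_volume_ml


def mu_map_from_density(density: VoxelImage, energy_kev: int,
                        mass_attenuation: dict[int, float] | None = None) -> VoxelImage:
    """Linear attenuation map mu = density x (mu/rho)_water at ``energy_kev``.

    Only the two main Lu-177 emission energies (113 and 208 keV) are
    supported; all phantom materials use the water mass-attenuation
    coefficient scaled by density (adequate for water, lung and the
    phosphate bone-equivalent at these energies).
    """
    if density.role != "density":
        raise ValueError("mu_map_from_density requires a density-role image")
    table = mass_attenuation or WATER_MASS_ATTENUATION_CM2_G
    if energy_kev not in table:
        raise ValueError(f"unsupported energy {energy_kev} keV; have {sorted(table)}")
    mu = density.values * table[energy_kev]
    return density.with_values(mu, "mu")


def surface_depth(spec: BodyPhantomSpec, point_mm) -> float:
    """Euclidean distance from a point to the nearest body-phantom surface.

    Used for depth-matched calibration-factor selection: the boundary of the
    in-plane ellipse is sampled densely and the axial faces checked directly.
    """
    px, py, pz = point_mm
    t = np.linspace(0, 2 * np.pi, 1441)
    bx = (spec.major_axis_mm / 2.0) * np.cos(t)
    by = (spec.minor_axis_mm / 2.0) * np.sin(t)
    d_side = np.sqrt((bx - px) ** 2 + (by - py) ** 2).min()
    d_axial = spec.height_mm / 2.0 - abs(pz)
    return float(min(d_side, d_axial))


def water_body(spec: BodyPhantomSpec, spacing: float, n_xy: int, n_z: int) -> VoxelImage:
    """Plain water-filled body (no inserts) as a density map.

    Stand-in for the various water-filled calibration phantoms (cylindrical
    or elliptical Jaszczak) at desk scale.
    """
    grid = empty_grid(n_xy, n_z, spacing)
    body = _ellipse_mask(
        grid, (0.0, 0.0), spec.major_axis_mm / 2.0, spec.minor_axis_mm / 2.0,
        spec.height_mm / 2.0,
    )
    return grid.with_values(np.where(body, spec.water_density, 0.0), "density")
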