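"""Synthetic gamma-camera: multi-window SPECT projections and planar images.

Stands in for the seven sites' physical cameras.  Primary photons are
parallel-beam line integrals of the activity, attenuated by the 113- or
208-keV mu map and blurred with a depth-dependent collimator-detector
response; scatter is a kernel/fraction model (not Monte Carlo): each energy
window receives a configurable fraction of the wide-blurred, unattenuated
projection of the activity.  Per-window fractions default to a flat
scatter-density-per-keV anchored at the photopeak fraction, which makes the
triple-energy-window estimator unbiased in expectation under this model.
Counts are Poisson samples of the window means; the pre-noise primary and
scatter components are stored separately so that an "ideal" scatter
correction (the desk-scale surrogate for the sites' Monte Carlo and ESSE
corrections) is available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import VoxelImage, mu_map_from_density
from .projector import SystemModel, fwhm_to_sigma

__all__ = [
    "EnergyWindow",
    "ScatterModel",
    "AcquisitionConfig",
    "ProjectionSet",
    "forward_project",
    "scatter_project",
    "acquire",
    "planar_acquire",
    "orbit_radii",
    "DEFAULT_SENSITIVITY_CPS_PER_MBQ",
]

#: Default per-photopeak system sensitivity (cps/MBq per head) for a
#: medium-energy collimator.  Absolute values are free parameters of the
#: simulation (quantification is relative to the simulated calibration);
#: the 113-keV value is scaled by the relative emission probability (6% vs
#: 10%).
DEFAULT_SENSITIVITY_CPS_PER_MBQ = {208: 10.0, 113: 6.0}


@dataclass(frozen=True)
class EnergyWindow:
    """An acquisition energy window, e.g. 208 keV +/- 10%.

    ``role`` is one of ``photopeak``, ``lower_scatter``, ``upper_scatter``.
    ``psf_scale`` widens the collimator response for this window (the
    113-keV photopeak images slightly worse than 208 keV).
    """

    centre_kev: float
    half_width_fraction: float
    role: str = "photopeak"
    psf_scale: float = 1.0

    def __post_init__(self):
        if self.role not in ("photopeak", "lower_scatter", "upper_scatter"):
            raise ValueError(f"unknown window role {self.role!r}")
        if self.width_kev <= 0:
            raise ValueError("window width must be positive")

    @property
    def width_kev(self) -> float:
        return 2.0 * self.centre_kev * self.half_width_fraction

    @property
    def name(self) -> str:
        prefix = "pk" if self.role == "photopeak" else "sc"
        return f"{prefix}{self.centre_kev:g}"


def photopeak_208(half_width_fraction: float = 0.10) -> EnergyWindow:
    return EnergyWindow(208.0, half_width_fraction, "photopeak")


def photopeak_113(half_width_fraction: float = 0.10) -> EnergyWindow:
    return EnergyWindow(113.0, half_width_fraction, "photopeak", psf_scale=1.1)


@dataclass(frozen=True)
class ScatterModel:
    """Fraction-and-kernel scatter model.

    ``photopeak_fraction[E]`` is the scatter-to-unattenuated-primary ratio
    in the photopeak window at energy E; adjacent scatter windows receive
    the flat per-keV density ``photopeak_fraction[E] / width(photopeak)``
    times their own width.  The spatial distribution is the unattenuated
    projection blurred with a wide Gaussian (``kernel_fwhm_mm``).
    """

    photopeak_fraction: dict = field(
        default_factory=lambda: {208: 0.15, 113: 0.30}
    )
    kernel_fwhm_mm: float = 40.0

    def window_fraction(self, window: EnergyWindow,
                        photopeaks: list[EnergyWindow]) -> float:
        if window.role == "photopeak":
            return float(self.photopeak_fraction.get(round(window.centre_kev), 0.0))
        # scatter window: flat per-keV density from the nearest photopeak
        parent = min(photopeaks, key=lambda p: abs(p.centre_kev - window.centre_kev))
        f_pp = float(self.photopeak_fraction.get(round(parent.centre_kev), 0.0))
        return f_pp / parent.width_kev * window.width_kev


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and physics settings for one SPECT scan.

    Defaults mirror the common protocol of the inter-comparison sites:
    120 projections over 360 degrees, 30 s per projection, 128 x 128
    matrix at 4.8 mm pixels, medium-energy collimator response
    (FWHM ~4 mm intrinsic growing by 0.05 mm per mm of distance, i.e.
    ~9 mm at 10 cm).  Desk-scale runs typically use a 64 in-plane grid at
    the same 4.8-mm pixel size; the simulated detector raster always
    matches the phantom grid, with ``matrix`` recording the nominal
    acquisition matrix.
    """

    n_projections: int = 120
    matrix: int = 128
    pixel_mm: float = 4.8
    time_per_projection_s: float = 30.0
    orbit: str = "contoured"
    orbit_clearance_mm: float = 20.0
    orbit_radius_mm: float | None = None
    windows: tuple[EnergyWindow, ...] = (photopeak_208(),)
    sensitivity_cps_per_mbq: dict = field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY_CPS_PER_MBQ)
    )
    psf_fwhm_intrinsic_mm: float = 4.0
    psf_fwhm_slope: float = 0.05
    scatter: ScatterModel = field(default_factory=ScatterModel)
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_projections <= 0 or self.matrix <= 0:
            raise ValueError("n_projections and matrix must be positive")
        if self.time_per_projection_s <= 0:
            raise ValueError("time per projection must be positive")
        if self.orbit not in ("circular", "contoured"):
            raise ValueError("orbit must be 'circular' or 'contoured'")

    @property
    def angles_deg(self) -> np.ndarray:
        """Detector angles: start at 0 deg (anterior), clockwise steps."""
        return np.arange(self.n_projections) * (360.0 / self.n_projections)

    def photopeaks(self) -> list[EnergyWindow]:
        return [w for w in self.windows if w.role == "photopeak"]

    def window_by_name(self, name: str) -> EnergyWindow:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(f"no window named {name!r}")

    def sensitivity_for(self, window: EnergyWindow) -> float:
        key = round(window.centre_kev)
        try:
            return float(self.sensitivity_cps_per_mbq[key])
        except KeyError:
            raise KeyError(f"no sensitivity configured for {key} keV") from None

    def psf_for(self, window: EnergyWindow) -> tuple[float, float]:
        return (
            self.psf_fwhm_intrinsic_mm * window.psf_scale,
            self.psf_fwhm_slope * window.psf_scale,
        )


def orbit_radii(config: AcquisitionConfig, body_semi_axes_mm=(152.5, 110.5)) -> np.ndarray:
    """Per-angle distance of the collimator face from the rotation centre.

    Contoured orbits follow the body-ellipse support function plus a
    clearance margin; circular orbits use the maximum of that profile (or an
    explicit radius).
    """
    a, b = body_semi_axes_mm
    th = np.deg2rad(config.angles_deg)
    support = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
    if config.orbit == "contoured":
        return support + config.orbit_clearance_mm
    if config.orbit_radius_mm is not None:
        return np.full_like(support, float(config.orbit_radius_mm))
    return np.full_like(support, a + config.orbit_clearance_mm)


@dataclass
class ProjectionSet:
    """Per-window projection stacks plus acquisition metadata.

    ``counts[name]`` has shape (n_projections, nu, nv); ``components[name]``
    holds the pre-noise ``primary`` and ``scatter`` means, which sum to the
    sampled distribution's mean.
    """

    counts: dict
    angles_deg: np.ndarray
    config: AcquisitionConfig
    orbit_radii_mm: np.ndarray
    components: dict | None = None
    pixel_mm: float = 4.8

    def window_names(self):
        return list(self.counts)

    def __eq__(self, other):
        if not isinstance(other, ProjectionSet):
            return NotImplemented
        return (
            self.window_names() == other.window_names()
            and all(np.array_equal(self.counts[k], other.counts[k])
                    for k in self.counts)
            and np.array_equal(self.angles_deg, other.angles_deg)
        )

    def save(self, directory) -> None:
        """One NIfTI stack per window plus a JSON sidecar of the metadata."""
        import json
        from pathlib import Path

        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, stack in self.counts.items():
            img = nib.Nifti1Image(np.asarray(stack, dtype=np.float32),
                                  np.eye(4))
            nib.save(img, str(directory / f"counts_{name}.nii.gz"))
        sidecar = {
            "windows": [
                {"centre_kev": w.centre_kev,
                 "half_width_fraction": w.half_width_fraction,
                 "role": w.role, "psf_scale": w.psf_scale}
                for w in self.config.windows
            ],
            "angles_deg": list(map(float, self.angles_deg)),
            "orbit_radii_mm": list(map(float, self.orbit_radii_mm)),
            "pixel_mm": self.pixel_mm,
            "time_per_projection_s": self.config.time_per_projection_s,
            "rng_seed": self.config.rng_seed,
        }
        (directory / "acquisition.json").write_text(json.dumps(sidecar,
                                                               indent=2))

    @classmethod
    def load(cls, directory) -> "ProjectionSet":
        """Counterpart of :meth:`save` (pre-noise components are not kept)."""
        import json
        from pathlib import Path

        import nibabel as nib

        directory = Path(directory)
        meta = json.loads((directory / "acquisition.json").read_text())
        windows = tuple(EnergyWindow(**w) for w in meta["windows"])
        config = AcquisitionConfig(
            n_projections=len(meta["angles_deg"]),
            windows=windows,
            time_per_projection_s=meta["time_per_projection_s"],
            rng_seed=meta["rng_seed"],
        )
        counts = {}
        for w in windows:
            path = directory / f"counts_{w.name}.nii.gz"
            counts[w.name] = np.asarray(nib.load(str(path)).dataobj,
                                        dtype=float)
        return cls(
            counts=counts,
            angles_deg=np.asarray(meta["angles_deg"]),
            config=config,
            orbit_radii_mm=np.asarray(meta["orbit_radii_mm"]),
            components=None,
            pixel_mm=float(meta["pixel_mm"]),
        )


def _voxel_activity_mbq(activity: VoxelImage) -> np.ndarray:
    return activity.values * activity.voxel_volume_ml


def _check_same_grid(activity: VoxelImage, mu: VoxelImage | None):
    if mu is not None and not activity.same_grid(mu):
        raise ValueError("activity and mu must live on the same grid")


def forward_project(
    activity: VoxelImage,
    mu: VoxelImage | None,
    config: AcquisitionConfig,
    angle_deg: float,
    window: EnergyWindow | None = None,
    orbit_radius_mm: float | None = None,
    blur: bool = True,
) -> np.ndarray:
    """Mean primary counts in one view for one photopeak window.

    Attenuated, depth-blurred parallel projection of the activity, scaled by
    the window sensitivity and the time per projection; linear in activity.
    """
    _check_same_grid(activity, mu)
    window = window or config.photopeaks()[0]
    if orbit_radius_mm is None:
        orbit_radius_mm = float(np.max(orbit_radii(config)))
    model = SystemModel(
        activity.shape,
        activity.spacing[0],
        [angle_deg],
        [orbit_radius_mm],
        mu=None if mu is None else mu.values,
        psf=config.psf_for(window) if blur else None,
    )
    scale = config.sensitivity_for(window) * config.time_per_projection_s
    return scale * model.forward(_voxel_activity_mbq(activity), 0)


def scatter_project(
    activity: VoxelImage,
    mu: VoxelImage | None,
    config: AcquisitionConfig,
    angle_deg: float,
    window: EnergyWindow | None = None,
) -> np.ndarray:
    """Mean scatter counts in one view for one window.

    A configurable fraction of the unattenuated broad-beam primary,
    convolved with a wide Gaussian kernel; zero fraction yields zeros.
    ``mu`` is accepted for interface symmetry (grid check) but does not
    enter the scatter estimate.
    """
    _check_same_grid(activity, mu)
    window = window or config.photopeaks()[0]
    photopeaks = config.photopeaks()
    frac = config.scatter.window_fraction(window, photopeaks)
    # scatter is referenced to the photopeak the window serves
    ref = (
        window
        if window.role == "photopeak"
        else min(photopeaks, key=lambda p: abs(p.centre_kev - window.centre_kev))
    )
    model = SystemModel(
        activity.shape, activity.spacing[0], [angle_deg], [0.0], mu=None, psf=None
    )
    p0 = model.forward(_voxel_activity_mbq(activity), 0)
    if frac == 0.0:
        return np.zeros_like(p0)
    sigma_px = fwhm_to_sigma(config.scatter.kernel_fwhm_mm) / activity.spacing[0]
    scale = config.sensitivity_for(ref) * config.time_per_projection_s
    return frac * scale * gaussian_filter(p0, sigma_px, mode="constant")


def acquire(
    activity: VoxelImage,
    density: VoxelImage | None,
    config: AcquisitionConfig,
    seed: int | None = None,
    noise: bool = True,
) -> ProjectionSet:
    """Simulate a full SPECT acquisition of the phantom.

    For every angle and configured window the mean is primary (photopeak
    windows only) plus scatter; counts are Poisson samples under the given
    seed (``noise=False`` returns the means).  Pre-noise primary/scatter
    components are stored per window.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    spacing = activity.spacing[0]
    radii = orbit_radii(config)
    vox_mbq = _voxel_activity_mbq(activity)

    mu_by_peak: dict[str, np.ndarray | None] = {}
    for pk in config.photopeaks():
        if density is None:
            mu_by_peak[pk.name] = None
        else:
            mu_by_peak[pk.name] = mu_map_from_density(
                density, round(pk.centre_kev)
            ).values

    angles = config.angles_deg
    counts: dict[str, np.ndarray] = {}
    components: dict[str, dict[str, np.ndarray]] = {}

    # unattenuated, unblurred projections drive the scatter model
    geo = SystemModel(activity.shape, spacing, angles, radii, mu=None, psf=None)
    p0 = geo.forward_all(vox_mbq)
    sigma_sc = fwhm_to_sigma(config.scatter.kernel_fwhm_mm) / spacing
    p0_wide = np.stack([gaussian_filter(p, sigma_sc, mode="constant") for p in p0])

    photopeaks = config.photopeaks()
    for w in config.windows:
        ref = (
            w if w.role == "photopeak"
            else min(photopeaks, key=lambda p: abs(p.centre_kev - w.centre_kev))
        )
        scale = config.sensitivity_for(ref) * config.time_per_projection_s
        frac = config.scatter.window_fraction(w, photopeaks)
        scatter = frac * scale * p0_wide
        if w.role == "photopeak":
            model = SystemModel(
                activity.shape, spacing, angles, radii,
                mu=mu_by_peak[w.name], psf=config.psf_for(w),
            )
            primary = scale * model.forward_all(vox_mbq)
            del model
        else:
            primary = np.zeros_like(scatter)
        mean = primary + scatter
        counts[w.name] = (
            rng.poisson(np.clip(mean, 0.0, None)).astype(float) if noise else mean
        )
        components[w.name] = {"primary": primary, "scatter": scatter}

    return ProjectionSet(
        counts=counts,
        angles_deg=angles,
        config=config,
        orbit_radii_mm=radii,
        components=components,
        pixel_mm=spacing,
    )


def planar_acquire(
    activity: VoxelImage,
    config: AcquisitionConfig,
    distance_mm: float = 100.0,
    window: EnergyWindow | None = None,
    background_cps_per_pixel: float = 0.0,
    seed: int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Single planar image of a thin source at a fixed collimator distance.

    No attenuation by default (air gap); blur at the given distance; a
    uniform background count rate can be added per pixel (e.g. room
    background for the petri-dish calibration).
    """
    window = window or config.photopeaks()[0]
    model = SystemModel(
        activity.shape, activity.spacing[0], [0.0], [distance_mm],
        mu=None, psf=config.psf_for(window),
    )
    scale = config.sensitivity_for(window) * config.time_per_projection_s
    mean = scale * model.forward(_voxel_activity_mbq(activity), 0)
    mean = mean + background_cps_per_pixel * config.time_per_projection_s
    if not noise:
        return mean
    rng = np.random.default_rng(seed if seed is not None else config.rng_seed)
    return rng.poisson(np.clip(mean, 0.0, None)).astype(float)
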