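"""Run the seven site protocols on a simulated comparison source.

Each preset bundles one hospital's acquisition, reconstruction,
segmentation, calibration and uncertainty choices:

========  ==========================  =====================  ==========================
protocol  reconstruction              segmentation           calibration
========  ==========================  =====================  ==========================
H1        OSEM 6i/6s, TEW, RR         CT sphere + 10 mm      large homogeneous bottle
H2        OSEM 8i/4s, no SC, no RR,   iso-contour 35%/10%    shell source at depths
          dual photopeak sum          (calibrated)
H3        OSEM 16i/5s, ideal SC, RR,  CT spheres             16-ml sphere, centre
          dual photopeak sum
H4        OSEM 24i/24s, TEW, RR,      freehand (truth)       16-ml sphere, 3 positions
          dual photopeak sum
H5        OSEM 5i/10s, TEW            CT spheres             16-ml sphere, 3 positions
          pre-subtracted, no RR                              x 2 VOIs
H6        OSEM 5i/15s, ideal SC, RR,  fixed 8-cm sphere,     large homogeneous cylinder
          8-mm Gaussian filter        inner only
H7        OSEM 8i/10s, ideal SC, RR,  Otsu (inner), manual   planar petri dishes +
          60 s/projection             whole source           recovery curve
========  ==========================  =====================  ==========================

"Monte Carlo" and "ESSE" scatter corrections are emulated by the ideal
(true simulated scatter) mode.  The report gathers percent differences
against the digital truth, their spread (max - min), mean bias and the
proportion of protocols within 5/10/20/50/75/100% of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration as cal
from . import segmentation as seg
from .phantom import (
    BodyPhantomSpec,
    ShellSourceSpec,
    VoxelImage,
    empty_grid,
    make_body_phantom,
    make_disc_source,
    make_shell_source,
    make_sphere_source,
    mask_volume,
    mu_map_from_density,
    shell_source_masks,
    surface_depth,
    water_body,
)
from .quantify import QuantResult, activity_estimate, counts_in_voi, uncertainty_estimate
from .recon import ReconConfig, ReconVolume, gaussian_postfilter, osem_reconstruct, sum_photopeaks, tew_estimate
from .simulator import (
    AcquisitionConfig,
    EnergyWindow,
    ProjectionSet,
    acquire,
    photopeak_113,
    photopeak_208,
    planar_acquire,
)

__all__ = [
    "PhantomBundle",
    "SiteProtocol",
    "ProtocolResult",
    "ComparisonReport",
    "make_comparison_phantom",
    "site_protocols",
    "ideal_protocol",
    "run_protocol",
    "reconstruct_protocol",
    "percent_difference",
    "within_threshold_table",
    "compile_report",
    "recovery_coefficients_for_spheres",
    "DEFAULT_THRESHOLDS_PCT",
]

DEFAULT_THRESHOLDS_PCT = (5.0, 10.0, 20.0, 50.0, 75.0, 100.0)

#: Relative standard uncertainty assumed for a dispensed calibration
#: activity or activity concentration (dose-calibrator certificate level).
ACTIVITY_REL_SIGMA = 0.02


# ---------------------------------------------------------------------------
# phantom bundle
# ---------------------------------------------------------------------------
@dataclass
class PhantomBundle:
    """A voxelised comparison phantom plus its digital ground truth.

    Truth volumes and activities are those of the phantom *as voxelised*
    (mask volumes and voxel activity sums), so protocol percent differences
    measure protocol error rather than voxelisation error.
    """

    activity: VoxelImage
    density: VoxelImage
    masks: dict
    body: BodyPhantomSpec
    source: ShellSourceSpec

    @property
    def grid(self) -> VoxelImage:
        return self.activity

    def truth_volume(self, compartment: str) -> float:
        if compartment == "total":
            return self.truth_volume("inner") + self.truth_volume("outer")
        return mask_volume(self.masks[compartment])

    def truth_activity(self, compartment: str) -> float:
        if compartment == "total":
            return self.truth_activity("inner") + self.truth_activity("outer")
        m = self.masks[compartment].values.astype(bool)
        return float(self.activity.values[m].sum()) * self.activity.voxel_volume_ml

    def mu(self, energy_kev: int) -> VoxelImage:
        return mu_map_from_density(self.density, energy_kev)


def make_comparison_phantom(
    source_id: str = "H1",
    inner_concentration: float = 2.0,
    ratio: float = 15.0,
    spacing: float = 4.8,
    n_xy: int = 64,
    n_z: int = 64,
    centre_mm=(0.0, 0.0, 0.0),
    body: BodyPhantomSpec | None = None,
) -> PhantomBundle:
    """The comparison set-up: one site's shell source centred in the body."""
    body = body or BodyPhantomSpec()
    source = ShellSourceSpec.for_site(
        source_id, inner_concentration=inner_concentration, ratio=ratio,
        centre_mm=tuple(centre_mm),
    )
    activity, density, masks = make_body_phantom(
        body, source, spacing, n_xy=n_xy, n_z=n_z
    )
    return PhantomBundle(activity, density, masks, body, source)


# ---------------------------------------------------------------------------
# protocol presets
# ---------------------------------------------------------------------------
def _sc(centre, role):
    return EnergyWindow(centre, 0.05, role)


@dataclass(frozen=True)
class SiteProtocol:
    """One site's full protocol: acquisition + recon + seg + calibration."""

    name: str
    acquisition: AcquisitionConfig
    recon: ReconConfig
    segmentation: str
    calibration: str
    uncertainty: str
    seg_params: dict = field(default_factory=dict)
    calib_params: dict = field(default_factory=dict)


def site_protocols(n_projections: int = 120) -> dict[str, SiteProtocol]:
    """The seven hospital presets (desk-scale angle count configurable)."""
    acq = dict(n_projections=n_projections)
    protocols = {}

    protocols["H1"] = SiteProtocol(
        "H1",
        AcquisitionConfig(
            windows=(photopeak_208(),
                     _sc(176.8, "lower_scatter"), _sc(239.2, "upper_scatter")),
            orbit="contoured", **acq,
        ),
        ReconConfig(6, 6, "TEW", resolution_recovery=True, photopeaks=(208,)),
        segmentation="ct_sphere_margin",
        calibration="large_homogeneous",
        uncertainty="calibration",
        seg_params={"margin_mm": 10.0},
        calib_params={"volume_ml": 130.0, "concentration": 2.0},
    )
    protocols["H2"] = SiteProtocol(
        "H2",
        AcquisitionConfig(
            windows=(photopeak_113(0.075), photopeak_208()),
            orbit="circular", **acq,
        ),
        ReconConfig(8, 4, "none", resolution_recovery=False, photopeaks=(113, 208)),
        segmentation="iso_contour",
        calibration="shell_matched",
        uncertainty="calibration",
        seg_params={"inner_fraction": 0.35, "outer_fraction": 0.10,
                    "calibrate_thresholds": True},
        calib_params={"concentration": 2.0,
                      "offsets_mm": (0.0, 50.0, 95.0)},
    )
    protocols["H3"] = SiteProtocol(
        "H3",
        AcquisitionConfig(
            windows=(photopeak_113(), photopeak_208()),
            orbit="contoured", **acq,
        ),
        ReconConfig(16, 5, "ideal", resolution_recovery=True, photopeaks=(113, 208)),
        segmentation="ct_sphere",
        calibration="sphere16ml",
        uncertainty="calibration",
        calib_params={"activity_mbq": 20.0, "offsets_mm": (0.0,),
                      "media": ("water",)},
    )
    protocols["H4"] = SiteProtocol(
        "H4",
        AcquisitionConfig(
            windows=(photopeak_113(), photopeak_208(),
                     _sc(98.7, "lower_scatter"), _sc(131.0, "upper_scatter"),
                     _sc(178.0, "lower_scatter"), _sc(214.0, "upper_scatter")),
            orbit="contoured", **acq,
        ),
        ReconConfig(24, 24, "TEW", resolution_recovery=True, photopeaks=(113, 208)),
        segmentation="manual",
        calibration="sphere16ml",
        uncertainty="calibration_plus_voi_poisson",
        calib_params={"activity_mbq": 35.0, "offsets_mm": (0.0, 0.0, 110.0),
                      "media": ("air", "water", "water")},
    )
    protocols["H5"] = SiteProtocol(
        "H5",
        AcquisitionConfig(
            windows=(photopeak_208(),
                     _sc(178.0, "lower_scatter"), _sc(214.0, "upper_scatter")),
            orbit="contoured", **acq,
        ),
        ReconConfig(5, 10, "TEW", resolution_recovery=False, photopeaks=(208,),
                    presubtract_scatter=True),
        segmentation="ct_sphere",
        calibration="sphere16ml_two_vois",
        uncertainty="calibration_plus_activity",
        calib_params={"activity_mbq": 25.0, "offsets_mm": (0.0, 0.0, 110.0),
                      "media": ("air", "water", "water")},
    )
    protocols["H6"] = SiteProtocol(
        "H6",
        AcquisitionConfig(windows=(photopeak_208(),), orbit="circular", **acq),
        ReconConfig(5, 15, "ideal", resolution_recovery=True, photopeaks=(208,),
                    post_filter_fwhm_mm=8.0),
        segmentation="fixed_sphere",
        calibration="large_cylinder",
        uncertainty="none",
        seg_params={"diameter_mm": 80.0, "inner_only": True},
        calib_params={"activity_mbq": 120.0, "volume_ml": 6900.0},
    )
    protocols["H7"] = SiteProtocol(
        "H7",
        AcquisitionConfig(
            windows=(photopeak_208(),), orbit="contoured",
            time_per_projection_s=60.0, **acq,
        ),
        ReconConfig(8, 10, "ideal", resolution_recovery=True, photopeaks=(208,)),
        segmentation="otsu_plus_manual",
        calibration="planar_petri",
        uncertainty="calibration_plus_recovery",
        calib_params={"dish_activity_mbq": 40.0, "n_dishes": 5,
                      "recovery_volumes_ml": (8.0, 16.0, 33.0, 100.0),
                      "recovery_concentration": 2.0},
    )
    return protocols


def ideal_protocol(n_projections: int = 60) -> SiteProtocol:
    """Best-case pipeline: truth VOIs, ideal scatter, oracle calibration."""
    return SiteProtocol(
        "ideal",
        AcquisitionConfig(windows=(photopeak_208(),), orbit="contoured",
                          n_projections=n_projections),
        ReconConfig(20, 6, "ideal", resolution_recovery=True, photopeaks=(208,)),
        segmentation="truth",
        calibration="oracle",
        uncertainty="none",
    )


# ---------------------------------------------------------------------------
# reconstruction driver
# ---------------------------------------------------------------------------
def _effective_subsets(n_angles: int, subsets: int) -> int:
    """Largest divisor of the angle count not exceeding the preset."""
    for s in range(min(subsets, n_angles), 0, -1):
        if n_angles % s == 0:
            return s
    return 1


def _tew_neighbours(config: AcquisitionConfig, peak: EnergyWindow):
    lowers = [w for w in config.windows
              if w.role == "lower_scatter" and w.centre_kev < peak.centre_kev]
    uppers = [w for w in config.windows
              if w.role == "upper_scatter" and w.centre_kev > peak.centre_kev]
    if not lowers or not uppers:
        raise KeyError(f"no TEW scatter windows around {peak.name}")
    low = min(lowers, key=lambda w: peak.centre_kev - w.centre_kev)
    up = min(uppers, key=lambda w: w.centre_kev - peak.centre_kev)
    return low, up


def reconstruct_protocol(
    projections: ProjectionSet,
    density: VoxelImage | None,
    protocol: SiteProtocol,
) -> ReconVolume:
    """Scatter handling, per-photopeak OSEM, summation and post-filter."""
    rc = protocol.recon
    n_angles = len(projections.angles_deg)
    eff = _effective_subsets(n_angles, rc.subsets)
    rc = replace(rc, subsets=eff)
    acq = projections.config
    recons = []
    for energy in rc.photopeaks:
        peak = next(w for w in acq.photopeaks()
                    if round(w.centre_kev) == energy)
        if rc.scatter_correction == "TEW":
            low, up = _tew_neighbours(acq, peak)
            scatter = tew_estimate(projections, peak, low, up,
                                   smooth_px=rc.tew_smooth_px)
        elif rc.scatter_correction == "ideal":
            scatter = projections.components[peak.name]["scatter"]
        else:
            scatter = None
        mu = None if density is None else mu_map_from_density(density, energy)
        recons.append(
            osem_reconstruct(projections, mu, rc, window=peak,
                             scatter_term=scatter)
        )
    out = recons[0] if len(recons) == 1 else sum_photopeaks(recons)
    if rc.post_filter_fwhm_mm:
        out = gaussian_postfilter(out, rc.post_filter_fwhm_mm)
    return out


# ---------------------------------------------------------------------------
# calibration drivers
# ---------------------------------------------------------------------------
def _total_counts(cps: float, acq: AcquisitionConfig) -> float:
    """Counts attributed to a VOI for Poisson budgeting."""
    return max(cps * acq.time_per_projection_s * acq.n_projections, 1e-12)


def _spect_calibration_run(activity, density, protocol, seed, noise):
    projset = acquire(activity, density, protocol.acquisition,
                      seed=seed, noise=noise)
    return reconstruct_protocol(projset, density, protocol)


@dataclass
class CalibrationOutcome:
    result: cal.CalibrationResult
    recovery: cal.RecoveryCurve | None = None
    iso_thresholds: tuple[float, float] | None = None
    poisson_rel: float = 0.0  # mean Poisson relative error of the calibration


def _calibrate(protocol: SiteProtocol, bundle: PhantomBundle,
               seeds, noise: bool) -> CalibrationOutcome:
    grid = bundle.grid
    spacing = grid.spacing[0]
    n_xy, _, n_z = grid.shape
    p = protocol.calib_params
    method = protocol.calibration
    water = water_body(bundle.body, spacing, n_xy, n_z)
    acqc = protocol.acquisition

    if method == "oracle":
        factor = acqc.sensitivity_for(acqc.photopeaks()[-1])
        return CalibrationOutcome(cal.CalibrationResult(factor, 0.0, "oracle"))

    if method == "large_homogeneous":
        # homogeneous bottle: VOI (physical surface + margin) captures the
        # whole source, so the factor divides by its total activity
        volume, conc = p["volume_ml"], p["concentration"]
        margin = protocol.seg_params.get("margin_mm", 10.0)
        activity, mask = make_sphere_source(volume, conc, grid)
        true_act = float(activity.values.sum()) * activity.voxel_volume_ml
        recon = _spect_calibration_run(activity, water, protocol, seeds[0], noise)
        d_phys = 2.0 * (3.0 * volume * 1000.0 / (4 * np.pi)) ** (1 / 3)
        voi = seg.sphere_voi((0, 0, 0), d_phys, margin, grid)
        cps = counts_in_voi(recon, voi)
        counts = _total_counts(cps, acqc)
        poisson_rel = 1.0 / np.sqrt(counts)
        base = cal.calib_factor_from_voi(cps * acqc.time_per_projection_s,
                                         acqc.time_per_projection_s, true_act,
                                         method=method)
        if protocol.uncertainty == "none":
            sigma = 0.0
        else:
            sigma = base.factor_cps_per_mbq * float(
                np.sqrt(poisson_rel ** 2 + ACTIVITY_REL_SIGMA ** 2))
        return CalibrationOutcome(
            cal.CalibrationResult(base.factor_cps_per_mbq, sigma, method),
            poisson_rel=poisson_rel,
        )

    if method == "large_cylinder":
        # homogeneous cylinder much larger than the VOI: the factor divides
        # by the activity inside the central VOI, not the whole phantom
        volume = p["volume_ml"]
        x, y, z = grid.coords()
        height = min(bundle.body.height_mm,
                     (grid.shape[2] - 2) * grid.spacing[2])
        radius = np.sqrt(volume * 1000.0 / (np.pi * height))
        cyl = ((x[:, None] ** 2 + y[None, :] ** 2) <= radius ** 2)[:, :, None] \
            & (np.abs(z) <= height / 2.0)[None, None, :]
        conc = p["activity_mbq"] / (float(cyl.sum()) * grid.voxel_volume_ml)
        activity = grid.with_values(np.where(cyl, conc, 0.0), "activity")
        recon = _spect_calibration_run(activity, water, protocol, seeds[0], noise)
        voi = seg.fixed_sphere_voi((0, 0, 0), 150.0, grid)
        act_in_voi = float(
            activity.values[voi.values.astype(bool)].sum()
        ) * grid.voxel_volume_ml
        cps = counts_in_voi(recon, voi)
        factor = cps / act_in_voi
        return CalibrationOutcome(
            cal.CalibrationResult(factor, 0.0, method),
            poisson_rel=1.0 / np.sqrt(_total_counts(cps, acqc)),
        )

    if method in ("sphere16ml", "sphere16ml_two_vois"):
        act_mbq = p["activity_mbq"]
        conc = act_mbq / 16.0
        factors, poissons = [], []
        for k, (off, medium) in enumerate(zip(p["offsets_mm"], p["media"])):
            density = water if medium == "water" else water.with_values(
                np.zeros(grid.shape), "density")
            activity, mask = make_sphere_source(
                16.0, conc, grid, centre_mm=(off, 0.0, 0.0))
            true_act = float(activity.values.sum()) * activity.voxel_volume_ml
            recon = _spect_calibration_run(activity, density, protocol,
                                           seeds[k], noise)
            if method == "sphere16ml_two_vois":
                for perturb in (-1, 1):
                    voi = seg.manual_voi(mask, perturb)
                    cps = counts_in_voi(recon, voi)
                    factors.append(cps / true_act)
                    poissons.append(1.0 / np.sqrt(_total_counts(cps, acqc)))
            else:
                cps = counts_in_voi(recon, mask)
                factors.append(cps / true_act)
                poissons.append(1.0 / np.sqrt(_total_counts(cps, acqc)))
        multi = cal.calib_factor_multi(factors, method=method)
        poisson_rel = float(np.mean(poissons))
        if method == "sphere16ml" and len(factors) == 1:
            # single-position variant: Poisson + activity certificate
            sigma = multi.factor_cps_per_mbq * float(
                np.sqrt(poisson_rel ** 2 + ACTIVITY_REL_SIGMA ** 2))
            multi = cal.CalibrationResult(multi.factor_cps_per_mbq, sigma,
                                          method, 1, multi.per_measurement)
        return CalibrationOutcome(multi, poisson_rel=poisson_rel)

    if method == "shell_matched":
        conc = p["concentration"]
        factors, depths = [], []
        for k, off in enumerate(p["offsets_mm"]):
            src = replace(bundle.source, inner_concentration=conc,
                          outer_concentration=conc,
                          centre_mm=(float(off), 0.0, 0.0))
            activity = make_shell_source(src, spacing, grid=grid)
            true_act = float(activity.values.sum()) * activity.voxel_volume_ml
            recon = _spect_calibration_run(activity, water, protocol,
                                           seeds[k], noise)
            masks = shell_source_masks(src, grid)
            whole = shell_subtract_union(masks["inner"], masks["outer"])
            cps = counts_in_voi(recon, whole)
            factors.append(cps / true_act)
            depths.append(surface_depth(bundle.body, src.centre_mm))
        # pick the factor measured at the most similar depth to the source
        target = surface_depth(bundle.body, bundle.source.centre_mm)
        best = int(np.argmin([abs(d - target) for d in depths]))
        sd = float(np.std(factors, ddof=1)) if len(factors) > 1 else 0.0
        result = cal.CalibrationResult(float(factors[best]), sd,
                                       "shell_matched", len(factors),
                                       tuple(factors))
        iso = None
        if protocol.seg_params.get("calibrate_thresholds"):
            src = replace(bundle.source, inner_concentration=conc,
                          outer_concentration=conc)
            activity = make_shell_source(src, spacing, grid=grid)
            recon = _spect_calibration_run(activity, water, protocol,
                                           seeds[len(p["offsets_mm"])], noise)
            region = seg.source_search_region(src.centre_mm,
                                              src.outer_radius_mm, grid)
            inner_frac = seg.calibrate_iso_threshold(
                recon, region, src.inner_volume_ml)
            outer_frac = seg.calibrate_iso_threshold(
                recon, region, src.inner_volume_ml + src.outer_volume_ml)
            iso = (inner_frac, outer_frac)
        return CalibrationOutcome(result, iso_thresholds=iso)

    if method == "planar_petri":
        rng = np.random.default_rng(seeds[0])
        n_dishes = p["n_dishes"]
        nominal = p["dish_activity_mbq"]
        # dispensing spread around the nominal activity, known exactly
        activities = nominal * (1.0 + 0.01 * rng.standard_normal(n_dishes))
        n_planar = 48
        pgrid = empty_grid(n_planar, n_planar, spacing)
        images = []
        for k, a in enumerate(activities):
            disc = make_disc_source(float(a), 60.0, pgrid)
            images.append(planar_acquire(
                disc, protocol.acquisition, distance_mm=100.0,
                background_cps_per_pixel=0.05, seed=seeds[k + 1], noise=noise,
            ))
        result = cal.calib_factor_planar(
            images, roi_diameter_mm=100.0, activities_mbq=activities,
            time_s=protocol.acquisition.time_per_projection_s,
            pixel_mm=spacing,
            background_centre_px=(6.0, 6.0), background_diameter_mm=40.0,
        )
        curve = recovery_curve_for_protocol(
            protocol, bundle, result, seeds[n_dishes + 1:], noise)
        return CalibrationOutcome(result, recovery=curve)

    raise ValueError(f"unknown calibration method {method!r}")


def shell_subtract_union(inner: VoxelImage, outer: VoxelImage) -> VoxelImage:
    union = inner.values.astype(bool) | outer.values.astype(bool)
    return inner.with_values(union.astype(np.uint8), "mask")


def recovery_coefficients_for_spheres(
    protocol: SiteProtocol,
    bundle: PhantomBundle,
    factor: cal.CalibrationResult,
    volumes_ml,
    concentration: float,
    seeds,
    noise: bool,
    voi: str = "otsu",
):
    """Measured/true activity for uniform spheres of the given volumes."""
    grid = bundle.grid
    water = water_body(bundle.body, grid.spacing[0], grid.shape[0], grid.shape[2])
    rcs = []
    for k, v in enumerate(volumes_ml):
        activity, mask = make_sphere_source(float(v), concentration, grid)
        true_act = float(activity.values.sum()) * activity.voxel_volume_ml
        recon = _spect_calibration_run(activity, water, protocol,
                                       seeds[k], noise)
        if voi == "otsu":
            radius = (3.0 * v * 1000.0 / (4 * np.pi)) ** (1 / 3)
            region = seg.source_search_region((0, 0, 0), radius, grid)
            mask_used = seg.otsu_voi(recon, region)
        else:
            mask_used = mask
        cps = counts_in_voi(recon, mask_used)
        est = activity_estimate(cps, factor)
        rcs.append(est / true_act)
    return np.asarray(volumes_ml, float), np.asarray(rcs)


def recovery_curve_for_protocol(protocol, bundle, factor, seeds, noise):
    p = protocol.calib_params
    volumes, rcs = recovery_coefficients_for_spheres(
        protocol, bundle, factor, p["recovery_volumes_ml"],
        p["recovery_concentration"], seeds, noise,
    )
    rcs = np.clip(rcs, 1e-3, 1.2)
    return cal.fit_recovery_curve(volumes, rcs)


# ---------------------------------------------------------------------------
# segmentation driver
# ---------------------------------------------------------------------------
def _segment(protocol: SiteProtocol, bundle: PhantomBundle,
             recon: ReconVolume, outcome: CalibrationOutcome):
    """Returns (vois, reported_volumes) keyed by compartment."""
    src = bundle.source
    grid = bundle.grid
    centre = src.centre_mm
    method = protocol.segmentation
    sp = protocol.seg_params

    if method == "truth":
        vois = {"inner": bundle.masks["inner"], "outer": bundle.masks["outer"]}
    elif method == "ct_sphere_margin":
        margin = sp.get("margin_mm", 10.0)
        inner = seg.sphere_voi(centre, 2 * src.inner_radius_mm, margin, grid)
        outer_s = seg.sphere_voi(centre, 2 * src.outer_radius_mm, margin, grid)
        vois = {"inner": inner, "outer": seg.shell_subtract(outer_s, inner)}
    elif method == "ct_sphere":
        inner = seg.sphere_voi(centre, 2 * src.inner_radius_mm, 0.0, grid)
        outer_s = seg.sphere_voi(centre, 2 * src.outer_radius_mm, 0.0, grid)
        vois = {"inner": inner, "outer": seg.shell_subtract(outer_s, inner)}
    elif method == "manual":
        perturb = sp.get("perturb_voxels", 0)
        inner = seg.manual_voi(bundle.masks["inner"], perturb)
        whole = seg.manual_voi(
            shell_subtract_union(bundle.masks["inner"], bundle.masks["outer"]),
            perturb,
        )
        vois = {"inner": inner, "outer": seg.shell_subtract(whole, inner)}
    elif method == "iso_contour":
        region = seg.source_search_region(centre, src.outer_radius_mm, grid)
        if outcome.iso_thresholds is not None:
            f_in, f_out = outcome.iso_thresholds
        else:
            f_in, f_out = sp["inner_fraction"], sp["outer_fraction"]
        inner = seg.iso_contour_voi(recon, f_in, region)
        outer_s = seg.iso_contour_voi(recon, f_out, region)
        vois = {"inner": inner, "outer": seg.shell_subtract(outer_s, inner)}
    elif method == "fixed_sphere":
        inner = seg.fixed_sphere_voi(centre, sp["diameter_mm"], grid)
        vois = {"inner": inner}
    elif method == "otsu_plus_manual":
        region = seg.source_search_region(centre, src.outer_radius_mm, grid)
        inner = seg.otsu_voi(recon, region)
        whole = seg.manual_voi(
            shell_subtract_union(bundle.masks["inner"], bundle.masks["outer"]),
            sp.get("perturb_voxels", 0),
        )
        vois = {"inner": inner, "outer": seg.shell_subtract(whole, inner),
                "whole": whole}
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    volumes: dict[str, float | None] = {}
    if method in ("ct_sphere", "ct_sphere_margin"):
        # sites report the CT-measured physical volume, not the expanded VOI
        inner_ct = seg.sphere_voi(centre, 2 * src.inner_radius_mm, 0.0, grid)
        outer_ct = seg.sphere_voi(centre, 2 * src.outer_radius_mm, 0.0, grid)
        volumes["inner"] = mask_volume(inner_ct)
        volumes["outer"] = mask_volume(outer_ct) - mask_volume(inner_ct)
    elif method == "fixed_sphere":
        volumes["inner"] = None  # arbitrary sphere: no volume reported
    else:
        volumes["inner"] = mask_volume(vois["inner"])
        if "outer" in vois:
            if "whole" in vois:
                volumes["outer"] = mask_volume(vois["whole"]) - volumes["inner"]
            else:
                volumes["outer"] = mask_volume(vois["outer"])
    return vois, volumes


# ---------------------------------------------------------------------------
# full protocol run
# ---------------------------------------------------------------------------
@dataclass
class ProtocolResult:
    protocol: str
    calibration: cal.CalibrationResult
    quant: dict  # compartment -> QuantResult
    recovery: cal.RecoveryCurve | None = None
    iso_thresholds: tuple | None = None


def run_protocol(
    protocol: SiteProtocol,
    bundle: PhantomBundle,
    seed: int,
    noise: bool = True,
) -> ProtocolResult:
    """calibrate -> simulate -> reconstruct -> segment -> quantify.

    Deterministic under ``seed``; ``noise=False`` gives noise-free means
    everywhere (the best-case check).
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s) for s in ss.generate_state(24, dtype=np.uint32) >> 1]
    outcome = _calibrate(protocol, bundle, child[:20], noise)

    projset = acquire(bundle.activity, bundle.density, protocol.acquisition,
                      seed=child[20], noise=noise)
    recon = reconstruct_protocol(projset, bundle.density, protocol)
    vois, volumes = _segment(protocol, bundle, recon, outcome)

    acqc = protocol.acquisition
    calres = outcome.result
    quant: dict[str, QuantResult] = {}

    def _sigma(cps, activity_mbq, extra=()):
        if protocol.uncertainty == "none":
            return None
        if protocol.uncertainty == "calibration":
            rel = calres.relative_sigma
            rel = float(np.sqrt(rel ** 2 + sum(float(e) ** 2 for e in extra)))
        elif protocol.uncertainty == "calibration_plus_voi_poisson":
            voi_rel = 1.0 / np.sqrt(_total_counts(cps, acqc))
            rel = float(np.sqrt(outcome.poisson_rel ** 2 + voi_rel ** 2))
        elif protocol.uncertainty == "calibration_plus_activity":
            rel = float(np.sqrt(calres.relative_sigma ** 2
                                + ACTIVITY_REL_SIGMA ** 2))
        elif protocol.uncertainty == "calibration_plus_recovery":
            rc_rel = outcome.recovery.relative_sigma if outcome.recovery else 0.0
            rel = float(np.sqrt(calres.relative_sigma ** 2 + rc_rel ** 2))
        else:
            raise ValueError(f"unknown uncertainty recipe {protocol.uncertainty!r}")
        return rel * activity_mbq

    inner_cps = counts_in_voi(recon, vois["inner"])
    if protocol.segmentation == "otsu_plus_manual" and outcome.recovery is not None:
        v_inner = volumes["inner"]
        a_inner = activity_estimate(inner_cps, calres,
                                    recovery=(outcome.recovery, v_inner))
    else:
        a_inner = activity_estimate(inner_cps, calres)
    quant["inner"] = QuantResult(protocol.name, "inner", volumes.get("inner"),
                                 a_inner, _sigma(inner_cps, a_inner))

    if "outer" in vois:
        if protocol.segmentation == "otsu_plus_manual":
            whole_cps = counts_in_voi(recon, vois["whole"])
            a_whole = activity_estimate(whole_cps, calres)
            a_outer = max(a_whole - a_inner, 0.0)
            outer_cps = whole_cps
        else:
            outer_cps = counts_in_voi(recon, vois["outer"])
            a_outer = activity_estimate(outer_cps, calres)
        quant["outer"] = QuantResult(protocol.name, "outer",
                                     volumes.get("outer"), a_outer,
                                     _sigma(outer_cps, a_outer))
        v_in, v_out = volumes.get("inner"), volumes.get("outer")
        v_tot = None if (v_in is None or v_out is None) else v_in + v_out
        sig_in = quant["inner"].sigma_mbq
        sig_out = quant["outer"].sigma_mbq
        sig_tot = (None if (sig_in is None or sig_out is None)
                   else float(np.hypot(sig_in, sig_out)))
        quant["total"] = QuantResult(protocol.name, "total", v_tot,
                                     a_inner + a_outer, sig_tot)

    return ProtocolResult(protocol.name, calres, quant,
                          recovery=outcome.recovery,
                          iso_thresholds=outcome.iso_thresholds)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------
def percent_difference(measured: float, truth: float) -> float:
    """100 x (measured - truth) / truth."""
    if truth == 0:
        raise ZeroDivisionError("truth value must be nonzero")
    return 100.0 * (measured - truth) / truth


def within_threshold_table(diffs, thresholds=DEFAULT_THRESHOLDS_PCT) -> pd.DataFrame:
    """Proportion of |diff| within each threshold, as "k/n (p%)" rows."""
    diffs = np.asarray(list(diffs), dtype=float)
    if diffs.size == 0:
        raise ValueError("empty difference list")
    thresholds = [float(t) for t in thresholds]
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    n = diffs.size
    rows = []
    for t in thresholds:
        k = int(np.sum(np.abs(diffs) <= t))
        rows.append({
            "threshold_pct": t,
            "k": k,
            "n": n,
            "proportion": k / n,
            "label": f"{k}/{n} ({100.0 * k / n:.0f}%)",
        })
    return pd.DataFrame(rows)


def _spread(diffs: np.ndarray) -> dict:
    return {
        "min": float(diffs.min()),
        "max": float(diffs.max()),
        "range": float(diffs.max() - diffs.min()),
        "mean": float(diffs.mean()),
    }


@dataclass
class ComparisonReport:
    """Cross-protocol percent differences, spreads and agreement tables."""

    table: pd.DataFrame
    spreads: dict
    within: dict
    truth: dict

    def summary_text(self) -> str:
        lines = ["Inter-comparison summary", "=" * 24, ""]
        for (quantity, compartment), s in sorted(self.spreads.items()):
            lines.append(
                f"{compartment} {quantity}: spread {s['range']:.0f}% "
                f"(range {s['min']:+.0f} to {s['max']:+.0f}%), "
                f"mean {s['mean']:+.0f}%"
            )
        lines.append("")
        for compartment, tab in sorted(self.within.items()):
            lines.append(f"activity within thresholds, {compartment}: "
                         + "  ".join(
                             f"<= {int(r.threshold_pct)}%: {r.label}"
                             for r in tab.itertuples()))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compile_report(results, bundle: PhantomBundle,
                   thresholds=DEFAULT_THRESHOLDS_PCT) -> ComparisonReport:
    """Percent differences against the digital truth for every protocol."""
    if not results:
        raise ValueError("no protocol results to report")
    rows = []
    for res in sorted(results, key=lambda r: r.protocol):
        for compartment, q in res.quant.items():
            t_vol = bundle.truth_volume(compartment)
            t_act = bundle.truth_activity(compartment)
            vol_diff = (None if q.volume_ml is None
                        else percent_difference(q.volume_ml, t_vol))
            act_diff = percent_difference(q.activity_mbq, t_act)
            covers = (None if q.sigma_mbq is None else
                      bool(abs(q.activity_mbq - t_act) <= q.sigma_mbq))
            rows.append({
                "protocol": res.protocol,
                "compartment": compartment,
                "volume_ml": q.volume_ml,
                "activity_mbq": q.activity_mbq,
                "sigma_mbq": q.sigma_mbq,
                "truth_volume_ml": t_vol,
                "truth_activity_mbq": t_act,
                "volume_pct_diff": vol_diff,
                "activity_pct_diff": act_diff,
                "uncertainty_covers_truth": covers,
            })
    table = pd.DataFrame(rows)
    spreads = {}
    within = {}
    truth = {}
    for compartment in table["compartment"].unique():
        sub = table[table["compartment"] == compartment]
        truth[compartment] = {
            "volume_ml": float(sub["truth_volume_ml"].iloc[0]),
            "activity_mbq": float(sub["truth_activity_mbq"].iloc[0]),
        }
        act = sub["activity_pct_diff"].to_numpy(dtype=float)
        spreads[("activity", compartment)] = _spread(act)
        within[compartment] = within_threshold_table(act, thresholds)
        vol = sub["volume_pct_diff"].dropna().to_numpy(dtype=float)
        if vol.size:
            spreads[("volume", compartment)] = _spread(vol)
    return ComparisonReport(table, spreads, within, truth)
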