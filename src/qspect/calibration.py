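"""Camera calibration (cps/MBq) and recovery-coefficient curves.

The system sensitivity factor converts reconstructed count rate in a VOI to
absolute activity.  The sites derived it from very different geometries —
a large homogeneous volume, a 16-ml sphere imaged at several positions, a
shell source of the same design as the comparison source, or planar images
of petri dishes — and those choices fold different amounts of partial-volume
loss into the factor.

The recovery coefficient RC(V) is the measured-to-true activity ratio for a
uniform sphere of volume V; estimates are corrected by dividing by RC.  The
fitted form RC(V) = 1 - exp(-(V/v0)^p) is monotone increasing with
RC(0) = 0 and RC(inf) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationResult",
    "RecoveryCurve",
    "calib_factor_from_voi",
    "calib_factor_multi",
    "calib_factor_planar",
    "circular_roi_counts",
    "fit_recovery_curve",
    "apply_recovery",
    "partial_volume_threshold",
]


@dataclass(frozen=True)
class CalibrationResult:
    """A cps/MBq factor with its uncertainty and provenance."""

    factor_cps_per_mbq: float
    sigma_cps_per_mbq: float = 0.0
    method: str = "large_homogeneous"
    n_measurements: int = 1
    per_measurement: tuple = ()

    def __post_init__(self):
        if self.factor_cps_per_mbq <= 0:
            raise ValueError("calibration factor must be positive")
        if self.sigma_cps_per_mbq < 0:
            raise ValueError("calibration sigma must be nonnegative")

    @property
    def relative_sigma(self) -> float:
        return self.sigma_cps_per_mbq / self.factor_cps_per_mbq


def calib_factor_from_voi(
    counts: float,
    acquisition_time_s: float,
    true_activity_mbq: float,
    method: str = "large_homogeneous",
    sigma_cps_per_mbq: float = 0.0,
) -> CalibrationResult:
    """factor = (counts / time) / activity for a single calibration VOI."""
    if counts <= 0 or acquisition_time_s <= 0 or true_activity_mbq <= 0:
        raise ValueError("counts, time and activity must all be positive")
    factor = (counts / acquisition_time_s) / true_activity_mbq
    return CalibrationResult(factor, sigma_cps_per_mbq, method, 1, (factor,))


def calib_factor_multi(factors, method: str = "sphere16ml_multi_position") -> CalibrationResult:
    """Mean +/- sd of per-measurement factors (multi-position calibrations)."""
    factors = tuple(float(f) for f in factors)
    if not factors:
        raise ValueError("no calibration factors given")
    if any(f <= 0 for f in factors):
        raise ValueError("calibration factors must be positive")
    mean = float(np.mean(factors))
    sd = float(np.std(factors, ddof=1)) if len(factors) > 1 else 0.0
    return CalibrationResult(mean, sd, method, len(factors), factors)


def circular_roi_counts(image: np.ndarray, centre_px, diameter_px: float) -> tuple[float, int]:
    """Counts and pixel count inside a circular ROI of a planar image."""
    n0, n1 = image.shape
    i, j = np.ogrid[:n0, :n1]
    r2 = (i - centre_px[0]) ** 2 + (j - centre_px[1]) ** 2
    mask = r2 <= (diameter_px / 2.0) ** 2
    if not mask.any():
        raise ValueError("ROI does not cover any pixel")
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("ROI exceeds the image bounds")
    return float(image[mask].sum()), int(mask.sum())


def calib_factor_planar(
    planar_images,
    roi_diameter_mm: float,
    activities_mbq,
    time_s: float,
    pixel_mm: float,
    centre_px=None,
    background_centre_px=None,
    background_diameter_mm: float | None = None,
) -> CalibrationResult:
    """Planar petri-dish calibration: mean +/- sd over the sources.

    Counts in a circular ROI around each dish are corrected for the mean
    background per pixel measured in an off-source ROI, then converted to a
    cps/MBq factor per dish.
    """
    activities = np.atleast_1d(np.asarray(activities_mbq, dtype=float))
    if len(planar_images) == 0:
        raise ValueError("no planar images given")
    if np.any(activities <= 0):
        raise ValueError("dish activities must be positive")
    if len(planar_images) != len(activities):
        raise ValueError("one activity per image required")
    if background_diameter_mm is None:
        background_diameter_mm = roi_diameter_mm

    factors = []
    for img, act in zip(planar_images, activities):
        img = np.asarray(img, dtype=float)
        c = centre_px or ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
        total, n_pix = circular_roi_counts(img, c, roi_diameter_mm / pixel_mm)
        if background_centre_px is not None:
            bg_total, bg_n = circular_roi_counts(
                img, background_centre_px, background_diameter_mm / pixel_mm
            )
            total -= n_pix * (bg_total / bg_n)
        factors.append((max(total, 0.0) / time_s) / act)
    if any(f <= 0 for f in factors):
        raise ValueError("background-corrected counts must remain positive")
    return calib_factor_multi(factors, method="planar_petri")


@dataclass(frozen=True)
class RecoveryCurve:
    """RC(V) = 1 - exp(-(V / v0)^p): monotone, RC(0)=0, RC(inf)=1."""

    v0_ml: float
    p: float
    residuals: tuple = ()

    def __post_init__(self):
        if self.v0_ml <= 0 or self.p <= 0:
            raise ValueError("v0 and p must be positive")

    def __call__(self, volume_ml):
        v = np.asarray(volume_ml, dtype=float)
        rc = 1.0 - np.exp(-((v / self.v0_ml) ** self.p))
        return float(rc) if np.isscalar(volume_ml) else rc

    @property
    def relative_sigma(self) -> float:
        """Relative scatter of the fit residuals (0 for a perfect fit)."""
        if len(self.residuals) < 2:
            return 0.0
        return float(np.std(self.residuals, ddof=1))


def fit_recovery_curve(volumes_ml, measured_over_true) -> RecoveryCurve:
    """Least-squares fit of the recovery model to (volume, RC) data."""
    v = np.asarray(volumes_ml, dtype=float)
    rc = np.asarray(measured_over_true, dtype=float)
    if v.size < 3 or np.unique(v).size < 3:
        raise ValueError("at least three distinct volumes required")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if np.any(rc <= 0) or np.any(rc > 1.2):
        raise ValueError("recovery coefficients must lie in (0, 1.2]")

    def resid(theta):
        v0, p = np.exp(theta)
        return 1.0 - np.exp(-((v / v0) ** p)) - rc

    # start near the half-recovery volume with a gentle slope
    v0_guess = float(np.interp(0.5, np.sort(rc), np.sort(v))) or float(v.min())
    sol = least_squares(resid, x0=[np.log(max(v0_guess, 1e-3)), 0.0])
    v0, p = np.exp(sol.x)
    curve = RecoveryCurve(float(v0), float(p))
    res = curve(v) - rc
    return RecoveryCurve(float(v0), float(p), tuple(float(r) for r in res))


def apply_recovery(
    activity_estimate_mbq: float,
    volume_ml: float,
    curve: RecoveryCurve,
    rc_floor: float = 0.05,
) -> float:
    """Partial-volume-corrected activity: estimate / RC(volume).

    Refuses to extrapolate below ``rc_floor`` (a tiny RC would blow the
    correction up arbitrarily).
    """
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    rc = curve(volume_ml)
    if rc < rc_floor:
        raise ValueError(
            f"recovery coefficient {rc:.3f} below the extrapolation floor"
        )
    return activity_estimate_mbq / rc


def partial_volume_threshold(volumes_ml, recovery_coeffs, rc_min: float = 0.95) -> float:
    """Smallest calibrated sphere volume whose RC reaches ``rc_min``.

    The volume below which partial-volume corrections should be applied;
    returns ``inf`` if no measured sphere reaches the target recovery.
    """
    v = np.asarray(volumes_ml, dtype=float)
    rc = np.asarray(recovery_coeffs, dtype=float)
    ok = rc >= rc_min
    return float(v[ok].min()) if ok.any() else float("inf")
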