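"""VOI counts to absolute activity, with per-site uncertainty propagation.

Activity is (VOI count rate) / (calibration factor), optionally divided by
a recovery coefficient for partial-volume correction.  Uncertainties are
relative sigmas combined in quadrature, exactly as the sites' budgets were
built: a Poisson term on counts, the calibration factor's relative sigma
and any extra terms (source-activity certificate, recovery-curve scatter).
Segmentation uncertainty is deliberately absent from every preset — none of
the sites included one — but can be passed as an extra term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationResult, RecoveryCurve, apply_recovery
from .phantom import VoxelImage
from .recon import ReconVolume

__all__ = [
    "QuantResult",
    "counts_in_voi",
    "activity_estimate",
    "uncertainty_estimate",
]


@dataclass
class QuantResult:
    """Reported volume, activity and uncertainty for one compartment."""

    protocol: str
    compartment: str  # inner | outer | total
    volume_ml: float | None
    activity_mbq: float
    sigma_mbq: float | None = None

    def __post_init__(self):
        if self.activity_mbq < 0:
            raise ValueError("activity must be nonnegative")
        if self.sigma_mbq is not None and self.sigma_mbq < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def relative_sigma(self) -> float | None:
        if self.sigma_mbq is None or self.activity_mbq == 0:
            return None
        return self.sigma_mbq / self.activity_mbq


def counts_in_voi(recon, voi: VoxelImage) -> float:
    """Sum of the reconstructed count rate (cps) over the VOI voxels."""
    image = recon.image if isinstance(recon, ReconVolume) else recon
    if not image.same_grid(voi):
        raise ValueError("VOI is not on the reconstruction grid")
    if voi.role != "mask":
        raise ValueError("VOI must be a mask-role image")
    return float(image.values[voi.values.astype(bool)].sum())


def activity_estimate(
    cps: float,
    calibration: CalibrationResult,
    recovery: tuple[RecoveryCurve, float] | None = None,
) -> float:
    """A = cps / factor, optionally recovery-corrected by (curve, volume_ml)."""
    if calibration.factor_cps_per_mbq <= 0:
        raise ValueError("calibration factor must be positive")
    a = cps / calibration.factor_cps_per_mbq
    if recovery is not None:
        curve, volume_ml = recovery
        a = apply_recovery(a, volume_ml, curve)
    return a


def uncertainty_estimate(
    counts: float,
    calibration: CalibrationResult,
    extra_relative_sigmas=(),
) -> float:
    """Relative sigma: sqrt(1/counts + (sigma_f/f)^2 + sum(extra^2)).

    ``counts`` is the total detected counts attributed to the measurement
    (its Poisson relative error is 1/sqrt(counts)); zero counts leave the
    relative error undefined and raise.
    """
    if counts < 0:
        raise ValueError("counts must be nonnegative")
    if counts == 0:
        raise ValueError("relative uncertainty undefined for zero counts")
    terms = [1.0 / counts, calibration.relative_sigma ** 2]
    terms.extend(float(e) ** 2 for e in extra_relative_sigmas)
    return float(np.sqrt(sum(terms)))
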