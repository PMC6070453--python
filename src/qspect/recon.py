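"""OSEM/MLEM reconstruction with attenuation and selectable scatter handling.

The reconstruction shares the simulator's projection engine, so a "matched"
system model (the default) commits the inverse crime deliberately: it is the
idealised best case against which model mismatch (e.g. reconstructing
without the collimator PSF) can be measured.  Scatter can be ignored
(``none``), estimated from adjacent energy windows (``TEW``) or taken as
the simulator's true pre-noise scatter term (``ideal`` — the desk-scale
surrogate for the sites' Monte Carlo and ESSE corrections).  Scatter enters
the forward model as an additive term; one site's protocol instead
subtracts it from the projections before reconstruction (``presubtract``).

The reconstructed voxel values are count rates (cps per voxel): the model
maps them to detector counts through geometry, attenuation, optional PSF
and the time per projection, but not through the (unknown to the site)
system sensitivity — converting to activity is the calibration's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import VoxelImage
from .projector import SystemModel, fwhm_to_sigma
from .simulator import EnergyWindow, ProjectionSet

__all__ = [
    "ReconConfig",
    "ReconVolume",
    "tew_estimate",
    "osem_reconstruct",
    "sum_photopeaks",
    "gaussian_postfilter",
    "poisson_loglik",
]

_FLOOR = 1e-12


@dataclass(frozen=True)
class ReconConfig:
    """OSEM settings for one protocol.

    ``iterations`` full passes over ``subsets`` angular subsets
    (``subsets=1`` is exact MLEM).  ``scatter_correction`` is one of
    ``none``, ``TEW``, ``ideal``; ``presubtract_scatter`` applies the
    estimate to the projections before reconstruction instead of adding it
    to the forward model.  ``photopeaks`` lists the emission energies
    reconstructed (each with its own attenuation map, summed afterwards).
    """

    iterations: int = 8
    subsets: int = 6
    scatter_correction: str = "none"
    resolution_recovery: bool = True
    post_filter_fwhm_mm: float | None = None
    photopeaks: tuple[int, ...] = (208,)
    presubtract_scatter: bool = False
    tew_smooth_px: float = 2.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if self.scatter_correction not in ("none", "TEW", "ideal"):
            raise ValueError("scatter_correction must be none, TEW or ideal")


@dataclass
class ReconVolume:
    """Reconstructed count-rate volume with provenance."""

    image: VoxelImage
    config: ReconConfig | None = None
    window: str | None = None
    info: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.image.values


def tew_estimate(
    projections: ProjectionSet,
    photopeak: EnergyWindow,
    lower: EnergyWindow,
    upper: EnergyWindow,
    smooth_px: float = 0.0,
) -> np.ndarray:
    """Triple-energy-window scatter estimate for every view.

    Trapezoidal rule: S = (C_low/w_low + C_up/w_up) / 2 * w_peak with the
    widths in keV, clipped at zero; optionally smoothed in-plane to temper
    the noise of the narrow windows before subtraction.
    """
    for w in (photopeak, lower, upper):
        if w.name not in projections.counts:
            raise KeyError(f"window {w.name!r} not present in the projection set")
    c_low = projections.counts[lower.name]
    c_up = projections.counts[upper.name]
    s = 0.5 * (c_low / lower.width_kev + c_up / upper.width_kev) * photopeak.width_kev
    s = np.clip(s, 0.0, None)
    if smooth_px > 0:
        s = np.stack([gaussian_filter(si, smooth_px, mode="nearest") for si in s])
    return s


def _subset_indices(n_angles: int, subsets: int) -> list[np.ndarray]:
    if n_angles % subsets != 0:
        raise ValueError(
            f"subset count {subsets} does not divide {n_angles} projections"
        )
    return [np.arange(s, n_angles, subsets) for s in range(subsets)]


def poisson_loglik(y: np.ndarray, mean: np.ndarray) -> float:
    """Poisson log likelihood sum(y log m - m), constants dropped."""
    m = np.clip(mean, _FLOOR, None)
    return float(np.sum(np.where(y > 0, y * np.log(m), 0.0) - m))


def osem_reconstruct(
    projections: ProjectionSet,
    mu: VoxelImage | None,
    config: ReconConfig,
    window: EnergyWindow | None = None,
    scatter_term: np.ndarray | None = None,
    track_loglik: bool = False,
    initial: np.ndarray | None = None,
) -> ReconVolume:
    """OSEM reconstruction of one photopeak window.

    Standard multiplicative updates from a uniform positive start; the
    scatter term (counts, same shape as the data) is added in the forward
    model denominator, or subtracted from the data first when
    ``config.presubtract_scatter`` is set.  With ``subsets=1`` the update
    is exact MLEM and the Poisson likelihood is non-decreasing.
    """
    acq = projections.config
    window = window or acq.photopeaks()[0]
    y = np.asarray(projections.counts[window.name], dtype=float)

    if scatter_term is not None:
        scatter_term = np.asarray(scatter_term, dtype=float)
        if scatter_term.shape != y.shape:
            raise ValueError("scatter term shape does not match the data")
        if np.any(scatter_term < 0):
            raise ValueError("scatter term must be nonnegative")
        if config.presubtract_scatter:
            y = np.clip(y - scatter_term, 0.0, None)
            scatter_term = None

    spacing = projections.pixel_mm
    shape = (y.shape[1], y.shape[1], y.shape[2])
    model = SystemModel(
        shape,
        spacing,
        projections.angles_deg,
        projections.orbit_radii_mm,
        mu=None if mu is None else mu.values,
        psf=acq.psf_for(window) if config.resolution_recovery else None,
    )
    t = acq.time_per_projection_s
    n_angles = len(projections.angles_deg)
    subsets = _subset_indices(n_angles, config.subsets)

    # per-subset sensitivity images: A^T 1 over the subset's angles
    ones = np.ones(y.shape[1:])
    sens = [
        t * model.backproject(np.broadcast_to(ones, y.shape), idx)
        for idx in subsets
    ]

    if initial is not None:
        x = np.asarray(initial, dtype=float).copy()
        if x.shape != shape or np.any(x < 0):
            raise ValueError("initial image must be nonnegative on the recon grid")
    else:
        # uniform positive start scaled so the forward total matches the data
        total_model = float(sum(s.sum() for s in sens))
        x = np.full(shape, max(y.sum(), _FLOOR) / max(total_model, _FLOOR))

    # Single-precision projection leaves ~1e-6-relative noise on pixels
    # whose true mean is zero; pixels below the data-scaled floor carry no
    # information and are excluded, and the same floor regularises the
    # forward-model denominator.
    data_floor = max(_FLOOR, 1e-6 * float(y.max()))
    loglik: list[float] = []
    for _ in range(config.iterations):
        for idx, s_img in zip(subsets, sens):
            ratio = np.zeros_like(y)
            for i in idx:
                fp = t * model.forward(x, i)
                if scatter_term is not None:
                    fp = fp + scatter_term[i]
                ratio[i] = np.where(
                    y[i] > data_floor,
                    y[i] / (np.clip(fp, 0.0, None) + data_floor),
                    0.0,
                )
            back = t * model.backproject(ratio, idx)
            # clamp the multiplicative factor: subsets with few angles can
            # otherwise run away in low-count regions (limit-cycle blow-up)
            factor = np.clip(back / np.clip(s_img, _FLOOR, None), 1e-2, 1e2)
            x = x * factor
        if track_loglik:
            fp_all = t * np.stack(
                [model.forward(x, i) for i in range(n_angles)]
            )
            if scatter_term is not None:
                fp_all = fp_all + scatter_term
            loglik.append(poisson_loglik(y, fp_all))

    # reconstructed grid is aligned with the phantom grid by construction
    origin = mu.origin if mu is not None else (
        -spacing * (shape[0] - 1) / 2.0,
        -spacing * (shape[0] - 1) / 2.0,
        -spacing * (shape[2] - 1) / 2.0,
    )
    image = VoxelImage(np.clip(x, 0.0, None), (spacing,) * 3, origin, "counts")
    info = {"loglik": loglik} if track_loglik else {}
    return ReconVolume(image, config=config, window=window.name, info=info)


def sum_photopeaks(recons: list[ReconVolume]) -> ReconVolume:
    """Voxelwise sum of individually reconstructed photopeak volumes."""
    if not recons:
        raise ValueError("nothing to sum")
    first = recons[0]
    total = np.array(first.values, dtype=float)
    for r in recons[1:]:
        if not r.image.same_grid(first.image):
            raise ValueError("reconstructions are not on the same grid")
        total = total + r.values
    names = "+".join(str(r.window) for r in recons)
    return ReconVolume(first.image.with_values(total), config=first.config,
                       window=names)


def gaussian_postfilter(recon: ReconVolume, fwhm_mm: float) -> ReconVolume:
    """3-D Gaussian post-filter; a normalised kernel preserves total counts."""
    if fwhm_mm < 0:
        raise ValueError("filter FWHM must be nonnegative")
    if fwhm_mm == 0:
        return recon
    sigma = [fwhm_to_sigma(fwhm_mm) / s for s in recon.image.spacing]
    smoothed = gaussian_filter(np.asarray(recon.values, float), sigma,
                               mode="constant")
    return ReconVolume(recon.image.with_values(smoothed), config=recon.config,
                       window=recon.window, info=dict(recon.info))
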