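"""VOI definition: the four segmentation families used by the sites.

* CT-geometry spheres: a spherical VOI of the physical diameter plus an
  optional radial margin (one site's "+10 mm in each spatial direction"
  rule), or a fixed arbitrary diameter (the 8-cm sphere).
* Relative iso-contours on the reconstructed image (35% / 10% of the
  in-region maximum), with calibration-time threshold tuning against known
  volumes.
* Otsu auto-contouring on the in-region intensity histogram.
* "Manual" freehand outlining, emulated by the truth mask optionally
  perturbed by one voxel of dilation or erosion (operator variability is
  bracketed, not replicated).

Shell compartments are obtained by subtracting the inner VOI from the VOI
of the outer surface.  All intensity-based masks keep only the largest
6-connected component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantom import VoxelImage
from .recon import ReconVolume

__all__ = [
    "SegmentationError",
    "sphere_voi",
    "fixed_sphere_voi",
    "iso_contour_voi",
    "otsu_voi",
    "otsu_threshold",
    "shell_subtract",
    "manual_voi",
    "calibrate_iso_threshold",
    "source_search_region",
]

# 6-connectivity in 3-D
_STRUCT = ndimage.generate_binary_structure(3, 1)


class SegmentationError(ValueError):
    """Degenerate input to a segmentation rule (empty or constant region)."""


def _as_image(recon) -> VoxelImage:
    return recon.image if isinstance(recon, ReconVolume) else recon


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def sphere_voi(
    centre_mm,
    physical_diameter_mm: float,
    margin_mm: float,
    grid: VoxelImage,
) -> VoxelImage:
    """Spherical VOI of radius ``physical_diameter/2 + margin`` (radial margin).

    A "+10 mm in each spatial direction" expansion adds 10 mm to the
    radius, i.e. 20 mm to the diameter: on the nominal 36-mm inner sphere
    this gives a 28-mm VOI radius, leaving exactly the outermost 1 mm of
    the 29-mm-radius physical shell outside the inner VOI.
    """
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    radius = physical_diameter_mm / 2.0 + margin_mm
    x, y, z = grid.coords()
    lo = [c[0] - s / 2 for c, s in zip((x, y, z), grid.spacing)]
    hi = [c[-1] + s / 2 for c, s in zip((x, y, z), grid.spacing)]
    if any(cc - radius < l or cc + radius > h
           for cc, l, h in zip(centre_mm, lo, hi)):
        raise SegmentationError("sphere VOI exceeds the grid bounds")
    r2 = (
        (x - centre_mm[0])[:, None, None] ** 2
        + (y - centre_mm[1])[None, :, None] ** 2
        + (z - centre_mm[2])[None, None, :] ** 2
    )
    return grid.with_values((r2 <= radius ** 2).astype(np.uint8), "mask")


def fixed_sphere_voi(centre_mm, diameter_mm: float, grid: VoxelImage) -> VoxelImage:
    """Spherical VOI of a fixed diameter (e.g. the arbitrary 8-cm sphere)."""
    return sphere_voi(centre_mm, diameter_mm, 0.0, grid)


def iso_contour_voi(
    recon,
    threshold_fraction: float,
    search_region: VoxelImage,
) -> VoxelImage:
    """Voxels >= ``threshold_fraction`` of the in-region maximum.

    Keeps the largest 6-connected component.  The fraction must lie in
    (0, 1]; the region must contain a positive maximum.
    """
    image = _as_image(recon)
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold fraction must be in (0, 1]")
    if not image.same_grid(search_region):
        raise ValueError("search region is not on the reconstruction grid")
    region = search_region.values.astype(bool)
    if not region.any():
        raise SegmentationError("empty search region")
    vmax = float(image.values[region].max())
    if vmax <= 0:
        raise SegmentationError("no positive values in the search region")
    mask = region & (image.values >= threshold_fraction * vmax)
    mask = _largest_component(mask)
    return image.with_values(mask.astype(np.uint8), "mask")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance of the histogram.

    The histogram has ``nbins`` equal-width bins over the data range; for a
    split after bin k the between-class variance is
    w0 * w1 * (m0 - m1)^2 with class weights w and means m, and the
    returned threshold is the centre of the last bin of the lower class at
    the maximising split.
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(float) / hist.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    cm = np.cumsum(p * centers)
    total_mean = cm[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cm / w0
        m1 = (total_mean - cm) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-1.0)
    return float(centers[int(np.argmax(var_between))])


def otsu_voi(recon, search_region: VoxelImage, nbins: int = 256) -> VoxelImage:
    """Auto-contour by Otsu's method on the in-region histogram.

    The threshold maximises the between-class variance of the 256-bin
    histogram of in-region values; the mask is the above-threshold voxels'
    largest 6-connected component.
    """
    image = _as_image(recon)
    if not image.same_grid(search_region):
        raise ValueError("search region is not on the reconstruction grid")
    region = search_region.values.astype(bool)
    if not region.any():
        raise SegmentationError("empty search region")
    values = np.asarray(image.values[region], dtype=float)
    if np.unique(values).size < 2:
        raise SegmentationError("constant region: Otsu histogram degenerate")
    thr = otsu_threshold(values, nbins=nbins)
    mask = region & (image.values > thr)
    mask = _largest_component(mask)
    out = image.with_values(mask.astype(np.uint8), "mask")
    out_info = out  # threshold retrievable for diagnostics
    out_info.threshold = thr  # type: ignore[attr-defined]
    return out_info


def shell_subtract(outer_voi: VoxelImage, inner_voi: VoxelImage) -> VoxelImage:
    """Set difference ``outer \\ inner`` — the shell compartment VOI."""
    if not outer_voi.same_grid(inner_voi):
        raise ValueError("VOIs are not on the same grid")
    diff = outer_voi.values.astype(bool) & ~inner_voi.values.astype(bool)
    return outer_voi.with_values(diff.astype(np.uint8), "mask")


def manual_voi(truth_mask: VoxelImage, perturb_voxels: int = 0) -> VoxelImage:
    """Emulated freehand outline: the truth mask dilated (+n) or eroded (-n).

    Operator variability cannot be replicated at desk scale; a +/- 1 voxel
    perturbation of the exact outline brackets it.
    """
    m = truth_mask.values.astype(bool)
    if perturb_voxels > 0:
        m = ndimage.binary_dilation(m, _STRUCT, iterations=perturb_voxels)
    elif perturb_voxels < 0:
        m = ndimage.binary_erosion(m, _STRUCT, iterations=-perturb_voxels)
    return truth_mask.with_values(m.astype(np.uint8), "mask")


def source_search_region(centre_mm, outer_radius_mm: float,
                         grid: VoxelImage, scale: float = 2.0) -> VoxelImage:
    """Bounding box of ``scale`` times the source extent around its centre."""
    half = scale * outer_radius_mm
    x, y, z = grid.coords()
    box = (
        (np.abs(x - centre_mm[0]) <= half)[:, None, None]
        & (np.abs(y - centre_mm[1]) <= half)[None, :, None]
        & (np.abs(z - centre_mm[2]) <= half)[None, None, :]
    )
    return grid.with_values(box.astype(np.uint8), "mask")


def calibrate_iso_threshold(
    recon,
    search_region: VoxelImage,
    true_volume_ml: float,
    candidates=None,
) -> float:
    """Threshold fraction whose iso-contour volume best matches a known volume.

    Mirrors the calibration-time threshold tuning of the iso-contour site:
    the fraction is swept and the one minimising |V(threshold) - V_true|
    is frozen for the comparison run.
    """
    from .phantom import mask_volume

    if candidates is None:
        candidates = np.round(np.arange(0.02, 0.96, 0.01), 2)
    best, best_err = None, np.inf
    for frac in candidates:
        try:
            voi = iso_contour_voi(recon, float(frac), search_region)
        except SegmentationError:
            continue
        err = abs(mask_volume(voi) - true_volume_ml)
        if err < best_err:
            best, best_err = float(frac), err
    if best is None:
        raise SegmentationError("no candidate threshold produced a mask")
    return best
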