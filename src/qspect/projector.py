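"""Matched parallel-beam projector with attenuation and depth-dependent blur.

The forward operator for one view is

    A_theta x = sum_j  B_j  D_theta  R_theta x

where R_theta is an in-plane rotation into the detector frame, D_theta the
diagonal of per-voxel attenuation survival factors exp(-integral mu dl) from
the voxel to the detector, and B_j a 2-D Gaussian blur of the depth slab j
whose FWHM grows with distance from the collimator,
FWHM(d) = sqrt(fwhm_intrinsic^2 + (slope * d)^2).

R_theta is realised as an explicit sparse bilinear-interpolation matrix so
that the back projector is its exact transpose; the blur kernels are
symmetric with zero padding, hence self-adjoint.  Forward and back
projection are therefore an exact adjoint pair, which makes the MLEM/OSEM
updates well behaved (monotone likelihood for MLEM).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.fft import irfft2, next_fast_len, rfft2, rfftfreq

__all__ = ["SystemModel", "rotation_operator", "fwhm_to_sigma"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm * FWHM_TO_SIGMA


@lru_cache(maxsize=256)
def rotation_operator(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse mass-preserving rotation of an n x n slice about its centre.

    Each input pixel is splatted onto the rotated raster with bilinear
    weights that sum to one, so the operator conserves the slice total
    exactly for pixels whose rotated position stays inside the grid (counts
    are lost only past the edge).  Rows index the rotated (detector-frame)
    raster, columns the input raster; the transpose is the exact adjoint
    used for back projection.
    """
    c = (n - 1) / 2.0
    th = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = ii - c
    y = jj - c
    # forward-rotate each input pixel and distribute to its 4 neighbours
    xs = cos_t * x - sin_t * y + c
    ys = sin_t * x + cos_t * y + c
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    cols_base = (ii * n + jj).ravel()
    rows, cols, vals = [], [], []
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            w = (wx * wy).ravel()
            inside = (
                (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)
            ).ravel() & (w > 0)
            rows.append((xi.ravel() * n + yi.ravel())[inside])
            cols.append(cols_base[inside])
            vals.append(w[inside])
    M = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    M.sum_duplicates()
    return M


class SystemModel:
    """Forward/adjoint projection operator for a fixed set of view angles.

    Parameters
    ----------
    shape : (nx, ny, nz) with nx == ny (square in-plane grid).
    spacing_mm : isotropic voxel size.
    angles_deg : view angles (detector normal direction in the x-y plane).
    orbit_radii_mm : per-angle collimator-face distance from the rotation
        centre; sets the depth entering the PSF model.
    mu : optional attenuation map (cm^-1) on the same grid.
    psf : ``None`` for a blur-free (geometric) model, else
        ``(fwhm_intrinsic_mm, fwhm_slope_per_mm)``.

    ``forward`` maps per-voxel emission (any linear unit) to detector-plane
    means in the same unit; the operator conserves counts up to attenuation
    and kernel truncation at the grid edge.
    """

    def __init__(self, shape, spacing_mm, angles_deg, orbit_radii_mm,
                 mu=None, psf=None):
        nx, ny, nz = shape
        if nx != ny:
            raise ValueError("SystemModel requires a square in-plane grid")
        self.shape = tuple(shape)
        self.n = nx
        self.nz = nz
        self.spacing = float(spacing_mm)
        self.angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        self.orbit_radii = np.broadcast_to(
            np.asarray(orbit_radii_mm, dtype=float), self.angles.shape
        ).copy()
        self.psf = psf
        self._rot = [
            rotation_operator(self.n, float(a)).astype(np.float32)
            for a in self.angles
        ]
        self._att = self._attenuation_factors(mu)
        self._sigma_px = self._depth_sigmas()

    # -- precomputation ----------------------------------------------------
    def _attenuation_factors(self, mu):
        """Per-angle survival factors in the detector frame (float32).

        Rays travel toward +y (detector beyond the last y index).  The path
        integral uses the half-voxel convention at the emission voxel.
        """
        if mu is None:
            return [None] * len(self.angles)
        mu = np.asarray(mu, dtype=float)
        if mu.shape != self.shape:
            raise ValueError("mu grid does not match the model grid")
        dl_cm = self.spacing / 10.0
        att = []
        flat = mu.reshape(self.n * self.n, self.nz)
        for M in self._rot:
            mur = (M @ flat).reshape(self.shape)
            beyond = np.cumsum(mur[:, ::-1, :], axis=1)[:, ::-1, :]
            tau = dl_cm * (beyond - 0.5 * mur)
            att.append(np.exp(-tau).astype(np.float32))
        return att

    def _depth_sigmas(self):
        """Per-angle spectral Gaussian transfer functions per depth slab.

        The depth-dependent blur is applied in Fourier space on a padded
        (x, z) raster: for slab j the separable transfer function is
        exp(-2 pi^2 sigma_j^2 f^2) along each detector axis (DC gain 1, so
        counts are conserved exactly; the kernel is symmetric, so the blur
        is exactly self-adjoint).  Returns None when the model is blur-free,
        else a list per angle of (Gx, Gz) arrays of shape (n_slabs, n_freq).
        """
        if self.psf is None:
            return None
        fwhm0, slope = self.psf
        c = (self.n - 1) / 2.0
        y_mm = (np.arange(self.n) - c) * self.spacing
        sig_max = fwhm_to_sigma(
            np.sqrt(fwhm0 ** 2 + (slope * (self.orbit_radii.max() + abs(y_mm).max())) ** 2)
        ) / self.spacing
        pad = int(np.ceil(5.0 * sig_max)) + 1
        self._px = next_fast_len(self.n + pad)
        self._pz = next_fast_len(self.nz + pad)
        fx2 = rfftfreq(self._px) ** 2
        fz2 = rfftfreq(self._pz) ** 2
        # rfft along x would halve the wrong axis; use full-resolution
        # frequencies along x via rfft over the last axis only, so the x
        # transfer needs all px frequencies
        fx_full2 = (np.fft.fftfreq(self._px)) ** 2
        transfers = []
        two_pi2 = 2.0 * np.pi ** 2
        for r in self.orbit_radii:
            depth = r - y_mm  # distance of slab to the collimator face
            sig2 = (fwhm_to_sigma(np.sqrt(fwhm0 ** 2 + (slope * depth) ** 2))
                    / self.spacing) ** 2
            gx = np.exp(-two_pi2 * sig2[:, None] * fx_full2[None, :]).astype(np.float32)
            gz = np.exp(-two_pi2 * sig2[:, None] * fz2[None, :]).astype(np.float32)
            transfers.append((gx, gz))
        return transfers

    # -- operators ---------------------------------------------------------
    def forward(self, x: np.ndarray, angle_idx: int) -> np.ndarray:
        """Project volume ``x`` into the (nx, nz) detector plane of one view.

        Internal arithmetic is single precision (adequate for count-level
        accuracy and twice as fast); forward and adjoint stay a matched
        pair because both use the same operators.
        """
        x = np.asarray(x, dtype=np.float32)
        r = (self._rot[angle_idx] @ x.reshape(self.n * self.n, self.nz))
        r = r.reshape(self.shape)
        att = self._att[angle_idx]
        if att is not None:
            r = r * att
        if self._sigma_px is None:
            return r.sum(axis=1)
        gx, gz = self._sigma_px[angle_idx]
        w = rfft2(r, s=(self._px, self._pz), axes=(0, 2))
        out_hat = np.einsum("ujv,ju,jv->uv", w, gx, gz)
        out = irfft2(out_hat, s=(self._px, self._pz), axes=(0, 1))
        return out[: self.n, : self.nz]

    def adjoint(self, p: np.ndarray, angle_idx: int) -> np.ndarray:
        """Transpose of :meth:`forward` for one view (matched pair)."""
        p = np.asarray(p, dtype=np.float32)
        if self._sigma_px is None:
            acc = np.broadcast_to(p[:, None, :], self.shape).copy()
        else:
            gx, gz = self._sigma_px[angle_idx]
            p_hat = rfft2(p, s=(self._px, self._pz), axes=(0, 1))
            acc_hat = np.einsum("uv,ju,jv->juv", p_hat, gx, gz)
            acc = irfft2(acc_hat, s=(self._px, self._pz), axes=(1, 2))
            acc = np.moveaxis(acc[:, : self.n, : self.nz], 0, 1)
        att = self._att[angle_idx]
        if att is not None:
            acc = acc * att
        out = self._rot[angle_idx].T @ np.ascontiguousarray(acc).reshape(
            self.n * self.n, self.nz
        )
        return out.reshape(self.shape)

    def forward_all(self, x: np.ndarray) -> np.ndarray:
        """Stack of projections for all views, shape (n_angles, nx, nz)."""
        return np.stack([self.forward(x, i) for i in range(len(self.angles))])

    def backproject(self, p: np.ndarray, angle_indices=None) -> np.ndarray:
        """Sum of adjoints over a set of views (default all)."""
        if angle_indices is None:
            angle_indices = range(len(self.angles))
        out = np.zeros(self.shape, dtype=np.float32)
        for i in angle_indices:
            out += self.adjoint(p[i], i)
        return out
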