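"""Diffuse-map utilities: isotropic/variational split, missing-voxel fill,
robust error-weighted Savitzky-Golay regridding, target-map assembly, and
resolution-shell statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .maps import VoxelMap

__all__ = [
    "ShellStatistics",
    "split_isotropic",
    "fill_missing",
    "robust_savgol_regrid",
    "build_target_map",
    "shell_stats",
]


def split_isotropic(vmap, n_bins=None, lam=None):
    """Fit a smooth 1D intensity-vs-resolution profile and subtract it.

    The measured intensities are binned by scattering-vector magnitude
    (1/d), bin means are joined by a smoothing spline, and the interpolant
    is evaluated at every voxel. Returns ``(profile, variational_map)``
    where ``profile`` is a callable of 1/d.
    """
    s = vmap.s_magnitude()
    meas = vmap.measured
    sv = s[meas]
    iv = vmap.data[meas]
    if n_bins is None:
        n_bins = max(20, min(200, int(np.sqrt(sv.size) / 4)))
    edges = np.linspace(0, sv.max() * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(sv, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=iv, minlength=n_bins)
    good = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])[good]
    means = (sums[good] / counts[good])
    if len(centers) < 4:
        raise ValueError("too few populated resolution bins")
    spline = make_smoothing_spline(centers, means, lam=lam)
    lo, hi = centers[0], centers[-1]

    def profile(x):
        return spline(np.clip(x, lo, hi))

    variational = vmap.copy(data=np.where(meas, vmap.data - profile(s), 0.0))
    return profile, variational


def fill_missing(vmap, max_iter=None):
    """Fill missing voxels with the mean of measured six-neighbors.

    Iterates until no fillable voxel remains; voxels that never acquire a
    measured neighbor stay flagged unmeasured.
    """
    data = np.array(vmap.data)
    meas = np.array(vmap.measured)
    if max_iter is None:
        max_iter = int(np.sum(~meas)) + 1
    from scipy.ndimage import convolve
    kernel = np.zeros((3, 3, 3))
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1
    for _ in range(max_iter):
        if np.all(meas):
            break
        nsum = convolve(np.where(meas, data, 0.0), kernel, mode="constant")
        ncnt = convolve(meas.astype(float), kernel, mode="constant")
        fillable = (~meas) & (ncnt > 0)
        if not np.any(fillable):
            break
        data[fillable] = nsum[fillable] / ncnt[fillable]
        meas[fillable] = True
    return vmap.copy(data=data, measured=meas)


@dataclass
class ShellStatistics:
    """Per-resolution-bin statistics of one map or a map pair."""

    edges: np.ndarray      # bin edges in 1/d (A^-1)
    mean_a: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    cc: np.ndarray
    counts: np.ndarray

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "s_center": self.centers, "mean": self.mean_a, "sd": self.sd_a,
            "sd_b": self.sd_b, "cc": self.cc, "n": self.counts,
        })


def shell_stats(map_a, map_b=None, bin_width=0.02, subtract_isotropic=True,
                min_voxels=5):
    """Mean, SD, and CC in resolution shells of width ``bin_width`` (1/d).

    SD and CC are computed after subtracting each map's smooth isotropic
    profile; bins with fewer than ``min_voxels`` voxels get NaN statistics.
    """
    s = map_a.s_magnitude()
    meas = map_a.measured if map_b is None else (map_a.measured & map_b.measured)
    a = map_a.data
    if subtract_isotropic:
        prof_a, _ = split_isotropic(map_a)
        a_var = a - prof_a(s)
    else:
        a_var = a
    if map_b is not None:
        b = map_b.data
        if subtract_isotropic:
            prof_b, _ = split_isotropic(map_b)
            b_var = b - prof_b(s)
        else:
            b_var = b
    edges = np.arange(0, s[meas].max() + bin_width, bin_width)
    n_bins = len(edges) - 1
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    mean_a = np.full(n_bins, np.nan)
    sd_a = np.full(n_bins, np.nan)
    sd_b = np.full(n_bins, np.nan)
    cc = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        sel = meas & (idx == i)
        counts[i] = sel.sum()
        if counts[i] < min_voxels:
            continue
        mean_a[i] = a[sel].mean()
        av = a_var[sel] - a_var[sel].mean()
        sd_a[i] = av.std()
        if map_b is not None:
            bv = b_var[sel] - b_var[sel].mean()
            sd_b[i] = bv.std()
            denom = np.sqrt((av**2).sum() * (bv**2).sum())
            cc[i] = float((av * bv).sum() / denom) if denom > 0 else np.nan
    return ShellStatistics(edges=edges, mean_a=mean_a, sd_a=sd_a, sd_b=sd_b,
                           cc=cc, counts=counts)


# ---------------------------------------------------------------------------
# robust error-weighted Savitzky-Golay regridding
# ---------------------------------------------------------------------------

def _poly_basis(x):
    """Second-order 3D polynomial basis (10 columns)."""
    return np.column_stack([
        np.ones(len(x)), x[:, 0], x[:, 1], x[:, 2],
        x[:, 0]**2, x[:, 1]**2, x[:, 2]**2,
        x[:, 0] * x[:, 1], x[:, 0] * x[:, 2], x[:, 1] * x[:, 2],
    ])


def bisquare_weights(residuals):
    """Bisquare factors: ``(1 - (r/6m)^2)^2`` inside ``|r| < 6m``, else 0.

    ``m`` is the median absolute deviation of the residuals.
    """
    r = np.asarray(residuals, dtype=float)
    m = np.median(np.abs(r - np.median(r)))
    if m <= 0:
        return np.ones_like(r)
    u = r / (6.0 * m)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w


def robust_savgol_regrid(vmap, target_hmax, target_subdivision=(1, 1, 1),
                         min_voxels=10, n_passes=2):
    """Regrid a map by local robust error-weighted quadratic fits.

    For each target voxel, parent voxels within a spherical neighborhood of
    radius ``(3 v_t / 4 pi)^(1/3)`` (``v_t`` = target voxel volume in
    reciprocal space) are fit with a second-order polynomial using
    inverse-variance weights; the fit value and propagated sigma are
    evaluated at the target point. A second pass multiplies the weights by
    bisquare factors computed from the first-pass residuals (via cubic
    interpolation of the pass-1 target map back onto the parent grid).

    Target voxels with fewer than ``min_voxels`` usable parents are flagged
    missing.
    """
    geom = vmap.geometry
    target = VoxelMap(geometry=geom, hmax=target_hmax,
                      subdivision=target_subdivision)
    # work in 1/d units (no 2 pi): reciprocal cell matrix
    R = geom.recip / (2 * np.pi)
    v_t = abs(np.linalg.det(R)) / np.prod(target.subdivision)
    radius = (3.0 * v_t / (4.0 * np.pi)) ** (1.0 / 3.0)

    meas = vmap.measured & (vmap.sigma > 0)
    ph = vmap.h_grid()[meas]
    pq = ph @ R.T
    pI = vmap.data[meas]
    psig = vmap.sigma[meas]
    tree = cKDTree(pq)
    th = target.h_grid().reshape(-1, 3)
    tq = th @ R.T
    neighborhoods = tree.query_ball_point(tq, radius)

    w_extra = np.ones(len(pq))
    for ipass in range(n_passes):
        vals = np.full(len(tq), np.nan)
        sigs = np.full(len(tq), np.nan)
        ok = np.zeros(len(tq), dtype=bool)
        for i, nb in enumerate(neighborhoods):
            nb = np.asarray(nb, dtype=int)
            if len(nb) > 0:
                nb = nb[w_extra[nb] > 0]
            if len(nb) < min_voxels:
                continue
            x = (pq[nb] - tq[i]) / radius
            X = _poly_basis(x)
            w = w_extra[nb] / psig[nb] ** 2
            XtW = X.T * w
            N = XtW @ X
            # degenerate neighborhoods (thin shells at the map edge) are
            # flagged missing rather than extrapolated
            try:
                evals = np.linalg.eigvalsh(N)
            except np.linalg.LinAlgError:
                continue
            if evals[0] <= 1e-10 * evals[-1]:
                continue
            cov = np.linalg.inv(N)
            beta = cov @ (XtW @ pI[nb])
            vals[i] = beta[0]
            sigs[i] = np.sqrt(max(cov[0, 0], 0.0))
            ok[i] = True
        if ipass + 1 >= n_passes:
            break
        # residuals via cubic interpolation of the target map back to parents
        tgrid = vals.reshape(target.shape)
        tgrid_f = np.where(np.isfinite(tgrid), tgrid, 0.0)
        coords = []
        for ax in range(3):
            hm, sd = target.hmax[ax], target.subdivision[ax]
            coords.append(ph[:, ax] * sd + hm * sd)
        interp = map_coordinates(tgrid_f, np.array(coords), order=3,
                                 mode="nearest")
        r = (pI - interp) / psig
        w_extra = bisquare_weights(r)
    target.data = vals.reshape(target.shape)
    target.sigma = np.where(np.isfinite(sigs.reshape(target.shape)),
                            sigs.reshape(target.shape), 0.0)
    target.measured = ok.reshape(target.shape)
    target.data[~target.measured] = 0.0
    return target


def build_target_map(exp_map, lattice_map, k0_map, target_hmax,
                     target_subdivision=(1, 1, 1), min_voxels=10):
    """Assemble an MD-comparable target map.

    Subtracts the full-supercell lattice simulation from the experimental
    map, robust-regrids the residual (internal motion) onto the MD-supercell
    Miller grid, and adds back the lattice scattering at the wavevectors the
    MD supercell supports (``k0_map``, e.g. the k = 0 intensities for a
    single-cell simulation).
    """
    internal = exp_map.copy(data=exp_map.data - lattice_map.data)
    regridded = robust_savgol_regrid(internal, target_hmax,
                                     target_subdivision, min_voxels=min_voxels)
    if regridded.shape != k0_map.shape:
        raise ValueError("k0 map must live on the target grid")
    out = regridded.copy(data=regridded.data + k0_map.data)
    out.measured &= k0_map.measured
    return out
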