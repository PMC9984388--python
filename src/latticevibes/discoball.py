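"""Model-free joint-ADP estimation by 3D-delta-PDF peak deconvolution.

The variational diffuse map is Fourier-transformed to real space, where
lattice vibrations produce sharp peaks at every lattice translation vector.
Each peak is (approximately) the Patterson origin peak convolved with the
transform of the quadratic form ``q . V q``, where ``V`` is the effective
joint-ADP of protein pairs related by that lattice vector. Working in
reciprocal space turns the deconvolution into ordinary least squares for the
six unique components of ``V``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

__all__ = [
    "DeltaPDF",
    "PattersonPeak",
    "JointADP",
    "compute_delta_pdf",
    "patterson_origin",
    "deconvolve_joint_adp",
    "effective_joint_adp",
    "split_adp",
    "validate_model",
    "deconvolve_map",
]


@dataclass
class JointADP:
    """Symmetrized 3x3 displacement covariance for a lattice-offset pair."""

    offset: tuple
    V: np.ndarray
    residual: float = 0.0
    condition: float = np.nan

    @property
    def total(self):
        return float(np.trace(self.V))

    @property
    def aniso(self):
        return self.V - np.eye(3) * self.total / 3.0


@dataclass
class DeltaPDF:
    """Real-space transform of the variational diffuse map.

    ``values`` covers ``n_cells`` unit cells per axis periodically with
    ``samples_per_cell`` grid points per cell, so every unit-cell translation
    vector within the field of view lies exactly on a grid node.
    """

    geometry: object
    values: np.ndarray
    n_cells: tuple
    samples_per_cell: tuple
    res_cutoff: float

    def node_index(self, n):
        """Array index of the lattice node at cell offset ``n``."""
        return tuple((ni * m) % (ci * m)
                     for ni, m, ci in zip(n, self.samples_per_cell, self.n_cells))

    def offsets(self):
        """Distinct lattice offsets in the field of view, origin first."""
        out = []
        for n1 in range(self.n_cells[0]):
            for n2 in range(self.n_cells[1]):
                for n3 in range(self.n_cells[2]):
                    n = tuple(ni - ci if ni > ci // 2 else ni
                              for ni, ci in zip((n1, n2, n3), self.n_cells))
                    out.append(n)
        out.sort(key=lambda n: (np.linalg.norm(
            self.geometry.to_cartesian(np.array(n, dtype=float))), n))
        return out

    def extract_peak(self, n, radius=4.0):
        """Spherically-masked peak region around lattice node ``n``.

        Returns ``(values, rel_cart)``: masked peak samples and their
        Cartesian positions relative to the node (only points with
        ``|r| < radius``).
        """
        vals, rel = self._crop(self.values, n, radius)
        return vals, rel

    def _crop(self, arr, n, radius):
        m = np.array(self.samples_per_cell)
        shape = np.array(arr.shape)
        node = np.array([ni * mi for ni, mi in zip(n, m)])
        step = self.geometry.orth / shape[None, :] * np.array(self.n_cells)[None, :]
        # half-widths in voxels covering the radius along each axis
        inv = np.linalg.inv(step)
        half = np.ceil(radius * np.linalg.norm(inv, axis=1)).astype(int) + 1
        ranges = [np.arange(-h, h + 1) for h in half]
        mesh = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
        rel = mesh @ step.T
        r = np.linalg.norm(rel, axis=-1)
        sel = r < radius
        i1 = (node[0] + mesh[..., 0]) % shape[0]
        i2 = (node[1] + mesh[..., 1]) % shape[1]
        i3 = (node[2] + mesh[..., 2]) % shape[2]
        vals = arr[i1, i2, i3]
        return vals[sel], rel[sel]


def compute_delta_pdf(vmap, res_cutoff=1.6):
    """FFT the variational diffuse map to real space.

    Intensities beyond the resolution cutoff and missing voxels are zeroed,
    the map is Friedel-symmetrized (so the transform is real), padded so the
    real-space grid is commensurate with the unit cell, and transformed. The
    result is scaled per unit cell.
    """
    data = np.where(vmap.measured, vmap.data, 0.0)
    if res_cutoff is not None:
        data = np.where(vmap.s_magnitude() <= 1.0 / res_cutoff, data, 0.0)
    # Friedel completion: average I(h) and I(-h) (grid is inversion-symmetric)
    data = 0.5 * (data + data[::-1, ::-1, ::-1])

    s = vmap.subdivision
    shape = np.array(data.shape)
    full = [si * (2 * hi + 1) for si, hi in zip(s, vmap.hmax)]
    pad = [(f - sh) // 2 for f, sh in zip(full, shape)]
    data = np.pad(data, [(p, p) for p in pad])
    wrapped = np.fft.ifftshift(data)
    pdf = np.fft.ifftn(wrapped) * np.prod(full)
    n_cells = int(np.prod(s))
    pdf /= n_cells
    im = float(np.abs(pdf.imag).max())
    scale = max(float(np.abs(pdf.real).max()), 1e-300)
    if im > 1e-8 * scale:
        raise RuntimeError(f"delta-PDF has residual imaginary part {im:g}")
    return DeltaPDF(
        geometry=vmap.geometry,
        values=pdf.real,
        n_cells=tuple(int(si) for si in s),
        samples_per_cell=tuple(2 * hi + 1 for hi in vmap.hmax),
        res_cutoff=res_cutoff if res_cutoff is not None else np.inf,
    )


@dataclass
class PattersonPeak:
    """Origin peak of the Patterson map on the delta-PDF's relative grid."""

    values: np.ndarray
    rel_cart: np.ndarray
    radius: float


def patterson_origin(geometry, h, intensities, samples_per_cell, radius=4.0,
                     target=None, res_cutoff=None):
    """Patterson origin peak from Bragg intensities.

    The FFT of the Bragg intensities (F000 term excluded) gives the Patterson
    map on a one-cell periodic grid; the central region is interpolated onto
    the same relative grid as the delta-PDF peaks (tricubic) and the
    spherical mask of ``radius`` Angstrom is applied.

    Parameters
    ----------
    geometry : UnitCellGeometry
    h : (n, 3) int array
        Miller indices (Friedel mates generated automatically).
    intensities : (n,) array
    samples_per_cell : tuple of int
        Patterson grid sampling (use the delta-PDF's ``samples_per_cell``).
    target : DeltaPDF, optional
        If given, the peak is evaluated at that map's relative peak grid;
        otherwise the Patterson's own grid nodes within the mask are used.
    """
    shape = np.array(samples_per_cell, dtype=int)
    grid = np.zeros(shape, dtype=float)
    h = np.atleast_2d(np.asarray(h, dtype=int))
    I = np.asarray(intensities, dtype=float)
    if res_cutoff is not None:
        keep = geometry.d_spacing(h.astype(float)) >= res_cutoff
        h, I = h[keep], I[keep]
    for hi, Ii in zip(h, I):
        if np.all(hi == 0):
            continue
        grid[tuple(hi % shape)] += Ii
        if np.any(((-hi) % shape) != (hi % shape)):
            grid[tuple((-hi) % shape)] += Ii
    pmap = np.fft.ifftn(grid).real * np.prod(shape)

    # relative grid to evaluate on
    if target is not None:
        _, rel = target._crop(target.values, (0, 0, 0), radius)
    else:
        step = geometry.orth / shape[None, :]
        inv = np.linalg.inv(step)
        half = np.ceil(radius * np.linalg.norm(inv, axis=1)).astype(int) + 1
        ranges = [np.arange(-hh, hh + 1) for hh in half]
        mesh = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
        rel = (mesh @ step.T)
        rel = rel[np.linalg.norm(rel, axis=-1) < radius]

    # fractional grid coordinates of the relative positions (periodic)
    frac = geometry.to_fractional(rel)
    coords = (frac * shape).T
    vals = map_coordinates(pmap, coords, order=3, mode="grid-wrap")
    return PattersonPeak(values=vals, rel_cart=rel, radius=radius)


def _quad_basis(q):
    """Design columns for the 6 unique components of a symmetric 3x3 form."""
    return np.stack([
        q[:, 0] ** 2, q[:, 1] ** 2, q[:, 2] ** 2,
        2 * q[:, 0] * q[:, 1], 2 * q[:, 0] * q[:, 2], 2 * q[:, 1] * q[:, 2],
    ], axis=1)


def _vec_to_sym(v):
    return np.array([
        [v[0], v[3], v[4]],
        [v[3], v[1], v[5]],
        [v[4], v[5], v[2]],
    ])


def default_q_samples(res_cutoff=1.6, exclusion=5.0, radius=4.0):
    """Reciprocal sample set for the deconvolution fit.

    A Cartesian q grid with spacing ``pi / (2 * radius)`` (half the Nyquist
    spacing of the masked peak) restricted to the resolution shell
    ``exclusion >= d >= res_cutoff``.
    """
    qmax = 2 * np.pi / res_cutoff
    dq = np.pi / (2 * radius)
    ax = np.arange(-qmax, qmax + dq / 2, dq)
    Q = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    qn = np.linalg.norm(Q, axis=1)
    keep = (qn <= qmax) & (qn >= 2 * np.pi / exclusion)
    return Q[keep]


def deconvolve_joint_adp(peak_values, peak_rel, patterson, q_samples=None,
                         res_cutoff=1.6, exclusion=5.0):
    """Recover a joint-ADP from a masked delta-PDF peak.

    Transforms the masked peak and the masked Patterson origin peak to
    reciprocal space (``Y(q)`` and ``X(q)``) and solves the ordinary least
    squares problem ``Y(q) = X(q) (q . V q)`` for the six unique components
    of ``V``, excluding samples with d-spacing above ``exclusion``.

    Returns a :class:`JointADP` with the fit residual norm and the condition
    number of the design matrix.
    """
    if q_samples is None:
        q_samples = default_q_samples(res_cutoff, exclusion, patterson.radius)
    if len(q_samples) < 6:
        raise ValueError("fewer than 6 reciprocal samples for the fit")
    # inverse FT of the masked peaks at the sample q
    EY = np.exp(-1j * peak_rel @ q_samples.T)      # (npeak, nq)
    Y = peak_values @ EY
    EX = np.exp(-1j * patterson.rel_cart @ q_samples.T)
    X = patterson.values @ EX
    B = _quad_basis(q_samples)
    M = X[:, None] * B
    A = np.concatenate([M.real, M.imag])
    y = np.concatenate([Y.real, Y.imag])
    sol, res, rank, sv = np.linalg.lstsq(A, y, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    resid = float(np.linalg.norm(A @ sol - y))
    return JointADP(offset=(0, 0, 0), V=_vec_to_sym(sol),
                    residual=resid, condition=cond)


def deconvolve_map(vmap, bragg_h, bragg_I, res_cutoff=1.6, radius=4.0,
                   exclusion=5.0, max_offsets=None, apodize=False):
    """Deconvolution analysis of a diffuse map: joint-ADP per lattice peak.

    Computes the delta-PDF, the Patterson origin peak, and deconvolves every
    lattice node in the field of view. ``apodize`` multiplies both masked
    peaks by a cosine-squared taper, which suppresses spectral leakage from
    the truncation ringing of neighboring-peak backgrounds (the hard
    spherical mask alone is the default). Returns a list of
    :class:`JointADP` ordered by distance from the origin.
    """
    pdf = compute_delta_pdf(vmap, res_cutoff=res_cutoff)
    patt = patterson_origin(vmap.geometry, bragg_h, bragg_I,
                            pdf.samples_per_cell, radius=radius, target=pdf,
                            res_cutoff=None)
    if apodize:
        w = np.cos(np.pi * np.linalg.norm(patt.rel_cart, axis=1)
                   / (2 * radius)) ** 2
        patt = PattersonPeak(values=patt.values * w, rel_cart=patt.rel_cart,
                             radius=radius)
    else:
        w = 1.0
    q_samples = default_q_samples(res_cutoff, exclusion, radius)
    out = []
    offsets = pdf.offsets()
    if max_offsets is not None:
        offsets = offsets[:max_offsets]
    for n in offsets:
        vals, rel = pdf.extract_peak(n, radius=radius)
        adp = deconvolve_joint_adp(vals * w, rel, patt, q_samples=q_samples,
                                   res_cutoff=res_cutoff, exclusion=exclusion)
        adp.offset = tuple(n)
        out.append(adp)
    return out


def effective_joint_adp(joint_adps):
    """Average self joint-ADPs over the K rigid groups (one per offset).

    ``joint_adps`` is the dict returned by
    :func:`~latticevibes.lattice_dynamics.com_joint_adps`; only the
    ``kappa == kappa'`` entries enter the average.
    """
    by_offset = {}
    for (n, ka, kb), V in joint_adps.items():
        if ka != kb:
            continue
        by_offset.setdefault(n, []).append(V)
    return {n: JointADP(offset=n, V=np.mean(vs, axis=0))
            for n, vs in by_offset.items()}


def split_adp(V):
    """Split a joint-ADP into (total, traceless anisotropic part)."""
    V = np.asarray(V, dtype=float)
    total = float(np.trace(V))
    return total, V - np.eye(3) * total / 3.0


_TRI = np.triu_indices(3)


def _aniso_components(V):
    _, an = split_adp(V)
    return an[_TRI]


def validate_model(estimated, model, fit_intercept=True):
    """Compare two joint-ADP sets paired by lattice offset.

    Fits an affine line to the scatter of estimated vs model total
    covariances (the intercept absorbs differing asymptotics) and computes
    Pearson correlations for the totals and for the pooled anisotropic
    components.

    Parameters
    ----------
    estimated : list of JointADP (e.g. from deconvolution)
    model : dict offset -> JointADP (e.g. from :func:`effective_joint_adp`)

    Returns
    -------
    dict with ``slope``, ``intercept``, ``r_total``, ``r_aniso``, ``n_pairs``.
    """
    pairs = []
    for adp in estimated:
        m = model.get(tuple(adp.offset))
        if m is not None:
            pairs.append((adp, m))
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched offsets")
    x = np.array([m.total for _, m in pairs])
    y = np.array([e.total for e, _ in pairs])
    if fit_intercept:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope, intercept = float(x @ y / (x @ x)), 0.0
    r_total = pearsonr(x, y).statistic if np.std(x) > 0 and np.std(y) > 0 else np.nan
    ax = np.concatenate([_aniso_components(m.V) for _, m in pairs])
    ay = np.concatenate([_aniso_components(e.V) for e, _ in pairs])
    r_aniso = pearsonr(ax, ay).statistic if np.std(ax) > 0 else np.nan
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_total": float(r_total),
        "r_aniso": float(r_aniso),
        "n_pairs": len(pairs),
    }
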