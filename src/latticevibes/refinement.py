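"""Staged refinement of spring constants against measured diffuse halos.

Each halo is the block of map voxels in the Brillouin zone of an intense
Bragg peak (the central voxel excluded). The model intensity is the
one-phonon prediction plus a per-halo linear background (4 coefficients:
constant + gradient in the fractional offset from the reciprocal-lattice
point). Backgrounds are profiled out exactly — a linear subproblem per halo
per objective evaluation — while the spring constants are optimized by
bound-constrained trust-region least squares in log space.

Stages progressively release restraints: (1) one global Gaussian constant;
(2) Gaussian per interface; (3) hybrid (Gaussian + parallel) per interface;
(4) hybrid per residue pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .crystal_model import SpringParameterSet
from .lattice_dynamics import covariance_kernel
from .diffuse_sim import one_phonon_sf

__all__ = [
    "HaloObservation",
    "RefinementStage",
    "STAGES",
    "select_halos",
    "halo_residual",
    "profile_background",
    "refine_stage",
    "refine",
    "subtract_lattice",
]


@dataclass
class HaloObservation:
    """Measured voxels surrounding one Bragg peak."""

    h_center: tuple              # integer Miller index
    dk: np.ndarray               # (m, 3) fractional offsets from the RLP
    intensities: np.ndarray      # (m,)
    sigmas: np.ndarray           # (m,)
    resolution: float            # d-spacing of the central RLP (A)

    def __post_init__(self):
        self.dk = np.atleast_2d(np.asarray(self.dk, dtype=float))
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(self.sigmas <= 0):
            raise ValueError("halo sigmas must be positive")
        if np.any(np.abs(self.dk) > 0.5 + 1e-9):
            raise ValueError("halo voxels must lie in the central RLP's "
                             "Brillouin zone")

    @property
    def n_voxels(self):
        return len(self.intensities)

    def background_design(self):
        """Design matrix of the 4-parameter linear background."""
        return np.column_stack([np.ones(self.n_voxels), self.dk])


@dataclass
class RefinementStage:
    """One stage of the staged spring-constant refinement."""

    index: int
    level: str          # "global" | "interface" | "residue"
    form: str           # "gaussian" | "hybrid"


STAGES = (
    RefinementStage(1, "global", "gaussian"),
    RefinementStage(2, "interface", "gaussian"),
    RefinementStage(3, "interface", "hybrid"),
    RefinementStage(4, "residue", "hybrid"),
)


def select_halos(bragg, vmap, resolution_range=(2.0, 2.5), n=400,
                 exclude_center=True):
    """Pick the ``n`` most intense Bragg peaks in a resolution window and
    extract their surrounding halo voxels from the map.

    ``bragg`` is a DataFrame-like mapping with columns h, k, l, I (sigma
    optional). Unmeasured voxels are dropped; the central (Bragg) voxel is
    excluded. Warns (via the returned count) if fewer than ``n`` peaks fall
    in the window; raises if none do.
    """
    import pandas as pd
    df = pd.DataFrame(bragg)
    geom = vmap.geometry
    hkl = df[["h", "k", "l"]].to_numpy(dtype=float)
    d = geom.d_spacing(hkl)
    lo, hi = min(resolution_range), max(resolution_range)
    sel = (d >= lo) & (d <= hi)
    if not np.any(sel):
        raise ValueError("no Bragg peaks in the resolution window")
    df = df.loc[sel].copy()
    df["d"] = d[sel]
    df = df.sort_values("I", ascending=False).head(n)

    halos = []
    s = vmap.subdivision
    for _, row in df.iterrows():
        hc = (int(row.h), int(row.k), int(row.l))
        dks, Is, sigs = [], [], []
        for d1 in range(-(s[0] // 2), s[0] // 2 + 1):
            for d2 in range(-(s[1] // 2), s[1] // 2 + 1):
                for d3 in range(-(s[2] // 2), s[2] // 2 + 1):
                    if exclude_center and d1 == d2 == d3 == 0:
                        continue
                    dk = (d1 / s[0], d2 / s[1], d3 / s[2])
                    hf = np.add(hc, dk)
                    try:
                        idx = vmap.index_of(hf)
                    except IndexError:
                        continue
                    if not vmap.measured[idx]:
                        continue
                    dks.append(dk)
                    Is.append(vmap.data[idx])
                    sigs.append(vmap.sigma[idx] if vmap.sigma[idx] > 0 else 1.0)
        if len(dks) < 6:
            continue
        halos.append(HaloObservation(
            h_center=hc, dk=np.array(dks), intensities=np.array(Is),
            sigmas=np.array(sigs), resolution=float(row.d)))
    if not halos:
        raise ValueError("no usable halos extracted")
    return halos


def profile_background(halo, model_intensity):
    """Exact weighted least-squares background for fixed model intensities.

    Returns ``(coeffs, residuals)`` where ``coeffs`` are the 4 background
    coefficients minimizing ``sum ((I - I_model - B b)/sigma)^2``.
    """
    B = halo.background_design()
    w = 1.0 / halo.sigmas
    y = (halo.intensities - model_intensity) * w
    A = B * w[:, None]
    coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coeffs
    return coeffs, resid


def halo_residual(halo, model_intensity, background=None):
    """Inverse-sigma-weighted residual vector for one halo.

    If ``background`` is None the optimal 4-coefficient background is
    profiled out first.
    """
    if background is None:
        _, resid = profile_background(halo, model_intensity)
        return resid
    B = halo.background_design()
    return (halo.intensities - model_intensity - B @ background) / halo.sigmas


class HaloModel:
    """Cached one-phonon predictor for a fixed halo set.

    The one-phonon structure factors depend only on the density model, so
    they are evaluated once per halo voxel; each objective evaluation only
    rebuilds the 6K x 6K covariance kernels at the unique wavevectors.
    """

    def __init__(self, network, transforms, halos, kT=1.0):
        self.network = network
        self.halos = halos
        self.kT = kT
        geom = network.crystal.geometry
        Gs = []
        kkey = []
        keys = {}
        self._slices = []
        start = 0
        for halo in halos:
            q = geom.q_cartesian(np.add(halo.h_center, halo.dk))
            Gs.append(one_phonon_sf(transforms, None, q))
            for dk in halo.dk:
                key = tuple(np.round(-dk, 9))
                keys.setdefault(key, len(keys))
                kkey.append(keys[key])
            self._slices.append(slice(start, start + halo.n_voxels))
            start += halo.n_voxels
        self._G = np.concatenate(Gs)                  # (n_total, 6K)
        self._kkey = np.array(kkey)
        self._kvecs = [np.array(k) for k in keys]
        # pre-group voxel indices by wavevector for batched evaluation
        self._by_key = [np.where(self._kkey == i)[0]
                        for i in range(len(self._kvecs))]

    def intensities(self, params):
        """Per-halo model intensity arrays for the given spring parameters."""
        I = np.empty(len(self._G))
        for kern_idx, idx in enumerate(self._by_key):
            if len(idx) == 0:
                continue
            kern = covariance_kernel(self.network, params,
                                     self._kvecs[kern_idx])
            G = self._G[idx]
            I[idx] = self.kT * np.einsum(
                "qa,ab,qb->q", G, kern, G.conj()).real
        return [I[sl] for sl in self._slices]


def _stage_parameter_map(stage, contacts):
    """Contact -> stage parameter-group index, honoring symmetry grouping."""
    if stage.level == "global":
        ids = np.zeros(len(contacts), dtype=int)
        n = 1
    elif stage.level == "interface":
        ids = np.array([c.interface_id for c in contacts])
        n = ids.max() + 1
    else:
        ids = np.array([c.residue_pair_id for c in contacts])
        n = ids.max() + 1
    return ids, int(n)


def _params_from_vector(theta, stage, ids, n_groups_contacts):
    """Expand the stage's log-parameters to a per-contact SpringParameterSet."""
    n = ids.max() + 1
    if stage.form == "gaussian":
        gg = np.exp(theta[:n])
        gp = np.zeros(n)
    else:
        gg = np.exp(theta[:n])
        gp = np.exp(theta[n:2 * n])
    ps = SpringParameterSet(level=stage.level, n_groups=n, gamma_g=gg,
                            gamma_p=gp)
    return ps


def refine_stage(stage, halo_model, init_gamma_g, init_gamma_p=None,
                 max_iter=200, xtol=1e-10, ftol=1e-6, verbose=0):
    """Run one refinement stage; returns (params, report).

    ``init_gamma_g``/``init_gamma_p`` are per-stage-group arrays (child
    groups inherit the parent value before calling). Hybrid stages with zero
    parallel initial values are started at 1e-3 of the Gaussian constant.
    """
    contacts = halo_model.network.contacts
    ids, n = _stage_parameter_map(stage, contacts)
    gg0 = np.broadcast_to(np.asarray(init_gamma_g, dtype=float), (n,)).copy()
    theta0 = [np.log(np.clip(gg0, 1e-12, None))]
    if stage.form == "hybrid":
        gp0 = (np.broadcast_to(np.asarray(init_gamma_p, dtype=float), (n,)).copy()
               if init_gamma_p is not None else np.zeros(n))
        gp0 = np.where(gp0 <= 0, 1e-3 * gg0, gp0)
        theta0.append(np.log(gp0))
    theta0 = np.concatenate(theta0)

    class _P:
        """Adapter: per_contact via the stage's grouping."""
        def __init__(self, gg, gp):
            self.gg, self.gp = gg, gp
        def per_contact(self, contacts_):
            return self.gg[ids], self.gp[ids]

    def build(theta):
        if stage.form == "gaussian":
            return _P(np.exp(theta), np.zeros(n))
        return _P(np.exp(theta[:n]), np.exp(theta[n:]))

    def residuals(theta):
        ps = build(theta)
        model = halo_model.intensities(ps)
        res = [halo_residual(h, m) for h, m in
               zip(halo_model.halos, model)]
        return np.concatenate(res)

    result = least_squares(residuals, theta0, method="trf", max_nfev=max_iter,
                           xtol=xtol, ftol=ftol, verbose=verbose)
    theta = result.x
    ps = build(theta)
    model = halo_model.intensities(ps)
    backgrounds = [profile_background(h, m)[0]
                   for h, m in zip(halo_model.halos, model)]
    chi2 = float(result.cost * 2)
    gamma_g = np.exp(theta[:n])
    gamma_p = np.exp(theta[n:2 * n]) if stage.form == "hybrid" else np.zeros(n)
    report = {
        "stage": stage.index,
        "level": stage.level,
        "form": stage.form,
        "n_parameters": len(theta0),
        "chi2": chi2,
        "n_residuals": sum(h.n_voxels for h in halo_model.halos),
        "gamma_g": gamma_g.tolist(),
        "gamma_p": gamma_p.tolist(),
        "backgrounds": [b.tolist() for b in backgrounds],
        "converged": bool(result.success),
    }
    return (gamma_g, gamma_p, ids), report


def refine(halo_model, init_gamma=1.0, stages=STAGES, **kwargs):
    """Run the staged refinement; returns (SpringParameterSet, reports).

    Stage-to-stage initialization: each child parameter group inherits its
    parent group's refined value.
    """
    contacts = halo_model.network.contacts
    reports = []
    prev = None  # (gamma_g per contact, gamma_p per contact)
    gg_c = np.full(len(contacts), float(init_gamma))
    gp_c = np.zeros(len(contacts))
    prev_chi2 = np.inf
    for stage in stages:
        ids, n = _stage_parameter_map(stage, contacts)
        # initialize each stage group from the mean of its contacts' values
        gg0 = np.array([gg_c[ids == g].mean() for g in range(n)])
        gp0 = np.array([gp_c[ids == g].mean() for g in range(n)])
        (gg, gp, ids), rep = refine_stage(stage, halo_model, gg0, gp0, **kwargs)
        rep["chi2_decreased"] = bool(rep["chi2"] <= prev_chi2 * (1 + 1e-9))
        prev_chi2 = min(prev_chi2, rep["chi2"])
        reports.append(rep)
        gg_c = gg[ids]
        gp_c = gp[ids]
    # final parameter set at the last stage's grouping
    last = stages[-1]
    ids, n = _stage_parameter_map(last, contacts)
    final = SpringParameterSet(level=last.level, n_groups=n,
                               gamma_g=gg, gamma_p=gp)
    for c, pid in zip(contacts, ids):
        c.parameter_id = int(pid)
    return final, reports


def subtract_lattice(total_map, lattice_map, total_adps=None,
                     lattice_adps=None):
    """Subtract the lattice (rigid-body) contribution from map and ADPs.

    Voxel-wise ``I_internal = I_total - I_lattice`` with sigma unchanged;
    per-atom ``U_internal = U_total - U_lattice`` with non-PSD results
    flagged.

    Returns ``(residual_map, residual_U, not_psd_flags)``; the ADP outputs
    are None when no ADPs are given.
    """
    if total_map.data.shape != lattice_map.data.shape:
        raise ValueError("maps must share a grid")
    res = total_map.copy(data=total_map.data - lattice_map.data)
    res.measured = total_map.measured & lattice_map.measured
    if total_adps is None or lattice_adps is None:
        return res, None, None
    U = np.asarray(total_adps) - np.asarray(lattice_adps)
    flags = np.array([np.linalg.eigvalsh(u).min() < -1e-10 for u in U])
    return res, U, flags
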