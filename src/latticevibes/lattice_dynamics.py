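"""Born/Von-Karman lattice dynamics for rigid-body elastic networks.

Each rigid group carries six generalized coordinates (three translations,
three rotations about the group origin). The spring network defines a
generalized Hessian whose Fourier transform over cell offsets yields, after
mass reduction, the dynamical matrix ``D(k)``. Classical equipartition then
gives the covariance of generalized coordinates as a sum of ``L^-T D+(k)
L^-1`` kernels over the supercell wavevector grid. From the covariance we
extract TLS matrices, per-atom ADPs, and center-of-mass joint-ADPs.

Spring constants are expressed in units of kT/A^2, so the thermal scale
enters only through the single prefactor ``kT``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SpringNetwork",
    "projection_matrix",
    "mass_factor",
    "assemble_dynamical_matrix",
    "covariance_kernel",
    "vcov_supercell",
    "VCov",
    "tls_from_vcov",
    "adps_from_tls",
    "com_joint_adps",
    "AtomicADP",
]

# eigenvalues below this fraction of the maximum are treated as zero modes
ZERO_MODE_RTOL = 1e-8


def projection_matrix(x):
    """3x6 operator mapping generalized displacements to Cartesian ones.

    For an atom at position ``x`` relative to the group origin,
    ``u = A(x) w`` with ``w = (t1,t2,t3,th1,th2,th3)`` gives
    ``u = t + theta x x`` (small-rotation linearization)::

        A(x) = | 1 0 0    0   x3  -x2 |
               | 0 1 0  -x3    0   x1 |
               | 0 0 1   x2  -x1    0 |
    """
    x = np.asarray(x, dtype=float)
    A = np.zeros((3, 6))
    A[:, :3] = np.eye(3)
    A[0, 4], A[0, 5] = x[2], -x[1]
    A[1, 3], A[1, 5] = -x[2], x[0]
    A[2, 3], A[2, 4] = x[1], -x[0]
    return A


def _group_projections(group):
    """Stacked A matrices (n_atoms, 3, 6) for all atoms of a group."""
    x = group.xyz - group.origin
    A = np.zeros((len(x), 3, 6))
    A[:, :, :3] = np.eye(3)
    A[:, 0, 4], A[:, 0, 5] = x[:, 2], -x[:, 1]
    A[:, 1, 3], A[:, 1, 5] = -x[:, 2], x[:, 0]
    A[:, 2, 3], A[:, 2, 4] = x[:, 1], -x[:, 0]
    return A


def mass_factor(crystal):
    """Block-diagonal lower-triangular factor of the generalized mass matrix.

    The 6x6 generalized mass matrix of group kappa is ``M = sum_j m_j A_j^T
    A_j``; its Cholesky factor ``L`` satisfies ``L L^T = M``. Returns the
    per-group factors stacked as an array of shape (K, 6, 6).

    Raises
    ------
    ValueError
        If a group's mass matrix is singular (e.g. all atoms collinear, which
        leaves a free rotation); perturb the geometry or use fewer DOF.
    """
    K = crystal.n_groups
    L = np.zeros((K, 6, 6))
    for k, g in enumerate(crystal.groups):
        A = _group_projections(g)
        M = np.einsum("j,jab,jac->bc", g.masses, A, A)
        try:
            L[k] = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"generalized mass matrix of group {k} is singular "
                "(collinear or single-atom body); perturb the geometry or "
                "reduce the degrees of freedom") from None
    return L


@dataclass
class SpringNetwork:
    """A rigid-group crystal plus its contact list and parameter grouping."""

    crystal: object
    contacts: list
    params: object  # SpringParameterSet skeleton (grouping only)

    def __post_init__(self):
        self._proj = [_group_projections(g) for g in self.crystal.groups]
        self._L = None
        self._blocks = None

    @property
    def n_groups(self):
        return self.crystal.n_groups

    @property
    def mass_factors(self):
        if self._L is None:
            self._L = mass_factor(self.crystal)
        return self._L

    def _linv(self):
        return np.stack([np.linalg.inv(L) for L in self.mass_factors])

    def _unit_blocks(self):
        """Per-contact 6x6 generalized blocks for unit Gaussian/parallel
        stiffness, so Phi(k) assembly is a vectorized weighted sum."""
        if self._blocks is not None:
            return self._blocks
        nc = len(self.contacts)
        B = {name: np.zeros((nc, 6, 6)) for name in
             ("g_ii", "g_jj", "g_ij", "p_ii", "p_jj", "p_ij")}
        gi = np.empty(nc, dtype=int)
        gj = np.empty(nc, dtype=int)
        offs = np.empty((nc, 3))
        for ic, c in enumerate(self.contacts):
            Ai = self._proj[c.group_i][c.atom_i]
            Aj = self._proj[c.group_j][c.atom_j]
            u = c.vector / c.length
            for name, C in (("g", np.eye(3)), ("p", np.outer(u, u))):
                AiC = Ai.T @ C
                B[f"{name}_ii"][ic] = AiC @ Ai
                B[f"{name}_jj"][ic] = Aj.T @ C @ Aj
                B[f"{name}_ij"][ic] = -AiC @ Aj
            gi[ic], gj[ic] = c.group_i, c.group_j
            offs[ic] = c.offset
        self._blocks = (B, gi, gj, offs)
        return self._blocks

    def generalized_hessian(self, params, k_frac):
        """Fourier-transformed generalized Hessian Phi(k), shape (6K, 6K).

        ``k_frac`` is the wavevector in fractional reciprocal coordinates
        (phase ``exp(2*pi*i k.n)`` for a partner displaced by integer cell
        offset n). Both directions of each stored unordered contact are
        accumulated, with self terms ensuring Phi(0) annihilates uniform
        translations.
        """
        K = self.n_groups
        B, gi, gj, offs = self._unit_blocks()
        gg, gp = params.per_contact(self.contacts)
        k_frac = np.asarray(k_frac, dtype=float)
        phase = np.exp(2j * np.pi * offs @ k_frac)
        wg = gg[:, None, None]
        wp = gp[:, None, None]
        Phi = np.zeros((K, K, 6, 6), dtype=complex)
        np.add.at(Phi, (gi, gi), wg * B["g_ii"] + wp * B["p_ii"])
        np.add.at(Phi, (gj, gj), wg * B["g_jj"] + wp * B["p_jj"])
        cross = (wg * B["g_ij"] + wp * B["p_ij"]) * phase[:, None, None]
        np.add.at(Phi, (gi, gj), cross)
        np.add.at(Phi, (gj, gi), cross.conj().transpose(0, 2, 1))
        return Phi.transpose(0, 2, 1, 3).reshape(6 * K, 6 * K)


def assemble_dynamical_matrix(network, params, k_frac):
    """Mass-reduced dynamical matrix ``D(k) = L^-1 Phi(k) L^-T`` (Hermitian).

    Returns ``(D, eigenvalues, eigenvectors)``; eigenvalues are squared
    vibrational frequencies in kT units, sorted ascending.
    """
    Phi = network.generalized_hessian(params, k_frac)
    Linv = network._linv()
    K = network.n_groups
    D = np.zeros_like(Phi)
    for a in range(K):
        ia = slice(6 * a, 6 * a + 6)
        for b in range(K):
            ib = slice(6 * b, 6 * b + 6)
            D[ia, ib] = Linv[a] @ Phi[ia, ib] @ Linv[b].conj().T
    D = 0.5 * (D + D.conj().T)
    evals, evecs = scipy.linalg.eigh(D)
    return D, evals, evecs


def _translation_basis(network):
    """Orthonormal basis of mass-reduced uniform translations (6K x 3)."""
    L = network.mass_factors
    K = network.n_groups
    B = np.zeros((6 * K, 3))
    for k in range(K):
        B[6 * k:6 * k + 6] = L[k].T @ np.vstack([np.eye(3), np.zeros((3, 3))])
    Q, _ = np.linalg.qr(B)
    return Q


def _pinv_dynamical(network, evals, evecs, D, k_frac):
    """Pseudo-inverse of D(k) with the acoustic null space handled exactly.

    At the Gamma point the three rigid-translation modes are removed by
    deflating the known null space (robust even when the stiffness spectrum
    spans many orders of magnitude); there must be exactly three. Off Gamma
    a stable connected network has no zero modes: tiny or negative
    eigenvalues raise.
    """
    emax = float(np.max(np.abs(evals))) if len(evals) else 0.0
    k_frac = np.asarray(k_frac, dtype=float)
    at_gamma = np.allclose(k_frac - np.round(k_frac), 0.0, atol=1e-12)
    if np.any(evals < -ZERO_MODE_RTOL * max(emax, 1.0)):
        raise ValueError(
            f"unstable network: negative eigenvalue {evals.min():.3g} at "
            f"k={k_frac}")
    if at_gamma:
        B = _translation_basis(network)
        resid = np.linalg.norm(D @ B) / max(emax, 1.0)
        if resid > 1e-6:
            raise ValueError(
                "translations are not zero modes at k=0 "
                f"(residual {resid:.2e}); Hessian assembly inconsistent")
        # numerical zeros sit at roundoff (~1e-14 emax); genuine soft modes
        # stay well above 1e-12 emax even for extreme stiffness ratios
        n_zero = int((np.abs(evals) < 1e-12 * max(emax, 1.0)).sum())
        if n_zero != 3:
            raise ValueError(
                f"expected 3 zero modes at k=0, found {n_zero}")
        sigma = max(emax, 1.0)
        reg = D + sigma * (B @ B.conj().T)
        return np.linalg.inv(reg) - (B @ B.conj().T) / sigma
    floor = 1e-14 * max(emax, 1.0)
    if evals.min() <= floor:
        raise ValueError(
            f"zero-frequency mode at k={k_frac} "
            f"(eigenvalue {evals.min():.3g}); network is not stable/connected")
    return (evecs / evals) @ evecs.conj().T


def covariance_kernel(network, params, k_frac):
    """The 6K x 6K kernel ``L^-T D+(k) L^-1`` entering covariance/intensity.

    At k = 0 exactly three zero-frequency modes (rigid supercell
    translations) are removed by the pseudo-inverse; at any other wavevector
    a stable connected network must have no zero modes.
    """
    k_frac = np.asarray(k_frac, dtype=float)
    D, evals, evecs = assemble_dynamical_matrix(network, params, k_frac)
    Dp = _pinv_dynamical(network, evals, evecs, D, k_frac)
    Linv = network._linv()
    K = network.n_groups
    out = np.zeros_like(Dp)
    for a in range(K):
        ia = slice(6 * a, 6 * a + 6)
        for b in range(K):
            ib = slice(6 * b, 6 * b + 6)
            out[ia, ib] = Linv[a].conj().T @ Dp[ia, ib] @ Linv[b]
    return out


@dataclass
class VCov:
    """Generalized-coordinate covariance blocks on a periodic supercell.

    ``blocks[n1, n2, n3]`` is the 6K x 6K real matrix
    ``<w_l w_{l'}^T>`` for cells separated by offset ``(n1, n2, n3)``
    (wrapped periodically; index with ``block(offset)``).
    """

    supercell: tuple
    kT: float
    blocks: np.ndarray  # (N1, N2, N3, 6K, 6K)

    @property
    def n_groups(self):
        return self.blocks.shape[-1] // 6

    def block(self, offset=(0, 0, 0)):
        n = tuple(int(o) % s for o, s in zip(offset, self.supercell))
        return self.blocks[n]

    def group_pair(self, offset, kappa, kappa_p):
        b = self.block(offset)
        return b[6 * kappa:6 * kappa + 6, 6 * kappa_p:6 * kappa_p + 6]

    def offsets(self, wrap_negative=True):
        """All distinct cell offsets, centered (e.g. -N/2..N/2)."""
        out = []
        for n1 in range(self.supercell[0]):
            for n2 in range(self.supercell[1]):
                for n3 in range(self.supercell[2]):
                    n = [n1, n2, n3]
                    if wrap_negative:
                        n = [ni - Ni if ni > Ni // 2 else ni
                             for ni, Ni in zip(n, self.supercell)]
                    out.append(tuple(n))
        return out


def wavevector_grid(supercell):
    """Fractional wavevectors k = (n1/N1, n2/N2, n3/N3) wrapped to the first
    Brillouin zone, as an array of shape (N, 3) with integer index triples."""
    N1, N2, N3 = supercell
    ks = []
    idx = []
    for n1 in range(N1):
        for n2 in range(N2):
            for n3 in range(N3):
                k = np.array([n1 / N1, n2 / N2, n3 / N3])
                k -= np.round(k)  # wrap to (-1/2, 1/2]
                ks.append(k)
                idx.append((n1, n2, n3))
    return np.array(ks), idx


def vcov_supercell(network, params, supercell=(8, 8, 8), kT=1.0):
    """Covariance of generalized coordinates on an N1 x N2 x N3 supercell.

    Sums ``exp(2*pi*i k.n) L^-T D+(k) L^-1`` over the allowed wavevectors
    (integer fractions of the supercell), scaled by ``kT / N``. The three
    acoustic modes at k = 0 are removed by the pseudo-inverse.
    """
    supercell = tuple(int(s) for s in supercell)
    if any(s < 1 for s in supercell):
        raise ValueError("supercell dimensions must be >= 1")
    K = network.n_groups
    N1, N2, N3 = supercell
    N = N1 * N2 * N3
    ks, idx = wavevector_grid(supercell)
    kernels = np.zeros((len(ks), 6 * K, 6 * K), dtype=complex)
    for i, k in enumerate(ks):
        kernels[i] = covariance_kernel(network, params, k)
    blocks = np.zeros((N1, N2, N3, 6 * K, 6 * K), dtype=complex)
    for n1 in range(N1):
        for n2 in range(N2):
            for n3 in range(N3):
                phases = np.exp(2j * np.pi * ks @ np.array([n1, n2, n3]))
                blocks[n1, n2, n3] = np.tensordot(phases, kernels, axes=1)
    blocks *= kT / N
    imag_max = float(np.abs(blocks.imag).max())
    scale = float(np.abs(blocks.real).max()) or 1.0
    if imag_max > 1e-9 * scale:
        raise RuntimeError(f"covariance has residual imaginary part {imag_max:g}")
    return VCov(supercell=supercell, kT=kT, blocks=blocks.real)


def tls_from_vcov(vcov, kappa=0):
    """Extract (T, L, S) from the diagonal block of group ``kappa``.

    The 6x6 self covariance is laid out as ``[[T, S^T], [S, L]]`` with the
    translational block first.
    """
    b = vcov.group_pair((0, 0, 0), kappa, kappa)
    T = b[:3, :3]
    L = b[3:, 3:]
    S = b[3:, :3]
    return T, L, S


@dataclass
class AtomicADP:
    """Per-atom anisotropic displacement parameters."""

    U: np.ndarray       # (n_atoms, 3, 3), A^2
    group_index: np.ndarray

    @property
    def b_iso(self):
        """Equivalent isotropic B = 8 pi^2 trace(U)/3 (A^2)."""
        return 8 * np.pi**2 * np.trace(self.U, axis1=1, axis2=2) / 3


def adps_from_tls(crystal, vcov):
    """Project the self covariance of each group onto atomic ADPs.

    ``U_j = A_j <w w^T> A_j^T``; an atom sitting exactly at the group origin
    gets ``U = T``.
    """
    Us = []
    gi = []
    for k, g in enumerate(crystal.groups):
        W = vcov.group_pair((0, 0, 0), k, k)
        A = _group_projections(g)
        Us.append(np.einsum("jab,bc,jdc->jad", A, W, A))
        gi.append(np.full(g.n_atoms, k))
    return AtomicADP(U=np.concatenate(Us), group_index=np.concatenate(gi))


def com_joint_adps(vcov, offsets=None):
    """Symmetrized center-of-mass displacement covariances (joint-ADPs).

    For groups kappa, kappa' in cells separated by offset n, the projection
    ``A(0)`` selects the translational 3x3 sub-block of the generalized
    covariance; the joint-ADP is the symmetrized combination
    ``V = (U + U'^T)/2``.

    Returns a dict ``{(offset, kappa, kappa'): V}`` over all group pairs and
    the requested offsets (default: all distinct supercell offsets).
    """
    if offsets is None:
        offsets = vcov.offsets()
    K = vcov.n_groups
    out = {}
    for n in offsets:
        b = vcov.block(n)
        for ka in range(K):
            for kb in range(K):
                U = b[6 * ka:6 * ka + 3, 6 * kb:6 * kb + 3]
                out[(tuple(n), ka, kb)] = 0.5 * (U + U.T)
    return out
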