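import numpy as np
import pytest

from latticevibes.diffuse_sim import (
    density_from_amplitudes,
    density_from_model,
    group_transforms,
    molecular_transform,
    one_phonon_intensity,
    one_phonon_sf,
    partition_density,
    simulate_halo_map,
)
from latticevibes.formfactors import evaluate as ff_evaluate, n_electrons
from latticevibes.lattice_dynamics import covariance_kernel
from latticevibes.synthetic_fixtures import (
    atomic_form_factors,
    make_toy_crystal,
    mc_sample_diffuse,
)


class TestDensity:
    def test_single_atom_integrates_to_Z(self):
        from latticevibes.crystal_model import (RigidGroup, RigidGroupCrystal,
                                                UnitCellGeometry)
        geom = UnitCellGeometry(14, 14, 14)
        g = RigidGroup(
            elements=np.array(["C", "C"], dtype=object),
            xyz=np.array([[7.0, 7.0, 7.0], [7.0, 7.0, 9.0]]),
            occupancies=np.ones(2), b_iso=np.full(2, 10.0),
            residue_ids=np.array([1, 1]))
        crystal = RigidGroupCrystal(geom, [g])
        cd = density_from_model(crystal, spacing=0.25, subtract_solvent=False)
        assert np.isclose(cd.total_electrons(), 2 * n_electrons("C"), rtol=0.01)

    def test_solvent_subtraction_zeroes_constant(self, p1_toy):
        net, _ = p1_toy
        cd = density_from_model(net.crystal, spacing=0.4,
                                subtract_solvent=False)
        offset = 0.37
        cd.rho += offset
        # constant subtraction recovers: mean in region far from atoms
        from latticevibes.diffuse_sim import _solvent_mask
        xyz, _ = net.crystal.all_atoms()
        mask = _solvent_mask(net.crystal.geometry, cd.shape, xyz, 3.0)
        if np.any(mask):
            cd2_rho = cd.rho - cd.rho[mask].mean()
            # far-from-atom region is now ~zero
            assert abs(cd2_rho[mask].mean()) < 1e-10

    def test_fourier_synthesis_round_trip(self, p1_toy):
        """Density -> amplitudes/phases -> Fourier synthesis -> density."""
        net, _ = p1_toy
        geom = net.crystal.geometry
        # odd grid: every frequency has a distinct Friedel mate
        cd = density_from_model(net.crystal, spacing=0.5, shape=(21, 21, 23),
                                subtract_solvent=False)
        F = np.fft.ifftn(cd.rho) * geom.volume
        shape = cd.shape
        hs, amps, phases = [], [], []
        for h1 in range(-(shape[0] - 1) // 2, (shape[0] - 1) // 2 + 1):
            for h2 in range(-(shape[1] - 1) // 2, (shape[1] - 1) // 2 + 1):
                for h3 in range(-(shape[2] - 1) // 2, (shape[2] - 1) // 2 + 1):
                    if (h1, h2, h3) <= (0, 0, 0):
                        continue  # one hemisphere; Friedel mates generated
                    val = F[h1 % shape[0], h2 % shape[1], h3 % shape[2]]
                    hs.append((h1, h2, h3))
                    amps.append(abs(val))
                    phases.append(np.angle(val))
        cd2 = density_from_amplitudes(geom, np.array(hs), amps, phases, shape)
        # round trip up to the constant (F000) term
        diff = (cd.rho - cd.rho.mean()) - (cd2.rho - cd2.rho.mean())
        assert np.abs(diff).max() < 1e-8 * np.abs(cd.rho).max()


class TestPartitionDensity:
    def test_soft_masks_sum_to_one(self, screw_toy):
        net, _ = screw_toy
        cd = density_from_model(net.crystal, spacing=0.5)
        gds = partition_density(cd, net.crystal, blur_b=30.0)
        # total group density equals cell density (masks partition unity)
        total = np.zeros(cd.shape)
        for gd in gds:
            # scatter the cropped box back into the cell grid
            n = np.array(cd.shape)
            idx = [np.arange(gd.origin_index[i],
                             gd.origin_index[i] + gd.rho.shape[i]) % n[i]
                   for i in range(3)]
            total[np.ix_(*idx)] += gd.rho
        assert np.allclose(total, cd.rho, atol=1e-6 * np.abs(cd.rho).max())

    def test_blur_zero_recovers_hard_partition(self, screw_toy):
        net, _ = screw_toy
        cd = density_from_model(net.crystal, spacing=0.5)
        gds = partition_density(cd, net.crystal, blur_b=0.0)
        for gd in gds:
            n = np.array(cd.shape)
            idx = [np.arange(gd.origin_index[i],
                             gd.origin_index[i] + gd.rho.shape[i]) % n[i]
                   for i in range(3)]
            box = cd.rho[np.ix_(*idx)]
            # hard partition: group density is either ~0 or the full density
            frac = gd.rho / np.where(np.abs(box) > 1e-12, box, 1.0)
            frac = frac[np.abs(box) > 1e-6 * np.abs(cd.rho).max()]
            assert np.all((np.abs(frac) < 1e-6) | (np.abs(frac - 1) < 1e-6))

    def test_moment_grids_consistent(self, p1_density_setup):
        net, params, cd, _ = p1_density_setup
        gds = partition_density(cd, net.crystal, blur_b=0.0)
        gd = gds[0]
        # moments / rho = coordinates relative to origin, where rho != 0
        sel = np.abs(gd.rho) > 1e-3 * np.abs(gd.rho).max()
        for c in range(3):
            coords = gd.moments[c][sel] / gd.rho[sel]
            assert np.all(np.isfinite(coords))
            assert coords.max() < 60.0  # bounded by the box


class TestMolecularTransform:
    def test_F0_equals_total_electrons(self, p1_density_setup):
        net, _, cd, tfs = p1_density_setup
        F = tfs[0][0]
        assert np.isclose(F(np.zeros((1, 3)))[0].real, cd.total_electrons(),
                          rtol=1e-6)

    def test_interpolation_vs_direct_dft(self, p1_density_setup, rng):
        net, _, cd, _ = p1_density_setup
        geom = net.crystal.geometry
        gds = partition_density(cd, net.crystal, blur_b=0.0)
        gd = gds[0]
        F, _ = molecular_transform(gd, oversample=4)
        n = np.array(gd.cell_shape)
        G = geom.orth / n[None, :]
        mesh = np.stack(np.meshgrid(
            *[np.arange(gd.origin_index[i], gd.origin_index[i] + gd.rho.shape[i])
              for i in range(3)], indexing="ij"), axis=-1)
        r = mesh @ G.T
        dv = geom.volume / np.prod(n)
        q = geom.q_cartesian(rng.uniform(-3, 3, size=(50, 3)))
        Fd = np.array([(gd.rho * np.exp(1j * (r @ qq))).sum() * dv for qq in q])
        Fi = F(q)
        assert np.abs(Fi - Fd).max() / np.abs(Fd).max() < 1e-3

    def test_point_mass_constant_modulus(self):
        from latticevibes.crystal_model import UnitCellGeometry
        from latticevibes.diffuse_sim import MolecularTransform
        rho = np.zeros((16, 16, 16))
        rho[5, 6, 7] = 1.0
        G = np.eye(3) * 0.5
        mt = MolecularTransform(rho, G, np.zeros(3), 1.0, oversample=4)
        q = np.random.default_rng(0).uniform(-2, 2, (20, 3))
        F = mt(q)
        assert np.allclose(np.abs(F), 1.0, atol=1e-3)
        # phase linear in q: phase = q . r_point
        r_point = G @ np.array([5, 6, 7])
        assert np.allclose(np.angle(F * np.exp(-1j * q @ r_point)), 0.0,
                           atol=1e-2)

    def test_nyquist_rejection(self, p1_density_setup):
        net, _, _, tfs = p1_density_setup
        geom = net.crystal.geometry
        qbig = np.array([[2 * np.pi / 0.3 * 0.7, 0.0, 0.0]])
        with pytest.raises(ValueError, match="Nyquist"):
            tfs[0][0](qbig)


class TestOnePhononSF:
    def test_zero_q(self, p1_density_setup):
        net, _, _, tfs = p1_density_setup
        G = one_phonon_sf(tfs, None, np.zeros((1, 3)))
        assert np.allclose(G, 0.0, atol=1e-10)

    def test_six_components_per_group(self, p1_density_setup, screw_toy):
        net, _, _, tfs = p1_density_setup
        G = one_phonon_sf(tfs, None, np.array([[0.5, 0.4, 0.3]]))
        assert G.shape == (1, 6 * net.crystal.n_groups)

    def test_matches_atom_sum(self, p1_density_setup, rng):
        net, _, _, tfs = p1_density_setup
        geom = net.crystal.geometry
        g0 = net.crystal.groups[0]
        q = geom.q_cartesian(rng.uniform(-3, 3, size=(20, 3)))
        G = one_phonon_sf(tfs, None, q)
        ff = atomic_form_factors(g0, q)
        ph = np.exp(1j * g0.xyz @ q.T)
        F = (ff * ph).sum(axis=0)
        Gt = q * F[:, None]
        x = g0.xyz - g0.origin
        M = np.einsum("ja,jq,jq->qa", x, ff, ph)
        Gr = -np.cross(q, M)
        oracle = np.concatenate([Gt, Gr], axis=1)
        assert np.abs(G - oracle).max() / np.abs(oracle).max() < 5e-3


class TestOnePhononIntensity:
    def test_non_negative(self, p1_density_setup, rng):
        net, params, _, tfs = p1_density_setup
        for _ in range(20):
            h = rng.integers(-3, 4, size=3).astype(float)
            k = rng.integers(-1, 2, size=3) / 3.0
            I = one_phonon_intensity(net, params, tfs, h, k)
            assert I >= -1e-10

    def test_matches_monte_carlo(self, p1_density_setup):
        """One-phonon intensity equals the harmonic-ensemble average in the
        small-displacement limit (stochastic oracle)."""
        net, params, _, tfs = p1_density_setup
        geom = net.crystal.geometry
        hlist = np.array([[1.0, 0, 0], [1, 1, 0], [2, 1, 1], [0, 2, 1]])
        ks = np.array([[0.5, 0, 0], [0, 0.5, 0.5], [0.5, 0.5, 0.5],
                       [0.5, 0, 0.5]])
        I1 = np.array([one_phonon_intensity(net, params, tfs, h, k)
                       for h, k in zip(hlist, ks)])
        amp = 0.05
        q = geom.q_cartesian(hlist - ks)
        Imc = mc_sample_diffuse(net, params, (2, 2, 2), q, n_samples=4000,
                                amplitude_scale=amp, seed=3)
        assert np.allclose(Imc / amp**2, I1, rtol=0.08)

    def test_kT_linearity(self, p1_density_setup):
        net, params, _, tfs = p1_density_setup
        h, k = np.array([1.0, 1, 0]), np.array([0.5, 0, 0])
        I1 = one_phonon_intensity(net, params, tfs, h, k, kT=1.0)
        I2 = one_phonon_intensity(net, params, tfs, h, k, kT=2.0)
        assert np.isclose(I2, 2 * I1)

    def test_unstable_network_rejected(self, p1_density_setup):
        net, params, _, tfs = p1_density_setup
        bad = type(params)(level=params.level, n_groups=params.n_groups)
        with pytest.raises(ValueError):
            one_phonon_intensity(net, bad, tfs, [1.0, 0, 0], [0.5, 0, 0])


class TestSimulateHaloMap:
    @pytest.fixture(scope="class")
    @staticmethod
    def halo_map(p1_density_setup):
        net, params, cd, tfs = p1_density_setup
        return simulate_halo_map(net, params, (4, 4, 4), (3, 3, 3),
                                 transforms=tfs)

    def test_satellites_match_pointwise(self, p1_density_setup, halo_map):
        net, params, _, tfs = p1_density_setup
        for h, dk in [((2, 0, 0), (1 / 3, 0, 0)), ((1, 2, 0), (0, -1 / 3, 1 / 3)),
                      ((0, 0, 3), (-1 / 3, 0, 0))]:
            hf = np.add(h, dk)
            expected = one_phonon_intensity(net, params, tfs, np.array(h, float),
                                            -np.asarray(dk))
            got = halo_map.data[halo_map.index_of(hf)]
            assert np.isclose(got, expected, rtol=1e-10)

    def test_halos_decay_from_rlps(self, p1_density_setup):
        # acoustic divergence: along one phonon branch the satellite closer
        # to the RLP (|k| = 1/5) outshines the farther one (|k| = 2/5)
        net, params, _, tfs = p1_density_setup
        vmap = simulate_halo_map(net, params, (3, 3, 3), (5, 1, 1),
                                 transforms=tfs)
        near = far = 0.0
        for h1 in range(-2, 3):
            for h2 in range(-2, 3):
                for h3 in range(-2, 3):
                    if h1 == h2 == h3 == 0:
                        continue
                    near += vmap.data[vmap.index_of((h1 + 1 / 5, h2, h3))]
                    far += vmap.data[vmap.index_of((h1 + 2 / 5, h2, h3))]
        assert near > far

    def test_laue_symmetry(self, halo_map):
        # P1 toy: Friedel symmetry I(h) = I(-h)
        d = halo_map.data
        assert np.allclose(d, d[::-1, ::-1, ::-1], rtol=1e-8, atol=1e-12)

    def test_kT_scaling(self, p1_density_setup):
        net, params, _, tfs = p1_density_setup
        m1 = simulate_halo_map(net, params, (2, 2, 2), (3, 3, 3),
                               transforms=tfs, kT=1.0)
        m2 = simulate_halo_map(net, params, (2, 2, 2), (3, 3, 3),
                               transforms=tfs, kT=2.0)
        assert np.allclose(m2.data, 2 * m1.data)
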