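import numpy as np
import pytest

from latticevibes.synthetic_fixtures import make_toy_crystal


# function-scoped: several operations (spring grouping, refinement) tag the
# contact list in place, so each test gets a fresh crystal
@pytest.fixture()
def p1_toy():
    """Small deterministic P1 toy crystal with a Gaussian spring network."""
    return make_toy_crystal(space_group="P 1", seed=1)


@pytest.fixture()
def screw_toy():
    """Orthorhombic 2_1-screw toy crystal (four symmetry-related bodies,
    three unique protein-protein interface classes)."""
    return make_toy_crystal(space_group="P 21 21 21", seed=1, n_atoms=13,
                            body_radius=3.0, contact_cutoff=3.8)


@pytest.fixture(scope="session")
def p1_density_setup():
    """P1 toy with unit-cell density and molecular transforms (shared)."""
    from latticevibes.diffuse_sim import density_from_model, group_transforms
    net, params = make_toy_crystal(space_group="P 1", seed=2)
    cd = density_from_model(net.crystal, spacing=0.3, subtract_solvent=False)
    tfs = group_transforms(net.crystal, cell_density=cd, blur_b=0.0,
                           oversample=4)
    return net, params, cd, tfs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
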