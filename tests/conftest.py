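import numpy as np
import pytest

from coilreg import ccgeom, rdc, synthetic
from coilreg.structure_io import amide_vectors


@pytest.fixture(scope="session")
def ideal_dimer():
    """Canonical parallel dimer, 76 residues per chain (70+ interior)."""
    return synthetic.generate_coiled_coil(synthetic.CrickParameters(n_res=76))


@pytest.fixture(scope="session")
def ideal_profile(ideal_dimer):
    fa = ccgeom.local_helix_frames(ideal_dimer.chain("A"))
    fb = ccgeom.local_helix_frames(ideal_dimer.chain("B"))
    return ccgeom.coiled_coil_profile(fa, fb)


@pytest.fixture(scope="session")
def irregular_template():
    """80-residue dimer with 0.3 A coordinate noise: a realistic template
    whose natural irregularity breaks the one-heptad offset degeneracy."""
    return synthetic.generate_coiled_coil(
        synthetic.CrickParameters(n_res=80),
        synthetic.DistortionSpec(noise_sd=0.3), seed=7)


@pytest.fixture(scope="session")
def template_vectors(irregular_template):
    return {v.residue_number: v.vector
            for v in amide_vectors(irregular_template, ["A"])}


@pytest.fixture(scope="session")
def planted_tensor():
    return rdc.AlignmentTensor.from_parameters(10.0, 0.3, (30.0, 50.0, 70.0))


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
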