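import numpy as np
import pytest

import enmsampler as es


@pytest.fixture(scope="session")
def helix():
    return es.make_toy(es.ToySpec(n_residues=12, geometry="helix"))


@pytest.fixture(scope="session")
def two_domain():
    return es.make_toy(es.ToySpec(n_residues=40, geometry="two_domain", linker_length=4))


@pytest.fixture(scope="session")
def helix_modes(helix):
    return es.compute_anm_modes(helix)


@pytest.fixture(scope="session")
def helix_ca(helix):
    return es.select(helix, "calpha")


@pytest.fixture(scope="session")
def helix_conformers(helix, helix_modes, helix_ca):
    """Small deformed ensemble of the helix toy, deterministic."""
    return es.generate_conformers(
        helix.coords, helix_modes, helix_ca,
        es.SamplingParams(n_confs=8, target_rmsd=1.2, seed=42),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation matrix from a seeded generator."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
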