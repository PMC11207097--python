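import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fuzzyens as fz

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fjc_medium() -> fz.Ensemble:
    """60-residue freely jointed chain, 4000 independent frames."""
    return fz.generate_fjc(fz.ChainSpec(n_residues=60, seed=101), 4000)


@pytest.fixture(scope="session")
def mc_ideal() -> fz.Ensemble:
    """Ideal-limit Monte Carlo chain (no core, no well)."""
    spec = fz.ChainSpec(n_residues=40, sweeps=6, seed=202)
    return fz.generate_solvent_chain(spec, 200)


@pytest.fixture(scope="session")
def two_domain_small() -> fz.Ensemble:
    """30-residue flexible tail + 40-bead rigid domain, 120 frames."""
    template = fz.make_domain_template(n_residues=40, radius=1.2, seed=7)
    spec = fz.ChainSpec(n_residues=30, sweeps=6, seed=8)
    return fz.generate_two_domain(30, template, spec, 120)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
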