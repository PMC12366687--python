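import numpy as np
import pytest

import spcryolm as sp


@pytest.fixture(scope="session")
def template_bank():
    return sp.build_template_bank()


@pytest.fixture(scope="session")
def standard_dataset():
    """Population at the defaults: 378 particles, sides 9/19/34, weights 21/51/28."""
    return sp.simulate_dataset(378, seed=2024)


@pytest.fixture(scope="session")
def standard_particles(standard_dataset):
    return sp.localize_known_fluorophores(standard_dataset.events)


def separated_azimuths(rng, n=3, lo=5.0, hi=85.0, gap=15.0):
    """Dipole azimuths with pairwise separation >= gap on the cos^2-identifiable
    range [0, 90] (theta and 180-theta give identical polarization)."""
    while True:
        az = np.sort(rng.uniform(lo, hi, n))
        if np.all(np.diff(az) >= gap):
            return az


def exact_particle(pid, side, yaw, pitch, roll, precision=1.4, n_loc=55):
    """Noise-free particle: fluorophores at the exact projected vertices."""
    gt = sp.GroundTruthParticle(pid, "ii", side, (yaw, pitch, roll), (0.0, 0.0, 0.0))
    pts = sp.project_particle(gt)
    s = precision * np.sqrt(n_loc)
    fluors = tuple(
        sp.LocalizedFluorophore(x, y, s, s, n_loc, precision) for x, y in pts
    )
    return sp.ParticleProjection(pid, fluors)
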