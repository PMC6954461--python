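import numpy as np
import pytest

from petdose import load_nuclide, load_tissue_weights
from petdose.nucdata_phantoms import Phantom, SMatrix


@pytest.fixture(scope="session")
def ga68():
    return load_nuclide()


@pytest.fixture(scope="session")
def icrp60():
    return load_tissue_weights()


def make_toy_phantom(rng: np.random.Generator, n_organs: int = 3) -> Phantom:
    """Random small phantom with a consistent S-matrix for algebra tests."""
    organs = [f"organ_{i}" for i in range(n_organs)]
    masses = {o: float(rng.uniform(50, 2000)) for o in organs}
    total = sum(masses.values()) * float(rng.uniform(1.5, 4.0))
    m_rob = total - sum(masses.values())
    entries = {}
    for target in organs:
        for source in organs:
            base = rng.uniform(0.2, 1.0) if target == source else rng.uniform(0.0, 0.05)
            entries[(target, source)] = float(base)
        # total-body row assembled from the organ rows plus a remainder term,
        # so the mass-correction algebra is exactly consistent (no clamping)
        s_rob = float(rng.uniform(0.0, 0.1))
        entries[(target, "total_body")] = (
            sum(entries[(target, s)] * masses[s] for s in organs) + s_rob * m_rob) / total
    return Phantom("toy", masses, total, SMatrix(entries, "toy"))


@pytest.fixture
def toy_phantom():
    return make_toy_phantom(np.random.default_rng(123))
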