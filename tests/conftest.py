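import numpy as np
import pytest

from shapedock import DescriptorConfig, Molecule
from shapedock.fixtures import FixtureSpec, make_molecule


@pytest.fixture(scope="session")
def coarse_config() -> DescriptorConfig:
    """Default descriptor settings used across tests."""
    return DescriptorConfig(spacing=0.3)


@pytest.fixture()
def single_carbon() -> Molecule:
    return Molecule("c", ("C",), np.zeros((1, 3)))


@pytest.fixture()
def cloud_molecule() -> Molecule:
    """A 20-atom random cloud with coordinates rounded to 1e-3 A, so every
    supported file format can represent it exactly."""
    mol = make_molecule(FixtureSpec(seed=42, kind="random_cloud", n_atoms=20))
    return Molecule(mol.name, mol.symbols, np.round(mol.coords, 3), mol.bonds)


def brute_force_moments(points: np.ndarray, h: float):
    """Independent plain-Python moment oracle over voxel centers (orders <= 3)."""
    m = np.full((4, 4, 4), np.nan)
    for p in range(4):
        for q in range(4 - p):
            for r in range(4 - p - q):
                total = 0.0
                for x, y, z in points:
                    total += (x ** p) * (y ** q) * (z ** r)
                m[p, q, r] = h ** 3 * total
    return m
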