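import math

import numpy as np
import pytest

from shapedock import (C3DDVector, DescriptorConfig, Molecule, c3dd, compactness,
                       compute_moments, hu_invariants, measure, voxelize)
from shapedock.elements import BONDI, VdwRadiusTable
from shapedock.errors import DegenerateShapeError
from shapedock.fixtures import (FixtureSpec, make_asymmetric_molecule,
                                make_molecule, random_rotation)
from shapedock.shape_grid import ShapeGrid

from conftest import brute_force_moments


def _grid_from_points(ijk: np.ndarray, h: float = 1.0, origin=(0.0, 0.0, 0.0)) -> ShapeGrid:
    ijk = np.asarray(ijk, int)
    dims = ijk.max(axis=0) + 2
    occ = np.zeros(tuple(dims), bool)
    occ[tuple(ijk.T)] = True
    return ShapeGrid(origin=origin, spacing=h, occupancy=occ)


def test_single_voxel_point_mass():
    grid = _grid_from_points([[1, 2, 3]])
    ms = compute_moments(grid)
    assert ms.centroid == (1.0, 2.0, 3.0)
    mu = ms.mu
    for p in range(4):
        for q in range(4 - p):
            for r in range(4 - p - q):
                if p + q + r >= 1:
                    assert mu[p, q, r] == pytest.approx(0.0, abs=1e-12)


def test_two_voxel_hand_arithmetic():
    ms = compute_moments(_grid_from_points([[0, 0, 0], [2, 0, 0]]))
    assert ms.centroid == (1.0, 0.0, 0.0)
    assert ms.mu[2, 0, 0] == pytest.approx(2.0)
    assert ms.m[0, 0, 0] == pytest.approx(2.0)  # volume = 2 voxels at h = 1


def test_moments_match_brute_force_oracle():
    rng = np.random.default_rng(11)
    ijk = rng.integers(0, 8, size=(50, 3))
    ijk = np.unique(ijk, axis=0)
    h = 0.5
    grid = _grid_from_points(ijk, h=h, origin=(-1.0, 0.5, 2.0))
    ms = compute_moments(grid)
    pts = grid.occupied_centers()
    m_ref = brute_force_moments(pts, h)
    mu_ref = brute_force_moments(pts - pts.mean(axis=0), h)
    for p in range(4):
        for q in range(4 - p):
            for r in range(4 - p - q):
                assert ms.m[p, q, r] == pytest.approx(m_ref[p, q, r], rel=1e-10, abs=1e-12)
                assert ms.mu[p, q, r] == pytest.approx(mu_ref[p, q, r], rel=1e-10, abs=1e-10)


def test_ball_tau1_closed_form():
    """mu2 diagonal of a ball is (4/15) pi r^5, so tau1 = (4/5) pi r^5."""
    radius = 1.7
    mol = Molecule("c", ("C",), np.zeros((1, 3)))
    ms = compute_moments(voxelize(mol, spacing=radius / 10))
    tau = hu_invariants(ms)
    tau1_true = 4.0 / 5.0 * math.pi * radius ** 5
    assert abs(tau[0] - tau1_true) / tau1_true < 0.02
    for off_diag in (ms.mu[1, 1, 0], ms.mu[1, 0, 1], ms.mu[0, 1, 1]):
        assert abs(off_diag) < 0.02 * tau1_true


def test_rotation_invariance_of_hu_set(coarse_config):
    mol = make_asymmetric_molecule(seed=3)
    v0 = c3dd(mol, coarse_config).values
    rng = np.random.default_rng(7)
    for _ in range(5):
        moved = mol.transformed(random_rotation(rng), rng.uniform(-10, 10, 3))
        v = c3dd(moved, coarse_config).values
        assert np.all(np.abs(v - v0) / np.abs(v0) < 0.03)


def test_mirror_symmetric_shape_has_vanishing_tau4():
    sym = Molecule("dimer", ("C", "C"), np.array([[-2.0, 0, 0], [2.0, 0, 0]]))
    grid = voxelize(sym, 0.2)
    ms = compute_moments(grid)
    tau4 = hu_invariants(ms)[3]
    # compare against the natural scale mu2^(12/5) ~ tau1^(12/5)
    scale = hu_invariants(ms)[0] ** (12.0 / 5.0)
    assert tau4 < 1e-4 * scale


def test_eq5_variants_differ_by_the_squared_cross_moment():
    mol = make_asymmetric_molecule(seed=1)
    ms = compute_moments(voxelize(mol, 0.3))
    tau2_std = hu_invariants(ms, eq5_variant="standard")[1]
    tau2_printed = hu_invariants(ms, eq5_variant="printed")[1]
    # the printed final term mu_001^2 is identically zero for central moments
    assert tau2_printed - tau2_std == pytest.approx(ms.mu[0, 1, 1] ** 2, rel=1e-12)


def test_scale_normalized_invariants_are_dimensionless():
    mol = make_asymmetric_molecule(seed=2)
    ms = compute_moments(voxelize(mol, 0.3))
    tau_raw = hu_invariants(ms)
    tau_norm = hu_invariants(ms, scale_normalized=True)
    v = ms.m[0, 0, 0]
    assert tau_norm[0] == pytest.approx(tau_raw[0] / v ** (5.0 / 3.0), rel=1e-12)


def test_ball_compactness_near_one(single_carbon):
    grid = voxelize(single_carbon, 0.2)
    ks = compactness(compute_moments(grid), measure(grid), grid)
    for k in ks:
        assert 0.95 <= k <= 1.0


def test_cube_isoperimetric_ratio():
    h, n = 0.25, 16
    occ = np.zeros((n + 8, n + 8, n + 8), bool)
    occ[4:4 + n, 4:4 + n, 4:4 + n] = True
    grid = ShapeGrid(origin=(0.0, 0.0, 0.0), spacing=h, occupancy=occ)
    ks = compactness(compute_moments(grid), measure(grid), grid)
    assert ks[1] == pytest.approx(math.pi / 6.0, rel=0.05)


def test_elongation_decreases_compactness(single_carbon, coarse_config):
    rod = make_molecule(FixtureSpec(kind="chain", n_atoms=23))  # ~20:1 aspect
    rod_grid = voxelize(rod, 0.3)
    rod_k = compactness(compute_moments(rod_grid), measure(rod_grid), rod_grid)
    ball_grid = voxelize(single_carbon, 0.3)
    ball_k = compactness(compute_moments(ball_grid), measure(ball_grid), ball_grid)
    assert rod_k[0] < 0.5 and rod_k[1] < 0.5
    assert rod_k[0] < ball_k[0] and rod_k[1] < ball_k[1]


def test_single_voxel_compactness_is_degenerate():
    grid = _grid_from_points([[1, 1, 1]])
    ms = compute_moments(grid)
    with pytest.raises(DegenerateShapeError):
        compactness(ms, measure(grid), grid)


def test_c3dd_is_deterministic_and_composes(cloud_molecule, coarse_config):
    v1 = c3dd(cloud_molecule, coarse_config)
    v2 = c3dd(cloud_molecule, coarse_config)
    assert np.array_equal(v1.values, v2.values)  # bitwise
    grid = voxelize(cloud_molecule, coarse_config.spacing, coarse_config.radii)
    meas = measure(grid)
    ms = compute_moments(grid)
    tau = hu_invariants(ms, coarse_config.eq5_variant, coarse_config.scale_normalized)
    ks = compactness(ms, meas, grid)
    manual = np.array([*tau, *ks, meas.S, meas.V, meas.R])
    assert np.array_equal(v1.values, manual)


def test_c3dd_translation_invariance(cloud_molecule, coarse_config):
    v0 = c3dd(cloud_molecule, coarse_config).values
    v1 = c3dd(cloud_molecule.translated((10.0, -3.0, 7.0)), coarse_config).values
    assert np.all(np.abs(v1 - v0) / np.abs(v0) < 0.02)


def test_dimensional_consistency_under_scaling(coarse_config):
    s = 1.5
    mol = make_molecule(FixtureSpec(seed=9, kind="random_cloud", n_atoms=10))
    scaled = Molecule(mol.name, mol.symbols, mol.coords * s)
    table = VdwRadiusTable(radii={e: r * s for e, r in BONDI.radii.items()},
                           label="scaled")
    v0 = c3dd(mol, DescriptorConfig(spacing=0.3)).values
    v1 = c3dd(scaled, DescriptorConfig(spacing=0.3 * s, radii=table)).values
    names_scale = {"volume": s ** 3, "surface_area": s ** 2, "tau1": s ** 5,
                   "kappa": 1.0, "kappa_st": 1.0, "kappa_fit": 1.0}
    from shapedock import COMPONENT_NAMES
    for name, factor in names_scale.items():
        i = COMPONENT_NAMES.index(name)
        assert v1[i] == pytest.approx(v0[i] * factor, rel=0.03)


def test_vector_validation():
    with pytest.raises(ValueError):
        C3DDVector(values=np.ones(9))
    with pytest.raises(ValueError):
        C3DDVector(values=np.array([np.inf] + [1.0] * 9))
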