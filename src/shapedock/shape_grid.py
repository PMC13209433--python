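"""Voxelization of the van der Waals solid and its shape measures.

A molecule is realized as the union of atom-centered vdW spheres. The solid is
sampled on a cubic grid: a voxel is occupied iff its *center* lies inside at
least one sphere (an unbiased volume estimator). Volume is occupied-voxel
counting; surface area comes from a marching-cubes triangulation of the signed
distance field

    phi(x) = min_i ( |x - c_i| - r_i ),

whose zero level set is the exact boundary of the union solid, so the measured
area converges to the true vdW surface as the spacing shrinks. Raw
boundary-face counting is deliberately avoided: it overestimates a sphere's
area by ~50% and would corrupt the isoperimetric compactness, whose sphere
limit must be 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure

from .elements import BONDI, VdwRadiusTable
from .errors import DegenerateGridError
from .structure_io import Molecule

DEFAULT_SPACING = 0.3  # Angstrom; <2% sphere error at tractable cost


@dataclass(frozen=True)
class ShapeGrid:
    """Cubic voxelization of a molecular solid.

    ``origin`` is the center of voxel (0,0,0); voxel (i,j,k) has center
    ``origin + h*(i,j,k)``. ``sdf`` (same shape as ``occupancy``) holds the
    signed distance to the union-of-spheres boundary, clipped far from the
    surface; it is ``None`` for grids injected directly as occupancy masks.
    """

    origin: tuple[float, float, float]
    spacing: float
    occupancy: np.ndarray
    sdf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 3 or min(occ.shape) < 1:
            raise ValueError("occupancy must be a non-empty 3D boolean field")
        object.__setattr__(self, "occupancy", occ)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def occupied_centers(self) -> np.ndarray:
        """Cartesian centers of occupied voxels, shape (n_occupied, 3), Angstrom."""
        idx = np.argwhere(self.occupancy)
        return np.asarray(self.origin, float) + self.spacing * idx


@dataclass(frozen=True)
class ShapeMeasures:
    """Volume, surface area, their ratio, and the occupied-voxel point cloud."""

    V: float          # A^3, exactly n_occupied * h^3
    S: float          # A^2, triangulated isosurface area
    R: float          # 1/A, S / V
    point_cloud: np.ndarray


def voxelize(molecule: Molecule, spacing: float = DEFAULT_SPACING,
             radii: VdwRadiusTable = BONDI) -> ShapeGrid:
    """Sample the union-of-vdW-spheres solid of ``molecule`` on a cubic grid.

    The grid box covers every atom sphere with a margin of
    ``max vdW radius + 2*spacing`` on all faces, guaranteeing a closed
    isosurface boundary.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    molecule.validate_elements(radii)
    h = float(spacing)
    coords = molecule.coords
    atom_radii = np.array([radii.radius(s) for s in molecule.symbols])

    margin = radii.max_radius + 2.0 * h
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    # Anchor the lattice to the atom-coordinate centroid with a quarter-voxel
    # offset: the grid translates rigidly with the molecule (so V and S are
    # exactly translation invariant) and the offset desynchronizes sphere
    # boundaries from lattice planes, damping the coherent voxel-count
    # oscillations that plague phase-aligned sampling of curved solids.
    anchor = coords.mean(axis=0)
    origin_vec = anchor + h * (np.floor((lo - anchor) / h) + 0.25)
    dims = np.ceil((hi - origin_vec) / h).astype(int) + 1
    origin = tuple(float(v) for v in origin_vec)

    # Signed distance field, computed per atom over a local sub-box and
    # min-reduced; clipped at +3h far from every sphere (sign-exact there).
    cap = 3.0 * h
    sdf = np.full(tuple(dims), cap, dtype=np.float64)
    axes = [origin_vec[d] + h * np.arange(dims[d]) for d in range(3)]
    for center, r in zip(coords, atom_radii):
        reach = r + cap
        i0 = np.maximum(np.floor((center - reach - origin_vec) / h).astype(int), 0)
        i1 = np.minimum(np.ceil((center + reach - origin_vec) / h).astype(int) + 1, dims)
        if np.any(i0 >= i1):
            continue
        dx = axes[0][i0[0]:i1[0]] - center[0]
        dy = axes[1][i0[1]:i1[1]] - center[1]
        dz = axes[2][i0[2]:i1[2]] - center[2]
        dist = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        sub = sdf[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(sub, dist - r, out=sub)
    np.minimum(sdf, cap, out=sdf)

    occupancy = sdf <= 0.0
    if not occupancy.any():
        raise DegenerateGridError(
            f"spacing {h} A produced zero occupied voxels for '{molecule.name}'"
        )
    return ShapeGrid(origin=origin, spacing=h, occupancy=occupancy, sdf=sdf)


def measure(grid: ShapeGrid) -> ShapeMeasures:
    """Measure volume, surface area, S/V ratio and the occupied point cloud.

    V is exactly ``h^3 * n_occupied``. S triangulates the zero level set of
    the stored signed distance field, whose surface is the smooth boundary of
    the union-of-spheres solid. A grid injected directly as an occupancy mask
    (no distance field) represents a union of voxel cubes, and its exact
    boundary is the set of exposed axis-aligned faces, so S = h^2 times the
    exposed-face count — exact for the solid the mask denotes.
    """
    if grid.n_occupied == 0:
        raise DegenerateGridError("cannot measure an empty grid")
    h = grid.spacing
    V = grid.n_occupied * h ** 3

    if grid.sdf is not None:
        verts, faces, _, _ = _skmeasure.marching_cubes(grid.sdf, level=0.0,
                                                       spacing=(h, h, h))
        S = float(_skmeasure.mesh_surface_area(verts, faces))
    else:
        S = h ** 2 * _exposed_face_count(grid.occupancy)
    return ShapeMeasures(V=float(V), S=S, R=S / V, point_cloud=grid.occupied_centers())


def _exposed_face_count(occ: np.ndarray) -> int:
    padded = np.pad(occ, 1, constant_values=False)
    count = 0
    for axis in range(3):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        count += int(np.abs(diff).sum())
    return count


def export_point_cloud(measures: ShapeMeasures, path) -> None:
    """Write occupied voxel centers as XYZ-like text (one center per line)."""
    with open(path, "w") as fh:
        for x, y, z in measures.point_cloud:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
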