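"""Deterministic synthetic inputs: molecules, screens, libraries, mock engine.

Everything the pipeline consumes can be generated here from a seed, so the
full system — descriptor computation, library build, similarity search,
reverse docking, ranking, evaluation — runs end to end with no downloads.

Screens model the benchmark construction geometrically: "actives" are
shape-perturbed copies of a seed molecule (same 3D shape up to noise,
scaffold chemistry being irrelevant to a pure shape descriptor), while
"decoys" are independent random atom clouds with matched atom counts, so they
overlap the actives in size but not in shape.

The mock docking engine returns a deterministic score in [-12, -1] kcal/mol —
the magnitude range of realistic binding scores — as a pure function of
(receptor identity, query heavy-atom count, seed), so native self-docking
reproduces ScoreB exactly and DetScore = 0.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .docking import BoxSpec, EngineOutcome
from .errors import GenerationError
from .similarity import ComplexSpec
from .structure_io import Molecule, write_molecule

CHAIN_SPACING = 1.5       # A between consecutive heavy atoms
MIN_CLOUD_DISTANCE = 1.2  # A minimum inter-atom distance in random clouds


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic molecule. Same spec => identical output."""

    seed: int = 0
    kind: str = "random_cloud"  # single_atom | chain | ring | random_cloud | perturbed_copy
    n_atoms: int = 10
    element: str = "C"
    box_size: float | None = None     # random_cloud sampling box edge, A
    perturbation: float = 0.1         # perturbed_copy Gaussian sigma, A
    base: Molecule | None = None      # perturbed_copy source
    name: str = ""


def _chain(spec: FixtureSpec) -> Molecule:
    n = spec.n_atoms
    coords = np.zeros((n, 3))
    coords[:, 0] = CHAIN_SPACING * np.arange(n)
    bonds = tuple((i, i + 1, 1.0) for i in range(n - 1))
    return Molecule(spec.name or f"chain{n}", (spec.element,) * n, coords, bonds)


def _ring(spec: FixtureSpec) -> Molecule:
    n = max(spec.n_atoms, 3)
    radius = CHAIN_SPACING / (2.0 * math.sin(math.pi / n))
    theta = 2.0 * math.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
    bonds = tuple((i, (i + 1) % n, 1.0) for i in range(n))
    return Molecule(spec.name or f"ring{n}", (spec.element,) * n, coords, bonds)


def _random_cloud(spec: FixtureSpec) -> Molecule:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    side = spec.box_size if spec.box_size is not None else max(4.0, 2.2 * n ** (1.0 / 3.0))
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise GenerationError(
                f"cannot pack {n} atoms at >= {MIN_CLOUD_DISTANCE} A in a {side} A box"
            )
        candidate = rng.uniform(0.0, side, size=3)
        if all(np.linalg.norm(candidate - p) >= MIN_CLOUD_DISTANCE for p in placed):
            placed.append(candidate)
    symbols = tuple(rng.choice(["C", "C", "N", "O"]) for _ in range(n))
    return Molecule(spec.name or f"cloud{n}s{spec.seed}", symbols, np.array(placed))


def _perturbed_copy(spec: FixtureSpec) -> Molecule:
    if spec.base is None:
        raise ValueError("perturbed_copy requires a base molecule")
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.perturbation, size=spec.base.coords.shape) \
        if spec.perturbation > 0 else 0.0
    return Molecule(spec.name or f"{spec.base.name}_p{spec.seed}",
                    spec.base.symbols, spec.base.coords + noise,
                    spec.base.bonds)


def make_molecule(spec: FixtureSpec) -> Molecule:
    """Generate one deterministic molecule from its spec."""
    makers = {
        "single_atom": lambda s: Molecule(s.name or "atom", (s.element,), np.zeros((1, 3))),
        "chain": _chain,
        "ring": _ring,
        "random_cloud": _random_cloud,
        "perturbed_copy": _perturbed_copy,
    }
    try:
        maker = makers[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return maker(spec)


def make_asymmetric_molecule(seed: int, cloud_atoms: int = 16, tail_atoms: int = 5) -> Molecule:
    """A random cloud with a linear tail: a shape with strong third moments.

    Near-symmetric clouds have third-order central moments close to zero,
    which makes the skewness invariant numerically ill-conditioned (tiny
    signal against grid jitter); the tail gives every invariant a healthy
    magnitude, so rigid-motion stability can be asserted in relative terms.
    """
    cloud = make_molecule(FixtureSpec(seed=seed, kind="random_cloud", n_atoms=cloud_atoms))
    tail = make_molecule(FixtureSpec(kind="chain", n_atoms=tail_atoms))
    center = cloud.coords.mean(axis=0)
    offset = center + np.array([cloud.coords[:, 0].max() - center[0] + CHAIN_SPACING, 0.0, 0.0])
    coords = np.vstack([cloud.coords, tail.coords + offset])
    return Molecule(f"blob{seed}", cloud.symbols + tail.symbols, coords)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_screen(seed: int, n_actives: int, n_decoys: int,
                base_spec: FixtureSpec | None = None,
                perturbation: float = 0.1) -> tuple[list[Molecule], list[Molecule]]:
    """A synthetic actives/decoys screen around one base shape.

    Actives are Gaussian-perturbed copies of the base molecule; decoys are
    independent random clouds with the same atom count (size-matched,
    shape-unmatched).
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    base = make_molecule(base_spec or FixtureSpec(seed=seed, kind="random_cloud",
                                                  n_atoms=12, name="screen_base"))
    actives = [
        make_molecule(FixtureSpec(seed=seed * 100003 + i, kind="perturbed_copy",
                                  base=base, perturbation=perturbation,
                                  name=f"active{i:03d}"))
        for i in range(n_actives)
    ]
    # decoys sample the base's own bounding box, so atom count AND packing
    # density match and the screen is not separable by volume alone
    base_side = float((base.coords.max(axis=0) - base.coords.min(axis=0)).max())
    decoys = [
        make_molecule(FixtureSpec(seed=seed * 200003 + i, kind="random_cloud",
                                  n_atoms=base.n_atoms, box_size=base_side,
                                  name=f"decoy{i:03d}"))
        for i in range(n_decoys)
    ]
    return actives, decoys


def make_library(seed: int, n_targets: int, outdir: str | Path,
                 min_atoms: int = 8, max_atoms: int = 20) -> list[ComplexSpec]:
    """Write a synthetic complex set: native ligand SDFs + receptor placeholders.

    Each "target" is a random-cloud native ligand plus a minimal receptor
    file (synthetic placeholder; the mock engine only needs its identity).
    Returns specs ready for ``build_library``.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    outdir = Path(outdir)
    (outdir / "ligands").mkdir(parents=True, exist_ok=True)
    (outdir / "receptors").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_targets):
        entry_id = f"T{i:04d}"
        n_atoms = int(rng.integers(min_atoms, max_atoms + 1))
        ligand = make_molecule(FixtureSpec(seed=seed * 300007 + i, kind="random_cloud",
                                           n_atoms=n_atoms, name=f"lig_{entry_id}"))
        # shift each complex to its own region of space
        ligand = ligand.translated(rng.uniform(-30.0, 30.0, size=3))
        ligand_file = outdir / "ligands" / f"{entry_id}.sdf"
        write_molecule(ligand, ligand_file, "sdf")
        receptor_file = outdir / "receptors" / f"{entry_id}.pdb"
        _write_receptor_placeholder(receptor_file, entry_id, ligand)
        specs.append(ComplexSpec(
            entry_id=entry_id, receptor_file=str(receptor_file),
            ligand_file=str(ligand_file), target_id=f"TGT{i:04d}",
            target_name=f"synthetic target {i}", pdb_id=f"{9000 + i:04d}",
        ))
    return specs


def _write_receptor_placeholder(path: Path, entry_id: str, ligand: Molecule) -> None:
    """A minimal synthetic receptor PDB: a CA shell around the ligand centroid."""
    center = ligand.coords.mean(axis=0)
    lines = [f"REMARK synthetic receptor placeholder for {entry_id}"]
    offsets = np.array([[6, 0, 0], [-6, 0, 0], [0, 6, 0], [0, -6, 0], [0, 0, 6], [0, 0, -6]])
    for i, off in enumerate(offsets, start=1):
        x, y, z = center + off
        lines.append(
            f"ATOM  {i:>5}  CA  GLY A{i:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class MockEngine:
    """Deterministic stand-in docking engine for tests and demos.

    The score is a pure function of (receptor file name, query heavy-atom
    count, seed), mapped into [-12, -1] kcal/mol. Identical inputs always
    score identically, so redocking a native ligand reproduces its stored
    ScoreB and DetScore vanishes exactly.
    """

    seed: int = 0
    workdir: str | None = None
    name: str = "mock"

    def dock(self, receptor_file: str, ligand: Molecule, box: BoxSpec) -> EngineOutcome:
        key = f"{Path(receptor_file).name}|{ligand.n_heavy_atoms}|{self.seed}"
        digest = hashlib.sha256(key.encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2 ** 64
        score = -1.0 - 11.0 * u
        pose_file = None
        if self.workdir is not None:
            pose_path = Path(self.workdir) / f"{ligand.name}_pose.pdb"
            write_molecule(ligand, pose_path, "pdb")
            pose_file = str(pose_path)
        return EngineOutcome(score=score, pose_file=pose_file,
                             metadata={"engine": self.name, "seed": self.seed})


def mock_engine(seed: int = 0, workdir: str | None = None) -> MockEngine:
    return MockEngine(seed=seed, workdir=workdir)
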