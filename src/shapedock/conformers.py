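"""Query conformer workflow: rotatable-bond gate, delegated generation,
Boltzmann population filtering and the ensemble cap.

Library ligands keep their experimental bioactive pose; only user queries get
an ensemble. Highly flexible queries (>= 5 rotatable bonds) skip generation to
avoid combinatorial explosion and are screened with their input conformation.
Rigid queries are expanded by an external generator (Monte Carlo, up to 500
conformers, or systematic enumeration with a 50.0 kcal/mol energy window),
energy-minimized (MMFF94-class, 3000 steps, inside the adapter), then filtered
by Boltzmann population at 298.15 K: conformers below the population threshold
(default 0.5%) are dropped and the ensemble is capped at 100 lowest-energy
members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .errors import GenerationError, MissingTopologyError
from .structure_io import Molecule

R_GAS = 0.0019872041       # kcal / (mol K)
DEFAULT_T = 298.15         # K
DEFAULT_THRESHOLD = 0.005  # minimum Boltzmann population retained
DEFAULT_CAP = 100          # maximum retained conformers
ROTATABLE_SKIP_AT = 5      # >= this many rotatable bonds: keep input pose

MONTE_CARLO_MAX_CONFORMERS = 500
SYSTEMATIC_ENERGY_CUTOFF = 50.0  # kcal/mol
MINIMIZATION_STEPS = 3000


@dataclass(frozen=True)
class Conformer:
    geometry: Molecule
    energy: float            # kcal/mol, relative scale is sufficient
    population: float = 0.0  # Boltzmann weight over the full pre-filter set
    retained: bool = True


@dataclass(frozen=True)
class ConformerEnsemble:
    conformers: tuple[Conformer, ...]
    temperature: float = DEFAULT_T
    metadata: dict = field(default_factory=dict)

    @property
    def retained(self) -> tuple[Conformer, ...]:
        return tuple(c for c in self.conformers if c.retained)

    @property
    def geometries(self) -> list[Molecule]:
        return [c.geometry for c in self.retained]


@dataclass(frozen=True)
class ConformerPlan:
    generate: bool
    rotatable_bonds: int
    method: str = "monte_carlo"   # "monte_carlo" | "systematic"
    reason: str = ""


def _ring_bonds(n_atoms: int, edges: list[tuple[int, int]]) -> set[frozenset[int]]:
    """Bonds on a cycle = edges that are not bridges (iterative DFS bridge finding)."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_atoms)]
    for eid, (i, j) in enumerate(edges):
        adj[i].append((j, eid))
        adj[j].append((i, eid))
    visited = [False] * n_atoms
    disc = [0] * n_atoms
    low = [0] * n_atoms
    bridges: set[int] = set()
    timer = 0
    for root in range(n_atoms):
        if visited[root]:
            continue
        stack = [(root, -1, iter(adj[root]))]
        visited[root] = True
        disc[root] = low[root] = timer = timer + 1
        while stack:
            node, in_edge, it = stack[-1]
            advanced = False
            for nbr, eid in it:
                if eid == in_edge:
                    continue
                if visited[nbr]:
                    low[node] = min(low[node], disc[nbr])
                else:
                    visited[nbr] = True
                    timer += 1
                    disc[nbr] = low[nbr] = timer
                    stack.append((nbr, eid, iter(adj[nbr])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                if stack:
                    parent, parent_edge, _ = stack[-1]
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        bridges.add(in_edge)
    return {frozenset(edges[eid]) for eid in range(len(edges)) if eid not in bridges}


def count_rotatable_bonds(molecule: Molecule) -> int:
    """Count rotatable bonds: non-ring single bonds between two heavy atoms,
    each carrying at least one further heavy neighbor; amide C-N excluded.
    """
    if molecule.bonds is None:
        raise MissingTopologyError(
            f"molecule '{molecule.name}' carries no bond information"
        )
    heavy = [s != "H" for s in molecule.symbols]
    edges = [(i, j) for i, j, _ in molecule.bonds]
    rings = _ring_bonds(molecule.n_atoms, edges)
    heavy_nbrs: dict[int, list[int]] = {i: [] for i in range(molecule.n_atoms)}
    order_of: dict[frozenset[int], float] = {}
    for i, j, order in molecule.bonds:
        order_of[frozenset((i, j))] = order
        if heavy[j]:
            heavy_nbrs[i].append(j)
        if heavy[i]:
            heavy_nbrs[j].append(i)

    def is_amide(i: int, j: int) -> bool:
        # single C-N bond where the carbon bears a double-bonded oxygen
        for c, n in ((i, j), (j, i)):
            if molecule.symbols[c] == "C" and molecule.symbols[n] == "N":
                for k in heavy_nbrs[c]:
                    if k != n and molecule.symbols[k] == "O" \
                            and order_of.get(frozenset((c, k))) == 2.0:
                        return True
        return False

    count = 0
    for i, j, order in molecule.bonds:
        if order != 1.0 or not (heavy[i] and heavy[j]):
            continue
        if frozenset((i, j)) in rings:
            continue
        if len([k for k in heavy_nbrs[i] if k != j]) < 1:
            continue
        if len([k for k in heavy_nbrs[j] if k != i]) < 1:
            continue
        if is_amide(i, j):
            continue
        count += 1
    return count


def plan_conformers(molecule: Molecule, method: str = "monte_carlo") -> ConformerPlan:
    """Decide whether to expand the query into a conformer ensemble.

    At or above ``ROTATABLE_SKIP_AT`` rotatable bonds generation is skipped
    and the input conformation is used as-is.
    """
    n_rot = count_rotatable_bonds(molecule)
    if n_rot >= ROTATABLE_SKIP_AT:
        return ConformerPlan(
            generate=False, rotatable_bonds=n_rot, method=method,
            reason=(f"{n_rot} rotatable bonds (>= {ROTATABLE_SKIP_AT}): skipping "
                    "conformer generation to avoid combinatorial explosion; "
                    "using the input conformation"),
        )
    return ConformerPlan(generate=True, rotatable_bonds=n_rot, method=method,
                         reason=f"{n_rot} rotatable bonds: generating conformers")


def boltzmann_filter(energies, temperature: float = DEFAULT_T,
                     threshold: float = DEFAULT_THRESHOLD,
                     cap: int = DEFAULT_CAP) -> tuple[np.ndarray, list[int]]:
    """Boltzmann populations and the retained index set.

    p_i = exp(-(E_i - E_min) / (R T)) / sum_j exp(-(E_j - E_min) / (R T));
    indices with p_i >= threshold are retained; if more than ``cap`` survive,
    the ``cap`` lowest-energy ones are kept (ties by input order). A screening
    ensemble must never be empty, so when the threshold removes every
    conformer (many near-degenerate energies dilute all populations below it)
    the ``cap`` lowest-energy conformers are retained instead.
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValueError("at least one conformer energy is required")
    if not np.all(np.isfinite(e)):
        raise ValueError("conformer energies must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (R_GAS * temperature))
    populations = w / w.sum()
    retained = [i for i in range(e.size) if populations[i] >= threshold]
    if not retained:
        retained = list(range(e.size))
    if len(retained) > cap:
        retained = sorted(sorted(retained, key=lambda i: (e[i], i))[:cap])
    return populations, retained


class ConformerAdapter(Protocol):
    """Contract for delegated generation: geometries with relative energies.

    Implementations are expected to have already minimized each geometry
    (MMFF94-class force field) and deduplicated by RMSD; ``metadata``
    reports the method, parameters and any RMSD cutoff applied.
    """

    def generate(self, molecule: Molecule, method: str) -> tuple[list[tuple[Molecule, float]], dict]:
        ...


def generate_ensemble(molecule: Molecule, plan: ConformerPlan,
                      adapter: ConformerAdapter | None = None,
                      temperature: float = DEFAULT_T,
                      threshold: float = DEFAULT_THRESHOLD,
                      cap: int = DEFAULT_CAP) -> ConformerEnsemble:
    """Build the query ensemble according to the plan.

    With ``plan.generate`` false (or no adapter configured) the ensemble is
    the input conformation with population 1. Otherwise generation is
    delegated to the adapter and the result Boltzmann-filtered.
    """
    if not plan.generate or adapter is None:
        conf = Conformer(geometry=molecule, energy=0.0, population=1.0, retained=True)
        return ConformerEnsemble(
            conformers=(conf,), temperature=temperature,
            metadata={"method": "input_conformation", "reason": plan.reason},
        )
    try:
        generated, adapter_meta = adapter.generate(molecule, plan.method)
    except Exception as exc:
        raise GenerationError(f"conformer generation failed for '{molecule.name}': {exc}") from exc
    if not generated:
        raise GenerationError(f"generator returned zero conformers for '{molecule.name}'")
    energies = [e for _, e in generated]
    populations, retained = boltzmann_filter(energies, temperature, threshold, cap)
    retained_set = set(retained)
    conformers = tuple(
        Conformer(geometry=geom, energy=float(e), population=float(populations[i]),
                  retained=i in retained_set)
        for i, (geom, e) in enumerate(generated)
    )
    meta = {"method": plan.method, "temperature_K": temperature,
            "population_threshold": threshold, "cap": cap}
    meta.update(adapter_meta or {})
    return ConformerEnsemble(conformers=conformers, temperature=temperature, metadata=meta)


@dataclass
class OpenBabelAdapter:
    """Generation adapter shelling out to the Open Babel CLI.

    Writes the query to SDF, runs ``obabel --conformer`` (Monte Carlo scoring,
    capped at MONTE_CARLO_MAX_CONFORMERS) or ``--confab`` (systematic, energy
    window SYSTEMATIC_ENERGY_CUTOFF kcal/mol with RMSD deduplication), then
    reads back the multi-record SDF with per-record energy tags.
    """

    executable: str = "obabel"
    workdir: str = "."
    rmsd_cutoff: float = 0.5

    def generate(self, molecule: Molecule, method: str):
        import subprocess
        from pathlib import Path

        from .structure_io import read_molecules, write_molecule

        work = Path(self.workdir)
        work.mkdir(parents=True, exist_ok=True)
        src = work / f"{molecule.name}_in.sdf"
        dst = work / f"{molecule.name}_confs.sdf"
        write_molecule(molecule, src, "sdf")
        if method == "systematic":
            args = ["--confab", "--ecutoff", str(SYSTEMATIC_ENERGY_CUTOFF),
                    "--rcutoff", str(self.rmsd_cutoff)]
        else:
            args = ["--conformer", "--nconf", str(MONTE_CARLO_MAX_CONFORMERS),
                    "--writeconformers"]
        cmd = [self.executable, str(src), "-O", str(dst), *args,
               "--ff", "MMFF94", "--steps", str(MINIMIZATION_STEPS)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not dst.exists():
            raise GenerationError(f"obabel failed: {proc.stderr.strip()[:500]}")
        geoms = read_molecules(dst, "sdf")
        energies = self._mmff94_energies(dst, len(geoms))
        meta = {"generator": "openbabel", "method": method,
                "rmsd_cutoff": self.rmsd_cutoff, "minimization_steps": MINIMIZATION_STEPS}
        return list(zip(geoms, energies)), meta

    def _mmff94_energies(self, sdf_path, n: int) -> list[float]:
        """MMFF94 single-point energies per record via obenergy (kcal/mol).

        The conformer writer emits no energy tags, so energies are recomputed;
        if obenergy is unavailable all conformers are treated as degenerate.
        """
        import re
        import subprocess

        try:
            proc = subprocess.run(["obenergy", "-ff", "MMFF94", str(sdf_path)],
                                  capture_output=True, text=True)
        except FileNotFoundError:
            return [0.0] * n
        found = re.findall(r"TOTAL ENERGY\s*=\s*(-?\d+(?:\.\d+)?)", proc.stdout)
        if len(found) != n:
            return [0.0] * n
        return [float(v) for v in found]
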