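"""Reverse docking orchestration and native-ligand-normalized ranking.

Raw docking scores are not comparable across protein targets: redocking native
ligands into their own receptors spans tens of kcal/mol depending on the
system. Each candidate target is therefore scored by the differential

    DetScore = ScoreA - ScoreB,

where ScoreA is the query's docking score in that pocket and ScoreB is the
stored score of the pocket's own co-crystallized ligand redocked under the
same settings. A negative DetScore predicts the query binds better than the
native ligand. Targets are ranked by ascending DetScore ("comprehensive
sorting"), carried alongside the shape-similarity rank.

The docking engine sits behind a small adapter protocol so the pipeline runs
identically against AutoDock Vina or a deterministic in-process mock.
"""

from __future__ import annotations

import math
import re
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .errors import ConsistencyError, EngineError, LibraryError
from .structure_io import Molecule

DEFAULT_BOX_MARGIN = 8.0   # A added around the native ligand per face
DEFAULT_MIN_EDGE = 16.0    # A floor on every box edge


@dataclass(frozen=True)
class BoxSpec:
    """Axis-aligned docking box: center and edge lengths in Angstrom."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "size", tuple(float(s) for s in self.size))
        if any(s <= 0 for s in self.size):
            raise ValueError(f"box sizes must be positive, got {self.size}")

    def contains(self, coords: np.ndarray, clearance: float = 0.0) -> bool:
        c = np.asarray(self.center)
        half = np.asarray(self.size) / 2.0
        return bool(np.all(np.abs(coords - c) <= half - clearance + 1e-9))


def make_box(native_ligand: Molecule, margin: float = DEFAULT_BOX_MARGIN,
             min_edge: float = DEFAULT_MIN_EDGE) -> BoxSpec:
    """Docking box from the native ligand: bounding box + margin, floored edges."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    lo = native_ligand.coords.min(axis=0)
    hi = native_ligand.coords.max(axis=0)
    center = (lo + hi) / 2.0
    size = np.maximum(hi - lo + 2.0 * margin, min_edge)
    return BoxSpec(center=tuple(center), size=tuple(size))


@dataclass(frozen=True)
class EngineOutcome:
    """Best score (kcal/mol) and optional pose file from one engine call."""

    score: float
    pose_file: str | None = None
    metadata: dict | None = None


class DockingEngine(Protocol):
    """Adapter contract: dock one ligand into one receptor box."""

    name: str

    def dock(self, receptor_file: str, ligand: Molecule, box: BoxSpec) -> EngineOutcome:
        ...


@dataclass(frozen=True)
class DockingResult:
    entry_id: str
    score_a: float   # query docking score, kcal/mol
    score_b: float   # native-ligand redock score, kcal/mol
    det_score: float
    pose_file: str | None = None
    engine: str = ""


def det_score(score_a: float, score_b: float) -> float:
    """DetScore = ScoreA - ScoreB (kcal/mol); negative = better than native."""
    if not (math.isfinite(score_a) and math.isfinite(score_b)):
        raise ValueError(f"scores must be finite, got {score_a}, {score_b}")
    return score_a - score_b


def dock(query: Molecule | Sequence[Molecule], entry, engine: DockingEngine) -> DockingResult:
    """Dock a query (single conformer or ensemble) into one library entry.

    ScoreA is the engine's best (lowest) score across the submitted
    conformers. Entries without a stored native-redock ScoreB are refused:
    without the baseline, the differential score is meaningless.
    """
    if entry.score_b_pending:
        raise LibraryError(
            f"entry '{entry.entry_id}' has no native redock score (ScoreB); "
            "rebuild the library with a docking engine before reverse docking"
        )
    conformers = [query] if isinstance(query, Molecule) else list(query)
    if not conformers:
        raise ValueError("empty query ensemble")
    best: EngineOutcome | None = None
    for conf in conformers:
        outcome = engine.dock(entry.receptor_file, conf, entry.box)
        if best is None or outcome.score < best.score:
            best = outcome
    return DockingResult(
        entry_id=entry.entry_id, score_a=best.score, score_b=entry.score_b,
        det_score=det_score(best.score, entry.score_b),
        pose_file=best.pose_file, engine=getattr(engine, "name", ""),
    )


@dataclass(frozen=True)
class RankedTarget:
    """One row of the final report, carrying both ranks."""

    entry_id: str
    similarity: float
    similarity_rank: int
    score_a: float
    score_b: float
    det_score: float
    comprehensive_rank: int


def rank_targets(hits, results: list[DockingResult]) -> list[RankedTarget]:
    """Merge similarity hits and docking results into the comprehensive ranking.

    Records are sorted by ascending DetScore (most negative = most promising);
    ties go to the higher similarity, then to the lexically smaller entry id.
    Every docking result must correspond to a similarity hit.
    """
    by_id = {h.entry_id: h for h in hits}
    orphans = [r.entry_id for r in results if r.entry_id not in by_id]
    if orphans:
        raise ConsistencyError(f"docking results without matching hits: {orphans}")
    merged = sorted(
        results,
        key=lambda r: (r.det_score, -by_id[r.entry_id].similarity, r.entry_id),
    )
    out = []
    for rank, r in enumerate(merged, start=1):
        h = by_id[r.entry_id]
        out.append(RankedTarget(
            entry_id=r.entry_id, similarity=h.similarity,
            similarity_rank=h.similarity_rank, score_a=r.score_a,
            score_b=r.score_b, det_score=r.det_score, comprehensive_rank=rank,
        ))
    return out


# ------------------------------------------------------------ Vina adapter

_AFFINITY_ROW = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)\s", re.MULTILINE)


def parse_vina_stdout(text: str) -> float:
    """Extract the best-mode affinity (kcal/mol) from Vina's result table."""
    match = _AFFINITY_ROW.search(text)
    if match is None:
        raise EngineError("could not find mode-1 affinity in engine output")
    return float(match.group(1))


@dataclass
class VinaEngine:
    """Adapter for the AutoDock Vina command-line dialect.

    Expects receptor and ligand already prepared as PDBQT (polar hydrogens,
    Gasteiger charges). The seed is fixed and recorded because scores vary
    with seed and exhaustiveness.
    """

    executable: str = "vina"
    exhaustiveness: int = 8
    seed: int = 0
    cpu: int = 1
    workdir: str = "."
    name: str = "vina"

    def dock(self, receptor_file: str, ligand: Molecule, box: BoxSpec) -> EngineOutcome:
        from .structure_io import write_molecule

        if not Path(receptor_file).exists():
            raise EngineError(f"receptor file not found: {receptor_file}")
        work = Path(self.workdir)
        work.mkdir(parents=True, exist_ok=True)
        ligand_pdbqt = work / f"{ligand.name}.pdbqt"
        if not ligand_pdbqt.exists():
            # delegate PDBQT preparation to Open Babel
            ligand_sdf = work / f"{ligand.name}.sdf"
            write_molecule(ligand, ligand_sdf, "sdf")
            conv = subprocess.run(
                ["obabel", str(ligand_sdf), "-O", str(ligand_pdbqt), "--partialcharge", "gasteiger"],
                capture_output=True, text=True,
            )
            if conv.returncode != 0 or not ligand_pdbqt.exists():
                raise EngineError(f"ligand PDBQT preparation failed: {conv.stderr.strip()}")
        pose = work / f"{ligand.name}_pose.pdbqt"
        cmd = [
            self.executable,
            "--receptor", str(receptor_file), "--ligand", str(ligand_pdbqt),
            "--center_x", str(box.center[0]), "--center_y", str(box.center[1]),
            "--center_z", str(box.center[2]),
            "--size_x", str(box.size[0]), "--size_y", str(box.size[1]),
            "--size_z", str(box.size[2]),
            "--exhaustiveness", str(self.exhaustiveness),
            "--seed", str(self.seed), "--cpu", str(self.cpu),
            "--out", str(pose),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineError(
                f"docking engine exited {proc.returncode}: {proc.stderr.strip()[:500]}"
            )
        score = parse_vina_stdout(proc.stdout)
        meta = {"engine": self.name, "exhaustiveness": self.exhaustiveness, "seed": self.seed}
        return EngineOutcome(score=score, pose_file=str(pose), metadata=meta)
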