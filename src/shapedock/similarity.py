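"""Descriptor similarity, library construction and shape pre-screening.

Two descriptor vectors A = [a1..a10] and B = [b1..b10] are compared without
any superposition by the mean componentwise min/max ratio

    sim(A, B) = (1/10) * sum_i  min(a_i, b_i) / max(a_i, b_i),

which is 1 exactly when the vectors are equal and decays toward 0 as they
diverge. Conventions for edge cases (both components zero -> the term is 1;
exactly one zero, or opposite signs -> 0) keep the score in [0, 1], symmetric,
and equal to 1 only for identical vectors.

A descriptor library holds one entry per protein target: the native
co-crystallized ligand's descriptor vector (its experimental pose, no
conformer search), a reference to the prepared receptor, the docking box
derived from the native ligand, and the native ligand's redocking score
(ScoreB) used later for score normalization.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import COMPONENT_NAMES, C3DDVector, DescriptorConfig, c3dd
from .docking import BoxSpec, make_box
from .errors import LibraryError, MetadataMismatchError
from .structure_io import read_molecule

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 200


def _term(a: float, b: float) -> float:
    if a == 0.0 and b == 0.0:
        return 1.0
    if a == 0.0 or b == 0.0 or (a > 0) != (b > 0):
        return 0.0
    aa, bb = abs(a), abs(b)
    return min(aa, bb) / max(aa, bb)


def similarity(a: C3DDVector, b: C3DDVector) -> float:
    """Mean min/max component ratio between two descriptor vectors, in [0, 1]."""
    if a.metadata and b.metadata and a.metadata != b.metadata:
        raise MetadataMismatchError(
            f"descriptor settings differ: {a.metadata} vs {b.metadata}"
        )
    return sum(_term(x, y) for x, y in zip(a.values, b.values)) / 10.0


@dataclass(frozen=True)
class ComplexSpec:
    """One protein-ligand complex to be turned into a library entry."""

    entry_id: str
    receptor_file: str
    ligand_file: str
    target_id: str = ""
    target_name: str = ""
    pdb_id: str = ""


@dataclass(frozen=True)
class LibraryEntry:
    entry_id: str
    target_id: str
    target_name: str
    pdb_id: str
    ligand_file: str
    receptor_file: str
    box: BoxSpec
    vector: C3DDVector
    score_b: float = math.nan  # kcal/mol; NaN = redock pending

    @property
    def score_b_pending(self) -> bool:
        return math.isnan(self.score_b)


@dataclass(frozen=True)
class SimilarityHit:
    entry_id: str
    similarity: float
    similarity_rank: int
    best_query_conformer: int


@dataclass
class DescriptorLibrary:
    """Target library: entries plus the shared descriptor metadata."""

    entries: list[LibraryEntry]
    metadata: dict[str, str]

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise LibraryError("library entry ids are not unique")
        for e in self.entries:
            if e.vector.metadata and e.vector.metadata != self.metadata:
                raise MetadataMismatchError(
                    f"entry '{e.entry_id}' descriptor settings differ from library metadata"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


def build_library(specs: list[ComplexSpec], config: DescriptorConfig | None = None,
                  engine=None, box_margin: float = 8.0,
                  min_edge: float = 16.0) -> DescriptorLibrary:
    """Build a descriptor library from protein-ligand complex specs.

    Each native ligand is read as-is (its experimental pose; no conformer
    search), its descriptor vector and docking box are computed, and — when a
    docking ``engine`` is supplied — the native ligand is redocked into its
    own receptor to obtain the normalization baseline ScoreB. Without an
    engine, ScoreB is marked pending. Per-entry failures are logged and
    skipped; an empty result raises :class:`~shapedock.errors.LibraryError`.
    """
    cfg = config or DescriptorConfig()
    entries: list[LibraryEntry] = []
    failures = 0
    for spec in specs:
        try:
            ligand = read_molecule(spec.ligand_file)
            vector = c3dd(ligand, cfg)
            box = make_box(ligand, margin=box_margin, min_edge=min_edge)
            if engine is not None:
                score_b = engine.dock(spec.receptor_file, ligand, box).score
            else:
                score_b = math.nan
            entries.append(LibraryEntry(
                entry_id=spec.entry_id, target_id=spec.target_id,
                target_name=spec.target_name, pdb_id=spec.pdb_id,
                ligand_file=spec.ligand_file, receptor_file=spec.receptor_file,
                box=box, vector=vector, score_b=score_b,
            ))
        except Exception as exc:  # noqa: BLE001 - per-entry isolation is the contract
            failures += 1
            logger.warning("skipping library entry '%s': %s", spec.entry_id, exc)
    if failures:
        logger.warning("library build skipped %d of %d entries", failures, len(specs))
    if not entries:
        raise LibraryError(f"library build produced no entries ({failures} failures)")
    return DescriptorLibrary(entries=entries, metadata=cfg.metadata)


def search(query_vectors: list[C3DDVector], library: DescriptorLibrary,
           top_k: int = DEFAULT_TOP_K) -> list[SimilarityHit]:
    """Rank library entries by best-conformer similarity to the query.

    Per entry the similarity is the maximum over the query conformer vectors
    (best-match convention); hits are sorted by similarity descending with
    ties broken by entry id, truncated to ``top_k``, and ranked 1-based.
    """
    if not query_vectors:
        raise LibraryError("at least one query conformer vector is required")
    if len(library) == 0:
        raise LibraryError("cannot search an empty library")
    scored = []
    for entry in library.entries:
        sims = [similarity(qv, entry.vector) for qv in query_vectors]
        best = int(np.argmax(sims))
        scored.append((entry.entry_id, sims[best], best))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        SimilarityHit(entry_id=eid, similarity=s, similarity_rank=rank,
                      best_query_conformer=conf)
        for rank, (eid, s, conf) in enumerate(scored[:top_k], start=1)
    ]


# ------------------------------------------------------------ persistence

_BOX_COLS = ("box_cx", "box_cy", "box_cz", "box_sx", "box_sy", "box_sz")
_COLUMNS = (("entry_id", "target_id", "target_name", "pdb_id",
             "ligand_file", "receptor_file") + _BOX_COLS
            + COMPONENT_NAMES + ("score_b",))


def save_library(library: DescriptorLibrary, path: str | Path) -> None:
    """Persist a library as a diffable TSV with a ``# key=value`` metadata head."""
    rows = []
    for e in library.entries:
        row = {
            "entry_id": e.entry_id, "target_id": e.target_id,
            "target_name": e.target_name, "pdb_id": e.pdb_id,
            "ligand_file": e.ligand_file, "receptor_file": e.receptor_file,
        }
        row.update(dict(zip(_BOX_COLS, (*e.box.center, *e.box.size))))
        row.update(e.vector.as_dict())
        row["score_b"] = e.score_b
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(_COLUMNS))
    buf = io.StringIO()
    for key, value in sorted(library.metadata.items()):
        buf.write(f"# {key}={value}\n")
    frame.to_csv(buf, sep="\t", index=False, float_format="%.10g", na_rep="nan")
    Path(path).write_text(buf.getvalue())


def load_library(path: str | Path) -> DescriptorLibrary:
    text = Path(path).read_text()
    metadata: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line[1:].strip().partition("=")
        metadata[key.strip()] = value.strip()
    str_cols = ("entry_id", "target_id", "target_name", "pdb_id",
                "ligand_file", "receptor_file")
    frame = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                        dtype={c: str for c in str_cols},
                        keep_default_na=False, na_values=["nan"])
    entries = []
    for _, row in frame.iterrows():
        vector = C3DDVector(
            values=np.array([row[c] for c in COMPONENT_NAMES], dtype=float),
            metadata=dict(metadata),
        )
        box = BoxSpec(center=(row["box_cx"], row["box_cy"], row["box_cz"]),
                      size=(row["box_sx"], row["box_sy"], row["box_sz"]))
        entries.append(LibraryEntry(
            entry_id=str(row["entry_id"]), target_id=str(row["target_id"]),
            target_name=str(row["target_name"]), pdb_id=str(row["pdb_id"]),
            ligand_file=str(row["ligand_file"]), receptor_file=str(row["receptor_file"]),
            box=box, vector=vector, score_b=float(row["score_b"]),
        ))
    return DescriptorLibrary(entries=entries, metadata=metadata)
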