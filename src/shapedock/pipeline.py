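"""End-to-end target prediction: screen, dock, rank, report.

The workflow mirrors how the tool is used from the shell: compute the query's
descriptor vector(s), rank the library by shape similarity, reverse-dock the
shortlisted targets, and emit a report carrying both the similarity rank and
the comprehensive (DetScore) rank for every docked entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .descriptors import C3DDVector, DescriptorConfig, c3dd
from .docking import DockingEngine, DockingResult, RankedTarget, dock, rank_targets
from .similarity import DescriptorLibrary, SimilarityHit, search
from .structure_io import Molecule

REPORT_COLUMNS = (
    "entry_id", "target_id", "target_name", "pdb_id",
    "similarity", "similarity_rank",
    "score_a", "score_b", "det_score", "comprehensive_rank",
)


@dataclass(frozen=True)
class PipelineResult:
    hits: list[SimilarityHit]
    docking: list[DockingResult]
    ranking: list[RankedTarget]


def run_pipeline(query_conformers: list[Molecule], library: DescriptorLibrary,
                 engine: DockingEngine, top_k: int = 200,
                 config: DescriptorConfig | None = None) -> PipelineResult:
    """Similarity shortlist -> reverse docking -> comprehensive ranking."""
    cfg = config or DescriptorConfig()
    vectors = [c3dd(m, cfg) for m in query_conformers]
    hits = search(vectors, library, top_k=top_k)
    results = []
    for hit in hits:
        entry = library.get(hit.entry_id)
        results.append(dock(query_conformers, entry, engine))
    ranking = rank_targets(hits, results)
    return PipelineResult(hits=hits, docking=results, ranking=ranking)


def write_report(result: PipelineResult, library: DescriptorLibrary,
                 path: str | Path) -> None:
    """Write the final ranking as a fixed-precision TSV (byte-stable)."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for rec in result.ranking:
        entry = library.get(rec.entry_id)
        lines.append("\t".join([
            rec.entry_id, entry.target_id, entry.target_name, entry.pdb_id,
            f"{rec.similarity:.6f}", str(rec.similarity_rank),
            f"{rec.score_a:.4f}", f"{rec.score_b:.4f}", f"{rec.det_score:.4f}",
            str(rec.comprehensive_rank),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
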