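"""Virtual-screening evaluation statistics: ROC AUC, enrichment factor, recall@K.

AUC is computed as the Mann-Whitney rank statistic — the probability that a
randomly chosen active outscores a randomly chosen inactive, with ties counted
one half — which makes the tie convention exact rather than an artifact of
threshold interpolation. The enrichment factor at fraction f is the actives
rate inside the top ceil(f*N) of the ranking divided by the overall actives
rate; EF = 1 is chance, EF = 1/f is perfect (when enough actives exist).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import CoverageError, UndefinedMetricError

DEFAULT_RECALL_K = 200


@dataclass(frozen=True)
class ScreenResult:
    """A scored, labelled screen: (item id, score, is_active) triples."""

    items: tuple[tuple[str, float, bool], ...]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items",
            tuple((str(i), float(s), bool(a)) for i, s, a in self.items),
        )

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.items])

    @property
    def labels(self) -> np.ndarray:
        return np.array([a for _, _, a in self.items], dtype=bool)


def roc_auc(result: ScreenResult) -> float:
    """Rank-based ROC AUC in [0, 1]; ties contribute 1/2 per pair."""
    y = result.labels
    n_act, n_inact = int(y.sum()), int((~y).sum())
    if n_act == 0 or n_inact == 0:
        raise UndefinedMetricError("AUC needs at least one active and one inactive")
    scores = result.scores if result.higher_is_better else -result.scores
    ranks = rankdata(scores)  # average ranks handle ties exactly
    u = ranks[y].sum() - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_inact))


def enrichment_factor(result: ScreenResult, fraction: float = 0.05) -> float:
    """Enrichment factor at the given fraction of the ranked list.

    The top set has ceil(fraction * N) items; ties at the cutoff are resolved
    deterministically by score and then item id.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    y = result.labels
    n = len(result.items)
    n_act = int(y.sum())
    if n_act == 0:
        raise UndefinedMetricError("enrichment factor needs at least one active")
    n_top = int(np.ceil(fraction * n))
    sign = -1.0 if result.higher_is_better else 1.0
    order = sorted(range(n), key=lambda i: (sign * result.items[i][1], result.items[i][0]))
    top_actives = sum(1 for i in order[:n_top] if y[i])
    return float((top_actives / n_top) / (n_act / n))


def recall_at_k(rankings: Iterable[tuple[str, str, Sequence]], k: int = DEFAULT_RECALL_K) -> float:
    """Fraction of queries whose true target ranks within the top k.

    ``rankings`` yields (query id, true target entry id, ranked records)
    where the records carry ``entry_id`` and ``comprehensive_rank``.
    """
    total = 0
    found = 0
    for query_id, true_id, records in rankings:
        total += 1
        ranks = {r.entry_id: r.comprehensive_rank for r in records}
        if true_id not in ranks:
            raise CoverageError(
                f"true target '{true_id}' for query '{query_id}' absent from the ranking"
            )
        if ranks[true_id] <= k:
            found += 1
    if total == 0:
        raise UndefinedMetricError("recall@K needs at least one query")
    return found / total
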