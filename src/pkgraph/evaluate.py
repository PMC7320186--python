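"""Clustering evaluation against PI ground truth.

Evaluation uses the crosswalk links (pi_id, pmid, and_id): funded-project
PI identifiers are trusted as ground truth for who wrote which article.
Precision asks, per disambiguated-author cluster, what fraction of its
articles belong to its most frequent PI; recall asks, per PI, what
fraction of their articles sit in their most frequent cluster; F1 is the
harmonic mean.  Aggregation is *micro* (article-weighted, the default —
the definitions are phrased in article counts) or *macro* (unweighted
over clusters/PIs).

Lumping and splitting diagnostics compare an assignment against a known
true world: the fraction of clusters containing two or more true
individuals, and the fraction of labeled instances belonging to
individuals scattered over two or more clusters.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .models import Clustering

logger = logging.getLogger(__name__)

Link = tuple[str, int, int]  # (pi_id, pmid, and_id)


class UndefinedMetricError(ValueError):
    """Metric requested on an empty link set."""


@dataclass
class EvalReport:
    """Precision/recall/F1 on the 0-100 scale, with per-cluster detail."""

    precision: float
    recall: float
    f1: float
    aggregation: str
    per_cluster: list[tuple[int, int, int]] = field(default_factory=list)
    # (cluster id, n articles, best-match article count)


def _grouped_best_fraction(
    pairs: Iterable[tuple[object, object, int]], aggregation: str
) -> tuple[float, list[tuple[object, int, int]]]:
    """Shared core: pairs are (group, counterpart, pmid).

    Per group: |articles of the most frequent counterpart| / |articles|.
    Micro aggregates by ratio of sums; macro averages per-group fractions.
    """
    articles: dict[object, set[int]] = defaultdict(set)
    by_pair: dict[object, dict[object, set[int]]] = defaultdict(lambda: defaultdict(set))
    for group, other, pmid in pairs:
        articles[group].add(pmid)
        by_pair[group][other].add(pmid)

    detail = []
    num = den = 0
    fractions = []
    for group in articles:
        total = len(articles[group])
        best = max(len(pmids) for pmids in by_pair[group].values())
        detail.append((group, total, best))
        num += best
        den += total
        fractions.append(best / total)
    if aggregation == "micro":
        value = 100.0 * num / den
    elif aggregation == "macro":
        value = 100.0 * sum(fractions) / len(fractions)
    else:
        raise ValueError(f"aggregation must be 'micro' or 'macro', got {aggregation!r}")
    detail.sort(key=lambda t: str(t[0]))
    return value, detail


def precision(links: set[Link], aggregation: str = "micro") -> float:
    """Per cluster: articles of its most frequent PI over all its articles.

    Returned on the 0-100 scale; raises on an empty link set (clusters
    with no PI link never enter — they are unevaluable).
    """
    if not links:
        raise UndefinedMetricError("precision undefined on an empty link set")
    value, _ = _grouped_best_fraction(
        ((and_id, pi_id, pmid) for pi_id, pmid, and_id in links), aggregation)
    return value


def recall(links: set[Link], aggregation: str = "micro") -> float:
    """Per PI: articles in their most frequent cluster over all their
    articles — precision with the two ID roles swapped."""
    if not links:
        raise UndefinedMetricError("recall undefined on an empty link set")
    value, _ = _grouped_best_fraction(
        ((pi_id, and_id, pmid) for pi_id, pmid, and_id in links), aggregation)
    return value


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of two percentages, rounded to two decimals.

    Both zero is reported as 0 with a warning rather than an error.
    """
    if precision_pct == 0.0 and recall_pct == 0.0:
        warnings.warn("P = R = 0; F1 reported as 0", stacklevel=2)
        return 0.0
    if not (0.0 < precision_pct <= 100.0 and 0.0 < recall_pct <= 100.0):
        raise ValueError("precision and recall must be percentages in (0, 100]")
    return round(2.0 * precision_pct * recall_pct / (precision_pct + recall_pct), 2)


def evaluate(links: set[Link], aggregation: str = "micro") -> EvalReport:
    """Full report: precision, recall and their harmonic mean."""
    p_value, detail = _grouped_best_fraction(
        ((and_id, pi_id, pmid) for pi_id, pmid, and_id in links), aggregation
    ) if links else (None, [])
    if p_value is None:
        raise UndefinedMetricError("evaluation undefined on an empty link set")
    r_value = recall(links, aggregation)
    return EvalReport(
        precision=p_value, recall=r_value, f1=f1(p_value, r_value),
        aggregation=aggregation,
        per_cluster=[(int(c), n, b) for c, n, b in detail],
    )


@dataclass
class LumpSplitReport:
    """Diagnostics of the two clustering error modes."""

    lump_fraction: float  # clusters containing >= 2 true individuals
    split_fraction: float  # labeled instances of individuals spread over >= 2 clusters
    n_clusters: int
    n_instances: int


def lump_split(assignment: Clustering, true_author_of: dict[int, int]) -> LumpSplitReport:
    """Measure lumping and splitting of an assignment against truth.

    ``true_author_of`` must cover every assigned instance.
    """
    clusters = assignment.clusters()
    n_clusters = len(clusters)
    n_instances = len(assignment.assignments)
    if n_clusters == 0:
        return LumpSplitReport(0.0, 0.0, 0, 0)

    lumped = 0
    clusters_of_author: dict[int, set[int]] = defaultdict(set)
    for label, members in clusters.items():
        authors = set()
        for m in members:
            author = true_author_of[m]
            authors.add(author)
            clusters_of_author[author].add(label)
        if len(authors) >= 2:
            lumped += 1

    split_instances = sum(
        1 for inst, label in assignment.assignments.items()
        if len(clusters_of_author[true_author_of[inst]]) >= 2
    )
    return LumpSplitReport(
        lump_fraction=lumped / n_clusters,
        split_fraction=split_instances / n_instances,
        n_clusters=n_clusters, n_instances=n_instances,
    )
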