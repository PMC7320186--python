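"""Author-bio-entity bipartite networks and their one-mode projections.

An edge connects a disambiguated author and a normalized bio-entity iff
at least one of the author's papers mentions the entity; its weight is
the number of *distinct* such papers (repeated mentions within one
abstract count once).  The one-mode projections connect two vertices of
the same class with weight equal to their number of common neighbors on
the other side — bipartite edge weights are ignored by the projection,
only presence counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx

from .models import AuthorInstance, Clustering, EntityMentionRecord


@dataclass
class BipartiteNetwork:
    """Weighted author-entity graph.

    ``edges`` maps (and_id, entity_id) to the distinct-paper count; the
    vertex sets are kept separately since author and entity IDs live in
    unrelated integer spaces.
    """

    authors: set[int] = field(default_factory=set)
    entities: set[int] = field(default_factory=set)
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    n_unassigned_excluded: int = 0

    def author_neighbors(self, and_id: int) -> set[int]:
        return {e for (a, e) in self.edges if a == and_id}

    def entity_neighbors(self, entity_id: int) -> set[int]:
        return {a for (a, e) in self.edges if e == entity_id}

    def to_networkx(self) -> nx.Graph:
        """Export with prefixed node names ('a:<id>', 'e:<id>') and the
        bipartite node attribute convention."""
        g = nx.Graph()
        g.add_nodes_from((f"a:{a}" for a in self.authors), bipartite=0)
        g.add_nodes_from((f"e:{e}" for e in self.entities), bipartite=1)
        g.add_weighted_edges_from(
            (f"a:{a}", f"e:{e}", w) for (a, e), w in self.edges.items())
        return g


@dataclass
class Projection:
    """One-mode projection: symmetric, no self-loops, weight = number of
    common neighbors (pairs with none are absent)."""

    side: str  # "authors" | "entities"
    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def weight(self, u: int, v: int) -> int:
        return self.edges.get((min(u, v), max(u, v)), 0)


def build_bipartite(
    mentions: Sequence[EntityMentionRecord],
    authors: Sequence[AuthorInstance],
    assignment: Clustering,
) -> BipartiteNetwork:
    """Build the network from normalized mentions and assigned authors.

    Mentions without a normalized ID are ignored; byline instances whose
    author is unassigned (label 0) are excluded and counted.
    """
    net = BipartiteNetwork()
    authors_of_pmid: dict[int, set[int]] = defaultdict(set)
    for inst in authors:
        and_id = assignment.label_of(inst.instance_id)
        if and_id <= 0:
            net.n_unassigned_excluded += 1
            continue
        authors_of_pmid[inst.pmid].add(and_id)

    entity_pmids: dict[int, set[int]] = defaultdict(set)
    for m in mentions:
        if m.entity_id is None:
            continue
        entity_pmids[m.entity_id].add(m.pmid)

    papers: dict[tuple[int, int], set[int]] = defaultdict(set)
    for entity_id, pmids in entity_pmids.items():
        for pmid in pmids:
            for and_id in authors_of_pmid.get(pmid, ()):
                papers[(and_id, entity_id)].add(pmid)

    for (and_id, entity_id), pmids in papers.items():
        net.authors.add(and_id)
        net.entities.add(entity_id)
        net.edges[(and_id, entity_id)] = len(pmids)
    return net


def project(net: BipartiteNetwork, side: str = "authors") -> Projection:
    """Project onto one vertex class via an inverted neighbor index.

    For each vertex on the *opposite* side, every pair of its neighbors
    gains one unit of weight; the result is exactly the common-neighbor
    count for each same-side pair.
    """
    if side not in ("authors", "entities"):
        raise ValueError(f"side must be 'authors' or 'entities', got {side!r}")
    neighbor_sets: dict[int, set[int]] = defaultdict(set)
    for (a, e) in net.edges:
        if side == "authors":
            neighbor_sets[e].add(a)
        else:
            neighbor_sets[a].add(e)

    proj = Projection(side=side)
    for shared in neighbor_sets.values():
        for u, v in combinations(sorted(shared), 2):
            proj.edges[(u, v)] = proj.edges.get((u, v), 0) + 1
    return proj


def write_edge_list(edges: dict[tuple, int], path) -> None:
    """3-column TSV (source, target, weight), sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in sorted(edges.items()):
            fh.write(f"{u}\t{v}\t{w}\n")
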