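"""Author-entity bipartite network and its one-mode projections.

An edge links an author and a bio-entity iff one of the author's papers
mentions the entity; the weight counts distinct papers.  Projections
connect same-class vertices by their number of common neighbors.
"""

from pkgraph.graph import build_bipartite, project
from pkgraph.synth import WorldConfig, generate_world

world = generate_world(WorldConfig(n_authors=80, seed=5))
net = build_bipartite(world.mentions, world.author_instances,
                      world.truth_clustering())
print(f"bipartite: {len(net.authors)} authors, {len(net.entities)} entities, "
      f"{len(net.edges)} edges")

heaviest = max(net.edges.items(), key=lambda kv: kv[1])
print(f"heaviest edge: author {heaviest[0][0]} - entity {heaviest[0][1]}, "
      f"{heaviest[1]} distinct papers")

authors = project(net, "authors")
entities = project(net, "entities")
print(f"author projection: {len(authors.edges)} edges; "
      f"entity projection: {len(entities.edges)} edges")
top = max(authors.edges.items(), key=lambda kv: kv[1])
print(f"strongest author pair {top[0]}: {top[1]} shared entities")
# A strong author-projection edge marks a pair with similar research
# focus — collaborators, or candidates for collaboration.
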