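"""Generate a synthetic bibliographic world with known ground truth.

The world contains true authors (some sharing a last name + first
initial, which is what makes disambiguation hard), their articles, and
derived ORCID-style and funded-project records.
"""

from pkgraph.synth import WorldConfig, generate_world, shared_name_keys

world = generate_world(WorldConfig(n_authors=100, name_pool_size=30, seed=7))

print(f"true authors:        {len(world.author_names)}")
print(f"articles:            {len(world.articles)}")
print(f"author instances:    {len(world.author_instances)}")
print(f"shared name keys:    {len(shared_name_keys(world))}")
print(f"registry records:    {len(world.orcid_records)}")
print(f"funded projects:     {len(world.project_records)}")
print(f"entity mentions:     {len(world.mentions)}")

# Every author instance maps to exactly one true author; a shared name
# key means two different people would collide under name-based matching.
first = world.author_instances[0]
print(f"\nexample instance: {first.last_name} {first.initials} on PMID "
      f"{first.pmid} -> true author {world.true_author_of[first.instance_id]}")
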