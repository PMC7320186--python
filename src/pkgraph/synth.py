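"""Synthetic bibliographic worlds with known ground truth.

The generator builds a population of *true authors*, gives them articles
(with co-authorship), and derives every input the downstream stages
consume: author instances, a truth clustering, ORCID-style researcher
records, funded-project records, bio-entity mentions embedded in
abstracts, and affiliation strings.  Homonymy — distinct people sharing a
(last name, first initial) key — emerges from sampling last names from a
finite pool, which is the property that makes author disambiguation and
its evaluation non-trivial.

Two perturbation operators turn the truth clustering into realistic noisy
inputs: :func:`perturb_clustering` injects lumping (two people merged) and
splitting (one person scattered) errors at controlled per-cluster rates,
and :func:`truncate_by_year` removes assignments after a cutoff year,
mimicking a high-precision disambiguation source whose coverage stops
early but leaks a few later preprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import (
    ArticleRecord,
    AuthorInstance,
    Clustering,
    EntityMentionRecord,
    OrcidAffiliation,
    OrcidRecord,
    OrcidWork,
    ProjectRecord,
)


class ConfigurationError(ValueError):
    """Infeasible world configuration."""


# Finite pools the generator samples from.  The surname pool is truncated to
# ``name_pool_size``, so shrinking it forces homonymous authors.
_SURNAMES = [
    "Smith", "Johnson", "Lee", "Kim", "Chen", "Wang", "Garcia", "Mueller",
    "Tanaka", "Singh", "Ivanov", "Rossi", "Silva", "Nguyen", "Park", "Zhang",
    "Brown", "Davis", "Martin", "Lopez", "Gonzalez", "Wilson", "Anderson",
    "Thomas", "Taylor", "Moore", "Jackson", "White", "Harris", "Clark",
    "Lewis", "Walker", "Hall", "Allen", "Young", "King", "Wright", "Scott",
    "Torres", "Hill", "Green", "Adams", "Baker", "Nelson", "Carter",
    "Mitchell", "Perez", "Roberts", "Turner", "Phillips", "Campbell",
    "Parker", "Evans", "Edwards", "Collins", "Stewart", "Sanchez", "Morris",
    "Rogers", "Reed", "Cook", "Morgan", "Bell", "Murphy", "Bailey", "Rivera",
    "Cooper", "Richardson", "Cox", "Howard", "Ward", "Peterson", "Gray",
    "Ramirez", "James", "Watson", "Brooks", "Kelly", "Sanders", "Price",
]
_FORENAMES = [
    "Alice", "Robert", "Maria", "John", "Wei", "Sofia", "David", "Yuki",
    "Elena", "James", "Priya", "Michael", "Anna", "Thomas", "Li", "Sarah",
    "Peter", "Nina", "Carlos", "Emma", "Hiro", "Laura", "Paul", "Ingrid",
    "George", "Fatima", "Henry", "Olga", "Samuel", "Clara", "Victor", "Ruth",
    "Walter", "Diana", "Oscar", "Hannah", "Felix", "Irene", "Leo", "Greta",
]
_JOURNALS = [
    "J Synth Biomed", "Ann Test Data", "Int J Model Organisms",
    "Clin Simul Rep", "Methods Inform", "Arch Comput Biol",
    "Biomed Data Lett", "Exp Corpus Stud",
]

# Bio-entity term table: (surface form, integer vocabulary ID) per type.
# Abstracts are assembled from these so mention offsets and normalization
# ground truth are known exactly.
TERM_TABLE: dict[str, list[tuple[str, int]]] = {
    "gene": [("BRCA1", 672), ("TP53", 7157), ("ACE2", 59272), ("EGFR", 1956),
             ("TNF", 7124), ("CGRP", 796)],
    "disease": [("migraine", 108881), ("influenza", 107251), ("asthma", 101201),
                ("coronavirus infection", 103050), ("melanoma", 108545)],
    "drug": [("aspirin", 201145), ("sumatriptan", 209186), ("ibuprofen", 205228),
             ("metformin", 204835)],
    "species": [("human", 9606), ("mouse", 10090), ("zebrafish", 7955),
                ("rat", 10116)],
    "mutation": [("V600E", 301001), ("C282Y", 301002), ("F508del", 301003)],
}

_INSTITUTIONS = [
    ("Dept. of Neurology", "Jefferson University", "Philadelphia", "PA", "19107", "USA"),
    ("Department of Genetics", "Riverside Institute", "Boston", "MA", "02115", "USA"),
    ("Division of Oncology", "Lakeshore Hospital", "Chicago", "IL", "60611", "USA"),
    ("Department of Medicine", "Northgate College", "Seattle", "WA", "98101", "USA"),
    ("Dept. of Biochemistry", "Harbor Center", "San Diego", "CA", "92093", "USA"),
    ("Division of Cardiology", "Summit University", "Denver", "CO", "80045", "USA"),
]


@dataclass
class WorldConfig:
    """Parameters of a synthetic bibliographic world.

    ``papers_per_author`` is the mean of a shifted-Poisson count (minimum
    one article per author).  ``name_pool_size`` truncates the surname
    pool; values below ``n_authors`` make shared (last name, first initial)
    keys likely.  The coverage fractions control which authors acquire an
    ORCID record or NIH-style PI role, and ``multi_pi_rate`` is the
    fraction of projects credited to two PIs (which the crosswalk must
    filter out).
    """

    n_authors: int = 100
    papers_per_author: float = 4.0
    name_pool_size: int = 40
    year_range: tuple[int, int] = (1990, 2018)
    doi_coverage: float = 0.8
    orcid_coverage: float = 0.4
    pi_coverage: float = 0.3
    multi_pi_rate: float = 0.1
    coauthors_mean: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_authors < 1:
            raise ConfigurationError("n_authors must be >= 1")
        if self.papers_per_author < 1:
            raise ConfigurationError("papers_per_author must be >= 1")
        if self.name_pool_size < 1:
            raise ConfigurationError("name_pool_size must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError("year_range must be (lo, hi) with lo <= hi")
        for name in ("doi_coverage", "orcid_coverage", "pi_coverage", "multi_pi_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TrueWorld:
    """A generated world plus its ground truth.

    ``true_author_of`` maps every author-instance ID to the true author who
    wrote it; it is the reference every evaluation compares against.
    """

    config: WorldConfig
    author_names: dict[int, tuple[str, str]]  # author id -> (last, fore)
    true_author_of: dict[int, int]
    articles: list[ArticleRecord]
    author_instances: list[AuthorInstance]
    orcid_records: list[OrcidRecord] = field(default_factory=list)
    project_records: list[ProjectRecord] = field(default_factory=list)
    mentions: list[EntityMentionRecord] = field(default_factory=list)

    def truth_clustering(self) -> Clustering:
        """The true assignment: one cluster per true author."""
        return Clustering(dict(self.true_author_of))

    def articles_by_pmid(self) -> dict[int, ArticleRecord]:
        return {a.pmid: a for a in self.articles}


def _name_key(last: str, fore: str) -> tuple[str, str]:
    return (last.casefold(), fore[:1].upper())


def generate_world(config: WorldConfig) -> TrueWorld:
    """Build a world deterministically from ``config.seed``.

    Articles are assembled by repeatedly drawing a byline of distinct
    authors who still owe papers, so per-author paper counts follow the
    configured distribution while co-authorship ties authors together.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pool = list(_SURNAMES)
    while len(pool) < config.name_pool_size:
        pool.append(f"Lastname{len(pool)}")
    pool = pool[: config.name_pool_size]

    author_names = {
        aid: (pool[int(rng.integers(len(pool)))],
              _FORENAMES[int(rng.integers(len(_FORENAMES)))])
        for aid in range(1, config.n_authors + 1)
    }

    # paper quota per author: 1 + Poisson(mean - 1)
    quota = {
        aid: 1 + int(rng.poisson(config.papers_per_author - 1.0))
        for aid in author_names
    }

    articles: list[ArticleRecord] = []
    bylines: list[list[int]] = []
    year_lo, year_hi = config.year_range
    pmid = 100000
    while any(v > 0 for v in quota.values()):
        owing = sorted(aid for aid, v in quota.items() if v > 0)
        m = min(len(owing), 1 + int(rng.poisson(max(config.coauthors_mean - 1.0, 0.0))))
        candidates = sorted(rng.choice(owing, size=m, replace=False).tolist())
        # one byline never lists two authors with the same name key: a
        # printed byline cannot distinguish them, so no instance-level
        # ground truth would exist for such a pair
        byline, keys_used = [], set()
        for aid in candidates:
            key = _name_key(*author_names[aid])
            if key not in keys_used:
                keys_used.add(key)
                byline.append(aid)
        rng.shuffle(byline)
        for aid in byline:
            quota[aid] -= 1
        pmid += 1
        year = int(rng.integers(year_lo, year_hi + 1))
        articles.append(ArticleRecord(
            pmid=pmid, pub_year=year,
            journal=_JOURNALS[int(rng.integers(len(_JOURNALS)))],
            doi=f"10.5555/synth.{pmid}" if rng.random() < config.doi_coverage else None,
        ))
        bylines.append([int(a) for a in byline])

    # abstracts with embedded bio-entity mentions
    mentions: list[EntityMentionRecord] = []
    types = list(TERM_TABLE)
    for art in articles:
        k = int(rng.integers(2, 5))
        chosen_types = rng.choice(types, size=k, replace=True)
        parts = ["We studied"]
        art_mentions = []
        text = "We studied"
        for j, etype in enumerate(chosen_types):
            surface, eid = TERM_TABLE[etype][int(rng.integers(len(TERM_TABLE[etype])))]
            sep = " " if j == 0 else (" and " if j == len(chosen_types) - 1 else ", ")
            start = len(text) + len(sep)
            text = text + sep + surface
            art_mentions.append(EntityMentionRecord(
                pmid=art.pmid, start=start, end=start + len(surface),
                mention=surface, entity_type=str(etype), entity_id=eid,
                mutation_detail=("substitution", surface) if etype == "mutation" else None,
            ))
        text += " in a controlled cohort."
        art.title = f"On {art_mentions[0].mention}: study {art.pmid}"
        art.abstract = text
        mentions.extend(art_mentions)

    # author instances + truth map
    first_year = {}
    for art, byline in zip(articles, bylines):
        for aid in byline:
            y = first_year.get(aid)
            if y is None or art.pub_year < y:
                first_year[aid] = art.pub_year

    instances: list[AuthorInstance] = []
    true_author_of: dict[int, int] = {}
    next_inst = 1
    for art, byline in zip(articles, bylines):
        for order, aid in enumerate(byline, start=1):
            last, fore = author_names[aid]
            instances.append(AuthorInstance(
                instance_id=next_inst, pmid=art.pmid, au_order=order,
                last_name=last, fore_name=fore, initials=fore[:1].upper(),
                au_num=len(byline), pub_year=art.pub_year,
                begin_year=first_year[aid],
            ))
            true_author_of[next_inst] = aid
            next_inst += 1

    articles_of: dict[int, list[ArticleRecord]] = {aid: [] for aid in author_names}
    for art, byline in zip(articles, bylines):
        for aid in byline:
            articles_of[aid].append(art)

    # ORCID records for a coverage fraction of authors
    orcid_records: list[OrcidRecord] = []
    for aid in sorted(author_names):
        if rng.random() >= config.orcid_coverage:
            continue
        last, fore = author_names[aid]
        works = [
            OrcidWork(doi=a.doi, title=a.title, journal=a.journal,
                      last_name=last, first_initial=fore[:1].upper())
            for a in articles_of[aid] if rng.random() < 0.8
        ]
        dept, inst, city, state, _zip, country = _INSTITUTIONS[
            int(rng.integers(len(_INSTITUTIONS)))]
        y0 = first_year[aid]
        orcid_records.append(OrcidRecord(
            orcid_id=f"0000-000{int(rng.integers(1, 4))}-{aid:04d}-{int(rng.integers(10000)):04d}",
            works=works,
            employments=[OrcidAffiliation(organization=inst, city=city,
                                          region=state, country=country,
                                          begin_year=y0, role=dept)],
            educations=[OrcidAffiliation(organization=inst, city=city,
                                         region=state, country=country,
                                         begin_year=y0 - 6, end_year=y0 - 1,
                                         role="PhD")],
        ))

    # NIH-style projects: a coverage fraction of authors act as PIs
    project_records: list[ProjectRecord] = []
    serial = 0
    pi_pool = sorted(aid for aid in author_names if rng.random() < config.pi_coverage)
    for aid in pi_pool:
        last, fore = author_names[aid]
        n_projects = 1 + int(rng.integers(0, 2))
        for _ in range(n_projects):
            serial += 1
            outputs = [a.pmid for a in articles_of[aid] if rng.random() < 0.7]
            if not outputs:
                outputs = [articles_of[aid][0].pmid]
            proj = ProjectRecord(
                project_number=f"R01GM{serial:06d}",
                pi_ids=[f"PI{aid:06d}"], pi_names=[(last, fore[:1].upper())],
                pmids=sorted(outputs),
            )
            if len(pi_pool) > 1 and rng.random() < config.multi_pi_rate:
                other = aid
                while other == aid:
                    other = pi_pool[int(rng.integers(len(pi_pool)))]
                olast, ofore = author_names[other]
                proj.pi_ids.append(f"PI{other:06d}")
                proj.pi_names.append((olast, ofore[:1].upper()))
            project_records.append(proj)

    return TrueWorld(
        config=config, author_names=author_names, true_author_of=true_author_of,
        articles=articles, author_instances=instances,
        orcid_records=orcid_records, project_records=project_records,
        mentions=mentions,
    )


def shared_name_keys(world: TrueWorld) -> list[tuple[str, str]]:
    """Name keys shared by at least two distinct true authors."""
    seen: dict[tuple[str, str], set[int]] = {}
    for aid, (last, fore) in world.author_names.items():
        seen.setdefault(_name_key(last, fore), set()).add(aid)
    return sorted(k for k, v in seen.items() if len(v) >= 2)


def perturb_clustering(
    truth: Clustering,
    lump_rate: float,
    split_rate: float,
    seed: int = 0,
    instances: Optional[Sequence[AuthorInstance]] = None,
) -> Clustering:
    """Inject lumping and splitting errors at per-cluster Bernoulli rates.

    Each cluster is independently selected for lumping with probability
    ``lump_rate``: it is merged into a partner cluster, preferring one that
    shares its (last name, first initial) key when ``instances`` are given
    (homonyms are what real disambiguators lump).  Each resulting cluster
    of size >= 2 is independently selected for splitting with probability
    ``split_rate``: a contiguous suffix of its instances (ordered by
    publication year when known — a "career break") moves to a fresh label.

    With both rates zero the output equals ``truth``.
    """
    if not (0.0 <= lump_rate <= 1.0 and 0.0 <= split_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    assignments = dict(truth.assignments)
    clusters = truth.clusters()
    labels = sorted(clusters)

    inst_info: dict[int, AuthorInstance] = {}
    if instances is not None:
        inst_info = {i.instance_id: i for i in instances}

    def cluster_key(label: int) -> Optional[tuple[str, str]]:
        if not inst_info:
            return None
        members = clusters[label]
        info = inst_info.get(members[0])
        if info is None:
            return None
        return _name_key(info.last_name, info.fore_name or info.initials)

    # --- lumping: union-find over labels
    parent = {lab: lab for lab in labels}

    def find(lab: int) -> int:
        while parent[lab] != lab:
            parent[lab] = parent[parent[lab]]
            lab = parent[lab]
        return lab

    keys = {lab: cluster_key(lab) for lab in labels}
    by_key: dict[Optional[tuple[str, str]], list[int]] = {}
    for lab in labels:
        by_key.setdefault(keys[lab], []).append(lab)

    label_pos = {lab: i for i, lab in enumerate(labels)}
    marked = [lab for lab in labels if rng.random() < lump_rate]
    for lab in marked:
        # partner: next same-name-key cluster cyclically, else next cluster
        # in label order; cyclic pairing keeps one Bernoulli mark ~ one
        # realized merge (except the degenerate all-marked cycle)
        group = by_key.get(keys[lab], [])
        if len(group) > 1:
            partner = group[(group.index(lab) + 1) % len(group)]
        elif len(labels) > 1:
            partner = labels[(label_pos[lab] + 1) % len(labels)]
        else:
            continue
        ra, rb = find(lab), find(partner)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, list[int]] = {}
    for lab in labels:
        merged.setdefault(find(lab), []).extend(clusters[lab])
    for root, members in merged.items():
        for inst in members:
            assignments[inst] = root

    # --- splitting
    next_label = truth.max_label() + 1
    for root in sorted(merged):
        members = merged[root]
        if len(members) < 2 or rng.random() >= split_rate:
            continue
        if inst_info:
            members = sorted(
                members,
                key=lambda i: (inst_info[i].pub_year if i in inst_info else 0, i),
            )
        else:
            members = sorted(members)
        cut = int(rng.integers(1, len(members)))
        for inst in members[cut:]:
            assignments[inst] = next_label
        next_label += 1

    return Clustering(assignments)


def truncate_by_year(
    clustering: Clustering,
    instances: Sequence[AuthorInstance],
    cutoff_year: int,
    leak_fraction: float = 0.0,
    seed: int = 0,
) -> Clustering:
    """Unassign instances published after ``cutoff_year``.

    Emulates a disambiguation source whose coverage stops at a cutoff: an
    instance with ``pub_year > cutoff_year`` loses its label, except a
    ``leak_fraction`` Bernoulli subset that is retained (late-indexed
    preprints).  Instances at or before the cutoff are untouched.
    """
    if not (0.0 <= leak_fraction <= 1.0):
        raise ValueError("leak_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    year_of = {i.instance_id: i.pub_year for i in instances}
    kept = {}
    for inst, label in sorted(clustering.assignments.items()):
        year = year_of.get(inst)
        if year is not None and year > cutoff_year:
            if rng.random() < leak_fraction:
                kept[inst] = label
        else:
            kept[inst] = label
    return Clustering(kept)


# ---------------------------------------------------------------------------
# affiliation strings with ground truth

@dataclass
class AffiliationTruth:
    """Expected parse of one generated affiliation string."""

    raw: str
    department: Optional[str]
    institution: Optional[str]
    email: Optional[str]
    zip: Optional[str]
    country: Optional[str]


def generate_affiliation_strings(n: int, seed: int = 0) -> list[AffiliationTruth]:
    """Build affiliation strings from templates, with known field values."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        dept, inst, city, state, zipc, country = _INSTITUTIONS[
            int(rng.integers(len(_INSTITUTIONS)))]
        email = f"user{i}@{inst.split()[0].lower()}.edu" if rng.random() < 0.5 else None
        raw = f"{dept}, {inst}, {city}, {state} {zipc}, {country}."
        if email:
            raw += f" {email}"
        out.append(AffiliationTruth(raw=raw, department=dept, institution=inst,
                                    email=email, zip=zipc, country=country))
    return out


def generate_affiliations(world: TrueWorld, seed: int = 0, parsed_until: int = 10**9):
    """Affiliation records for first authors, one institution per true author.

    Records with ``pub_year <= parsed_until`` carry fine-grained fields (as
    an upstream parser would have produced); later records carry only the
    raw string, which is the situation affiliation propagation repairs.
    """
    from .models import AffiliationRecord

    rng = np.random.default_rng(seed)
    site_of = {
        aid: _INSTITUTIONS[int(rng.integers(len(_INSTITUTIONS)))]
        for aid in sorted(world.author_names)
    }
    year_of = {a.pmid: a.pub_year for a in world.articles}
    records = []
    for inst in world.author_instances:
        if inst.au_order != 1:
            continue
        aid = world.true_author_of[inst.instance_id]
        dept, org, city, state, zipc, country = site_of[aid]
        raw = f"{dept}, {org}, {city}, {state} {zipc}, {country}."
        rec = AffiliationRecord(pmid=inst.pmid, au_order=1, affiliation_order=1,
                                and_id=aid, raw=raw)
        if year_of[inst.pmid] <= parsed_until:
            rec.department, rec.institution = dept, org
            rec.city, rec.state, rec.zip, rec.country = city, state, zipc, country
            rec.affiliation_type = "EDU"
        records.append(rec)
    return records
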