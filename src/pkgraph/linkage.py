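"""Multi-source record linkage around disambiguated authors.

Three linkage tasks share a (last name, first initial) *name key*:

* :func:`build_pi_crosswalk` connects funded-project PIs to disambiguated
  authors through the articles the projects supported, after two filters —
  projects matching no article in the corpus are dropped, and multi-PI
  projects are dropped because article credit cannot be attributed to one
  PI.
* :func:`link_orcid` matches researcher-registry works to corpus articles,
  first on (DOI, name key), then on (title, journal, name key), and emits
  only 1:1 author-to-registry links.
* :func:`propagate_affiliations` carries an author's fine-grained
  affiliation fields forward past a parsing-coverage cutoff when the
  institution did not change, and :func:`parse_affiliation` extracts
  fine-grained fields from a raw affiliation string.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .integrate import IntegratedAssignment
from .models import (
    AffiliationRecord,
    ArticleRecord,
    AuthorInstance,
    OrcidRecord,
    ProjectRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NameKey:
    """Canonicalized (last name, first initial) used as a crosswalk key."""

    last_name: str
    first_initial: str

    @classmethod
    def from_parts(cls, last_name: str, fore: str) -> Optional["NameKey"]:
        last = last_name.strip().casefold()
        initial = fore.strip()[:1].upper()
        if not last or not initial:
            return None
        return cls(last, initial)

    @classmethod
    def of_instance(cls, inst: AuthorInstance) -> Optional["NameKey"]:
        return cls.from_parts(inst.last_name, inst.fore_name or inst.initials)


# ---------------------------------------------------------------------------
# PI <-> article <-> author crosswalk

@dataclass
class PIArticleCrosswalk:
    """The link table (pi_id, pmid, and_id) plus filter bookkeeping.

    ``projects_in == retained + dropped_no_article + dropped_multi_pi``
    is an exact partition of the input projects.
    """

    links: set[tuple[str, int, int]] = field(default_factory=set)
    projects_in: int = 0
    retained: int = 0
    dropped_no_article: int = 0
    dropped_multi_pi: int = 0
    dropped_bad_name: int = 0


def build_pi_crosswalk(
    projects: Sequence[ProjectRecord],
    articles: Sequence[ArticleRecord],
    authors: Sequence[AuthorInstance],
    assignment: IntegratedAssignment,
) -> PIArticleCrosswalk:
    """Link single-PI projects to disambiguated authors through articles.

    For each retained (project, pmid) the PI's name key is matched against
    the article byline; every byline instance with a matching key and an
    assigned label contributes a (pi_id, pmid, and_id) link.
    """
    corpus = {a.pmid for a in articles}
    byline: dict[int, list[AuthorInstance]] = defaultdict(list)
    for inst in authors:
        byline[inst.pmid].append(inst)

    xwalk = PIArticleCrosswalk(projects_in=len(projects))
    for proj in projects:
        matched = [p for p in proj.pmids if p in corpus]
        if not matched:
            xwalk.dropped_no_article += 1
            continue
        if len(proj.pi_ids) >= 2:
            xwalk.dropped_multi_pi += 1
            continue
        pi_id = proj.pi_ids[0]
        last, initial = proj.pi_names[0]
        key = NameKey.from_parts(last, initial)
        if key is None:
            xwalk.dropped_bad_name += 1
            logger.warning("project %s: unparseable PI name %r, skipped",
                           proj.project_number, proj.pi_names[0])
            continue
        xwalk.retained += 1
        for pmid in matched:
            for inst in byline[pmid]:
                if NameKey.of_instance(inst) != key:
                    continue
                and_id = assignment.label_of(inst.instance_id)
                if and_id > 0:
                    xwalk.links.add((pi_id, pmid, and_id))
    return xwalk


# ---------------------------------------------------------------------------
# registry (ORCID-style) linkage

@dataclass(frozen=True)
class OrcidLink:
    """A 1:1 link between a disambiguated author and a registry record.

    ``pass_`` records which feature combination matched first: 1 for
    (DOI, name), 2 for (title, journal, name).
    """

    and_id: int
    orcid_id: str
    pass_: int


_CANON_STRIP = re.compile(r"[^\w\s]")
_CANON_WS = re.compile(r"\s+")


def canonical_text(s: str) -> str:
    """Casefold, strip punctuation and collapse whitespace (title/journal
    matching for the second linkage pass)."""
    return _CANON_WS.sub(" ", _CANON_STRIP.sub(" ", s.casefold())).strip()


def link_orcid(
    orcid_records: Sequence[OrcidRecord],
    articles: Sequence[ArticleRecord],
    authors: Sequence[AuthorInstance],
    assignment: IntegratedAssignment,
) -> list[OrcidLink]:
    """Match registry works to corpus authors and emit 1:1 links.

    Pass 1 matches a work on (DOI, name key); works that fail retry in
    pass 2 on (canonical title, canonical journal, name key).  A candidate
    pair (and_id, orcid_id) is scored by its number of matched works; the
    emitted set is 1:1 in both directions, conflicts resolved by match
    count and ties dropped and logged.
    """
    by_doi: dict[str, int] = {}
    by_title_journal: dict[tuple[str, str], int] = {}
    for art in articles:
        if art.doi:
            by_doi[art.doi.casefold()] = art.pmid
        by_title_journal[(canonical_text(art.title), canonical_text(art.journal))] = art.pmid

    authors_on: dict[int, list[AuthorInstance]] = defaultdict(list)
    for inst in authors:
        authors_on[inst.pmid].append(inst)

    def name_match(pmid: int, key: NameKey) -> list[int]:
        out = []
        for inst in authors_on.get(pmid, ()):
            if NameKey.of_instance(inst) == key:
                and_id = assignment.label_of(inst.instance_id)
                if and_id > 0:
                    out.append(and_id)
        return out

    # candidate scores: (and_id, orcid) -> [n_matches, best_pass]
    scores: dict[tuple[int, str], list[int]] = {}
    for rec in orcid_records:
        for work in rec.works:
            key = NameKey.from_parts(work.last_name, work.first_initial)
            if key is None:
                continue
            pmid, which = None, 0
            if work.doi and work.doi.casefold() in by_doi:
                pmid, which = by_doi[work.doi.casefold()], 1
            else:
                tj = (canonical_text(work.title), canonical_text(work.journal))
                if tj in by_title_journal:
                    pmid, which = by_title_journal[tj], 2
            if pmid is None:
                continue
            for and_id in name_match(pmid, key):
                entry = scores.setdefault((and_id, rec.orcid_id), [0, which])
                entry[0] += 1
                entry[1] = min(entry[1], which)

    # enforce 1:1 by match count, ties dropped
    by_orcid: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for (and_id, orcid_id), (n, which) in scores.items():
        by_orcid[orcid_id].append((n, and_id, which))

    chosen: dict[str, tuple[int, int, int]] = {}
    for orcid_id, cands in by_orcid.items():
        best = max(n for n, _, _ in cands)
        top = [c for c in cands if c[0] == best]
        if len(top) > 1:
            logger.warning("registry record %s: %d authors tied at %d matches, "
                           "dropped", orcid_id, len(top), best)
            continue
        chosen[orcid_id] = top[0]

    by_and: dict[int, list[tuple[int, str, int]]] = defaultdict(list)
    for orcid_id, (n, and_id, which) in chosen.items():
        by_and[and_id].append((n, orcid_id, which))

    links: list[OrcidLink] = []
    for and_id, cands in by_and.items():
        best = max(n for n, _, _ in cands)
        top = sorted(c for c in cands if c[0] == best)
        if len(top) > 1:
            logger.warning("author %d: %d registry records tied at %d matches, "
                           "dropped", and_id, len(top), best)
            continue
        n, orcid_id, which = top[0]
        links.append(OrcidLink(and_id=and_id, orcid_id=orcid_id, pass_=which))
    links.sort(key=lambda l: (l.and_id, l.orcid_id))
    return links


# ---------------------------------------------------------------------------
# affiliation parsing and propagation

_EMAIL = re.compile(r"[\w.+-]+@[\w-]+(?:\.[\w-]+)+")
_US_ZIP = re.compile(r"\b(\d{5})(?:-\d{4})?\b")
_INSTITUTION_KEYWORDS = (
    "univ", "institut", "hospital", "college", "center", "centre", "school",
    "academy", "clinic", "foundation", "laborator",
)
_DEPARTMENT_KEYWORDS = ("dept", "department", "division")
_COUNTRIES = {
    "usa", "united states", "united states of america", "uk",
    "united kingdom", "england", "scotland", "china", "japan", "germany",
    "france", "italy", "spain", "canada", "australia", "india", "brazil",
    "south korea", "korea", "netherlands", "sweden", "switzerland",
    "belgium", "austria", "denmark", "norway", "finland", "poland",
    "russia", "mexico", "israel", "taiwan", "singapore", "ireland",
    "portugal", "greece", "turkey", "egypt", "south africa", "argentina",
    "chile", "new zealand", "czech republic", "hungary", "iran", "thailand",
}


@dataclass
class ParsedAffiliation:
    """Fine-grained fields extracted from one affiliation string."""

    department: Optional[str] = None
    institution: Optional[str] = None
    email: Optional[str] = None
    zip: Optional[str] = None
    country: Optional[str] = None
    location: Optional[str] = None


def parse_affiliation(raw: str) -> ParsedAffiliation:
    """Extract department, institution, email, ZIP and country from a raw
    affiliation string.

    Segment rules: the string is split on commas; the email is found by
    pattern anywhere; the ZIP is the first US 5-digit pattern; the country
    is a gazetteer match on the last segment; the institution is the first
    segment containing an institution keyword (University, Institute,
    Hospital, ...); the department is the first segment containing
    Dept/Department/Division.  Unmatched fields stay absent.
    """
    out = ParsedAffiliation()
    if not raw or not raw.strip():
        return out

    text = raw
    m = _EMAIL.search(text)
    if m:
        out.email = m.group(0).rstrip(".")
        text = text[: m.start()] + text[m.end():]

    segments = [seg.strip() for seg in text.split(",")]
    segments = [s for s in segments if s]
    if not segments:
        return out

    zm = _US_ZIP.search(text)
    if zm:
        out.zip = zm.group(1)

    last = segments[-1].strip(" .;")
    if last.casefold() in _COUNTRIES:
        out.country = last

    for seg in segments:
        low = seg.casefold()
        if out.department is None and any(k in low for k in _DEPARTMENT_KEYWORDS):
            out.department = seg
        if out.institution is None and any(k in low for k in _INSTITUTION_KEYWORDS):
            # a department segment often contains "Division of ..." etc.;
            # institution must not be the department segment itself
            if seg != out.department:
                out.institution = seg

    inst_idx = segments.index(out.institution) if out.institution in segments else None
    if inst_idx is not None:
        tail = segments[inst_idx + 1:]
        if out.country:
            tail = tail[:-1]
        if tail:
            out.location = ", ".join(tail)
    return out


_FINE_FIELDS = ("department", "institution", "email", "zip", "location",
                "country", "city", "state", "affiliation_type", "latitude",
                "longitude", "fips")


def _has_fine_grained(rec: AffiliationRecord) -> bool:
    return rec.institution is not None


def _canonical_institution(rec: AffiliationRecord) -> Optional[str]:
    inst = rec.institution
    if inst is None and rec.raw:
        inst = parse_affiliation(rec.raw).institution
    return canonical_text(inst) if inst else None


def affiliation_coverage(records: Sequence[AffiliationRecord]) -> float:
    """Fraction of records carrying fine-grained fields."""
    if not records:
        return 0.0
    return sum(1 for r in records if _has_fine_grained(r)) / len(records)


def propagate_affiliations(
    affiliations: Sequence[AffiliationRecord],
    article_years: dict[int, int],
    cutoff_year: int,
) -> list[AffiliationRecord]:
    """Carry fine-grained affiliation fields forward past a cutoff year.

    For each author (by ``and_id``), the latest pre-cutoff record with
    fine-grained fields is the donor; each post-cutoff record of the same
    author that lacks fine-grained fields receives the donor's fields iff
    the canonical institution strings match ("the author did not change
    affiliation").  Pre-cutoff records are never modified, so coverage
    never decreases.  Returns new records; inputs are left untouched.
    """
    import copy

    out = [copy.copy(r) for r in affiliations]
    by_author: dict[int, list[AffiliationRecord]] = defaultdict(list)
    for rec in out:
        if rec.and_id is not None and rec.and_id > 0:
            by_author[rec.and_id].append(rec)

    for and_id, recs in by_author.items():
        donors = [r for r in recs
                  if article_years.get(r.pmid, 0) <= cutoff_year
                  and _has_fine_grained(r)]
        if not donors:
            continue
        donor = max(donors, key=lambda r: (article_years.get(r.pmid, 0), r.pmid))
        donor_inst = _canonical_institution(donor)
        if donor_inst is None:
            continue
        for rec in recs:
            if article_years.get(rec.pmid, 0) <= cutoff_year:
                continue
            if _has_fine_grained(rec):
                continue
            if _canonical_institution(rec) != donor_inst:
                continue
            for f in _FINE_FIELDS:
                if getattr(rec, f) is None:
                    setattr(rec, f, getattr(donor, f))
    return out
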