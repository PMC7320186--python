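"""Domain types for bibliographic knowledge-graph records.

The central objects are articles, author *instances* (one row per name
appearing on one article byline), disambiguated-author assignments
(``Clustering``), extracted bio-entity mentions, affiliation rows, ORCID
researcher records, and funded-project records.  These mirror the seven
tabular schemas the toolkit reads and writes (see :mod:`pkgraph.schemas`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Allowed bio-entity types.
ENTITY_TYPES = ("species", "disease", "gene", "drug", "mutation")

#: Allowed affiliation classifications.
AFFILIATION_TYPES = ("COM", "EDU", "EDU-HOS", "GOV", "HOS", "MIL", "ORG", "UNK")


class ValidationError(ValueError):
    """A record violates a schema invariant."""


@dataclass
class ArticleRecord:
    """One article: PubMed-style integer ID plus bibliographic fields."""

    pmid: int
    title: str = ""
    journal: str = ""
    doi: Optional[str] = None
    pub_year: int = 0
    abstract: str = ""

    def validate(self) -> None:
        if self.pmid <= 0:
            raise ValidationError(f"pmid must be positive, got {self.pmid}")


@dataclass
class AuthorInstance:
    """One author name as printed on one article byline.

    ``instance_id`` identifies the (article, byline position) pair;
    ``au_order`` is the 1-based byline position and ``au_num`` the number
    of co-authors on the article.  ``begin_year`` is the year of the
    disambiguated author's first article, when known.
    """

    instance_id: int
    pmid: int
    au_order: int
    last_name: str = ""
    fore_name: str = ""
    initials: str = ""
    suffix: Optional[str] = None
    au_num: int = 1
    pub_year: int = 0
    begin_year: Optional[int] = None

    def validate(self) -> None:
        if self.instance_id <= 0:
            raise ValidationError(f"instance_id must be positive, got {self.instance_id}")
        if not (1 <= self.au_order <= self.au_num):
            raise ValidationError(
                f"au_order {self.au_order} outside [1, au_num={self.au_num}] "
                f"for instance {self.instance_id}"
            )


class Clustering:
    """A (possibly partial) map from author-instance IDs to cluster labels.

    Labels are positive integers; 0 or absence means *unassigned*.  A
    clustering is how any author-name-disambiguation result is represented,
    whether it is ground truth, a noisy input, or an integrated output.
    """

    __slots__ = ("assignments",)

    def __init__(self, assignments: Optional[dict[int, int]] = None):
        self.assignments: dict[int, int] = {}
        if assignments:
            for inst, label in assignments.items():
                if label < 0:
                    raise ValidationError(f"negative cluster label {label} for instance {inst}")
                if label > 0:
                    self.assignments[int(inst)] = int(label)

    def label_of(self, instance_id: int) -> int:
        """Return the cluster label for an instance, 0 if unassigned."""
        return self.assignments.get(instance_id, 0)

    def clusters(self) -> dict[int, list[int]]:
        """Group assigned instance IDs by label (sorted within cluster)."""
        out: dict[int, list[int]] = {}
        for inst, label in self.assignments.items():
            out.setdefault(label, []).append(inst)
        for members in out.values():
            members.sort()
        return out

    def max_label(self) -> int:
        return max(self.assignments.values(), default=0)

    def __len__(self) -> int:
        return len(self.assignments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        return self.assignments == other.assignments

    def __repr__(self) -> str:
        return f"Clustering({len(self.assignments)} assigned, {len(self.clusters())} clusters)"

    def copy(self) -> "Clustering":
        return Clustering(dict(self.assignments))


@dataclass
class EntityMentionRecord:
    """A typed bio-entity mention located in an abstract.

    Offsets are 0-based half-open character positions into the abstract;
    ``mention`` equals ``abstract[start:end]``.  ``entity_id`` is the
    normalized vocabulary ID when normalization succeeded.  Mutations
    additionally carry ``mutation_detail = (mutation_type, normalized_name)``.
    """

    pmid: int
    start: int
    end: int
    mention: str
    entity_type: str
    entity_id: Optional[int] = None
    mutation_detail: Optional[tuple[str, str]] = None

    def validate(self, abstract: Optional[str] = None) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad offsets [{self.start}, {self.end}) for pmid {self.pmid}")
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(f"unknown entity type {self.entity_type!r}")
        if (self.mutation_detail is not None) != (self.entity_type == "mutation"):
            raise ValidationError("mutation_detail present iff entity_type == 'mutation'")
        if abstract is not None:
            if self.end > len(abstract):
                raise ValidationError(f"mention end {self.end} beyond abstract length")
            if abstract[self.start : self.end] != self.mention:
                raise ValidationError(
                    f"mention {self.mention!r} does not match abstract slice "
                    f"{abstract[self.start:self.end]!r}"
                )


@dataclass
class AffiliationRecord:
    """One affiliation string on one byline slot, plus parsed fields.

    ``raw`` is the affiliation string as printed; the remaining optional
    fields are fine-grained items extracted from it (or propagated from an
    earlier record of the same author).  Geocode fields (latitude,
    longitude, fips) are pass-through.
    """

    pmid: int
    au_order: int
    affiliation_order: int = 1
    and_id: Optional[int] = None
    raw: str = ""
    department: Optional[str] = None
    institution: Optional[str] = None
    email: Optional[str] = None
    zip: Optional[str] = None
    location: Optional[str] = None
    country: Optional[str] = None
    city: Optional[str] = None
    state: Optional[str] = None
    affiliation_type: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    fips: Optional[int] = None

    def validate(self) -> None:
        if self.affiliation_order < 1:
            raise ValidationError(f"affiliation_order must be >= 1, got {self.affiliation_order}")
        if self.affiliation_type is not None and self.affiliation_type not in AFFILIATION_TYPES:
            raise ValidationError(f"unknown affiliation_type {self.affiliation_type!r}")


@dataclass
class OrcidWork:
    """One work claimed on an ORCID record."""

    doi: Optional[str]
    title: str
    journal: str
    last_name: str
    first_initial: str


@dataclass
class OrcidAffiliation:
    """One employment or education entry on an ORCID record."""

    organization: str
    city: str = ""
    region: str = ""
    country: str = ""
    begin_year: Optional[int] = None
    end_year: Optional[int] = None
    role: str = ""


@dataclass
class OrcidRecord:
    """A researcher's self-claimed registry record."""

    orcid_id: str
    works: list[OrcidWork] = field(default_factory=list)
    employments: list[OrcidAffiliation] = field(default_factory=list)
    educations: list[OrcidAffiliation] = field(default_factory=list)


@dataclass
class ProjectRecord:
    """A funded project with its PIs and the articles it supported."""

    project_number: str
    subproject_number: Optional[str] = None
    pi_ids: list[str] = field(default_factory=list)
    pi_names: list[tuple[str, str]] = field(default_factory=list)
    pmids: list[int] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.pi_ids) != len(self.pi_names) or not self.pi_ids:
            raise ValidationError(
                f"project {self.project_number}: pi_ids and pi_names must be "
                f"equal-length and non-empty"
            )
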