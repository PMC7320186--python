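"""Readers and writers for the seven tabular knowledge-graph schemas.

Each schema is a CSV file (comma-separated, UTF-8, double-quote escaping)
with a fixed header and column order:

========================  ====================================================
``Author_List``           author instances with disambiguated author IDs
``Bio_entities_Main``     extracted bio-entity mentions with normalized IDs
``Bio_entities_Mutation`` extra normalization detail for mutation mentions
``Affiliations``          affiliation strings plus fine-grained parsed fields
``Researcher_Employment`` employment history linked to disambiguated authors
``Researcher_Education``  educational background linked to disambiguated authors
``NIH_Projects``          project -> article -> PI/author crosswalk rows
========================  ====================================================

Conventions: absent values are empty cells, except the ``AND_ID`` column of
``Author_List`` where an unassigned author is written as ``0``.  Surrogate
``id`` columns are assigned sequentially on write (1-based) and not retained
on read, so write-read-write is byte-stable; the ``id`` of ``Author_List``
is the meaningful ``instance_id`` and *is* retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Any, Callable, Optional, Sequence

from .models import (
    AffiliationRecord,
    AuthorInstance,
    Clustering,
    EntityMentionRecord,
    ProjectRecord,
    ValidationError,
)


class SchemaError(ValueError):
    """File header does not match the schema."""


class RowParseError(ValueError):
    """A data cell could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# flat row types for the join-output schemas

@dataclass
class MutationRow:
    """Normalization detail for one mutation mention (``Main_id`` is the
    foreign key into ``Bio_entities_Main``)."""

    main_id: int
    mention: str
    mutation_type: str
    normalized_name: str


@dataclass
class ResearcherBackgroundRow:
    """One employment or education entry, flattened for the two
    ``Researcher_*`` schemas."""

    and_id: int
    orcid: str
    organization: str
    city: str = ""
    region: Optional[str] = None
    country: str = ""
    begin_year: Optional[str] = None
    end_year: Optional[str] = None
    identifier: Optional[str] = None
    id_source: Optional[str] = None
    department: Optional[str] = None  # employment only
    role: Optional[str] = None  # education only


@dataclass
class NihProjectRow:
    """One crosswalk row: a PI credited on one article of one project."""

    pi_id: str
    pmid: int
    project_number: str
    pi_name: str  # "Last, F" with F the first initial
    and_id: Optional[int] = None
    subproject_number: Optional[str] = None


# ---------------------------------------------------------------------------
# cell codecs

def _s(v: Any) -> str:
    return "" if v is None else str(v)


def _opt_str(cell: str) -> Optional[str]:
    return cell if cell != "" else None


def _opt_int(cell: str) -> Optional[int]:
    return int(cell) if cell != "" else None


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell != "" else None


def _req_int(cell: str) -> int:
    return int(cell)


# ---------------------------------------------------------------------------
# per-schema record <-> cell mappings

AuthorListEntry = tuple[AuthorInstance, int]


def _author_to_cells(entry: AuthorListEntry, _i: int) -> list[str]:
    inst, and_id = entry
    inst.validate()
    if and_id < 0:
        raise ValidationError(f"negative AND_ID {and_id} for instance {inst.instance_id}")
    return [
        str(inst.instance_id), str(inst.pmid), str(and_id), str(inst.au_order),
        inst.last_name, inst.fore_name, inst.initials, _s(inst.suffix),
        str(inst.au_num), str(inst.pub_year), _s(inst.begin_year),
    ]


def _author_from_cells(c: dict[str, str]) -> AuthorListEntry:
    inst = AuthorInstance(
        instance_id=_req_int(c["id"]), pmid=_req_int(c["PMID"]),
        au_order=_req_int(c["AuOrder"]), last_name=c["LastName"],
        fore_name=c["ForeName"], initials=c["Initials"],
        suffix=_opt_str(c["Suffix"]), au_num=_req_int(c["AuNum"]),
        pub_year=_req_int(c["PubYear"]), begin_year=_opt_int(c["BeginYear"]),
    )
    return inst, _req_int(c["AND_ID"])


def _mention_to_cells(m: EntityMentionRecord, i: int) -> list[str]:
    m.validate()
    return [str(i), str(m.pmid), str(m.start), str(m.end), m.mention,
            _s(m.entity_id), m.entity_type]


def _mention_from_cells(c: dict[str, str]) -> EntityMentionRecord:
    etype = c["Type"]
    return EntityMentionRecord(
        pmid=_req_int(c["PMID"]), start=_req_int(c["Start"]), end=_req_int(c["End"]),
        mention=c["Mention"], entity_type=etype, entity_id=_opt_int(c["EntityID"]),
        mutation_detail=("", "") if etype == "mutation" else None,
    )


def _mutation_to_cells(r: MutationRow, _i: int) -> list[str]:
    return [str(r.main_id), r.mention, r.mutation_type, r.normalized_name]


def _mutation_from_cells(c: dict[str, str]) -> MutationRow:
    return MutationRow(main_id=_req_int(c["Main_id"]), mention=c["Mention"],
                       mutation_type=c["MutationType"], normalized_name=c["NormalizedName"])


def _affil_to_cells(a: AffiliationRecord, i: int) -> list[str]:
    a.validate()
    return [
        str(i), str(a.pmid), str(a.au_order), _s(a.and_id), str(a.affiliation_order),
        a.raw, _s(a.department), _s(a.institution), _s(a.email), _s(a.zip),
        _s(a.location), _s(a.country), _s(a.city), _s(a.state), _s(a.affiliation_type),
        _s(a.latitude), _s(a.longitude), _s(a.fips),
    ]


def _affil_from_cells(c: dict[str, str]) -> AffiliationRecord:
    return AffiliationRecord(
        pmid=_req_int(c["PMID"]), au_order=_req_int(c["AuOrder"]),
        and_id=_opt_int(c["AND_ID"]), affiliation_order=_req_int(c["AffiliationOrder"]),
        raw=c["Affiliation"], department=_opt_str(c["Department"]),
        institution=_opt_str(c["Institution"]), email=_opt_str(c["Email"]),
        zip=_opt_str(c["ZipCode"]), location=_opt_str(c["Location"]),
        country=_opt_str(c["Country"]), city=_opt_str(c["City"]),
        state=_opt_str(c["State"]), affiliation_type=_opt_str(c["AffiliationType"]),
        latitude=_opt_float(c["Latitude"]), longitude=_opt_float(c["Longitude"]),
        fips=_opt_int(c["Fips"]),
    )


def _employment_to_cells(r: ResearcherBackgroundRow, i: int) -> list[str]:
    return [str(i), str(r.and_id), r.orcid, _s(r.department), _s(r.begin_year),
            r.organization, r.city, _s(r.region), r.country, _s(r.identifier),
            _s(r.id_source), _s(r.end_year)]


def _employment_from_cells(c: dict[str, str]) -> ResearcherBackgroundRow:
    return ResearcherBackgroundRow(
        and_id=_req_int(c["AND_ID"]), orcid=c["ORCID"], department=_opt_str(c["Department"]),
        begin_year=_opt_str(c["BeginYear"]), organization=c["Organization"],
        city=c["City"], region=_opt_str(c["Region"]), country=c["Country"],
        identifier=_opt_str(c["Identifier"]), id_source=_opt_str(c["IdSource"]),
        end_year=_opt_str(c["EndYear"]),
    )


def _education_to_cells(r: ResearcherBackgroundRow, i: int) -> list[str]:
    return [str(i), str(r.and_id), r.orcid, _s(r.begin_year), r.organization,
            r.city, _s(r.region), r.country, _s(r.identifier), _s(r.id_source),
            _s(r.end_year), _s(r.role)]


def _education_from_cells(c: dict[str, str]) -> ResearcherBackgroundRow:
    return ResearcherBackgroundRow(
        and_id=_req_int(c["AND_ID"]), orcid=c["ORCID"],
        begin_year=_opt_str(c["BeginYear"]), organization=c["Organization"],
        city=c["City"], region=_opt_str(c["Region"]), country=c["Country"],
        identifier=_opt_str(c["Identifier"]), id_source=_opt_str(c["IdSource"]),
        end_year=_opt_str(c["EndYear"]), role=_opt_str(c["Role"]),
    )


def _project_to_cells(r: NihProjectRow, i: int) -> list[str]:
    return [str(i), _s(r.and_id), r.pi_id, str(r.pmid), r.project_number,
            _s(r.subproject_number), r.pi_name]


def _project_from_cells(c: dict[str, str]) -> NihProjectRow:
    return NihProjectRow(
        and_id=_opt_int(c["AND_ID"]), pi_id=c["PI_ID"], pmid=_req_int(c["PMID"]),
        project_number=c["ProjectNumber"],
        subproject_number=_opt_str(c["subProjectNumber"]), pi_name=c["PI_Name"],
    )


@dataclass(frozen=True)
class _Schema:
    name: str
    columns: tuple[str, ...]
    to_cells: Callable[[Any, int], list[str]]
    from_cells: Callable[[dict[str, str]], Any]


SCHEMAS: dict[str, _Schema] = {
    s.name: s
    for s in [
        _Schema("Author_List",
                ("id", "PMID", "AND_ID", "AuOrder", "LastName", "ForeName",
                 "Initials", "Suffix", "AuNum", "PubYear", "BeginYear"),
                _author_to_cells, _author_from_cells),
        _Schema("Bio_entities_Main",
                ("id", "PMID", "Start", "End", "Mention", "EntityID", "Type"),
                _mention_to_cells, _mention_from_cells),
        _Schema("Bio_entities_Mutation",
                ("Main_id", "Mention", "MutationType", "NormalizedName"),
                _mutation_to_cells, _mutation_from_cells),
        _Schema("Affiliations",
                ("id", "PMID", "AuOrder", "AND_ID", "AffiliationOrder", "Affiliation",
                 "Department", "Institution", "Email", "ZipCode", "Location",
                 "Country", "City", "State", "AffiliationType", "Latitude",
                 "Longitude", "Fips"),
                _affil_to_cells, _affil_from_cells),
        _Schema("Researcher_Employment",
                ("id", "AND_ID", "ORCID", "Department", "BeginYear", "Organization",
                 "City", "Region", "Country", "Identifier", "IdSource", "EndYear"),
                _employment_to_cells, _employment_from_cells),
        _Schema("Researcher_Education",
                ("id", "AND_ID", "ORCID", "BeginYear", "Organization", "City",
                 "Region", "Country", "Identifier", "IdSource", "EndYear", "Role"),
                _education_to_cells, _education_from_cells),
        _Schema("NIH_Projects",
                ("id", "AND_ID", "PI_ID", "PMID", "ProjectNumber",
                 "subProjectNumber", "PI_Name"),
                _project_to_cells, _project_from_cells),
    ]
}


def read_schema(path, schema: str) -> list:
    """Read one schema file into records.

    Raises :class:`SchemaError` when the header does not match the schema
    (naming the offending column) and :class:`RowParseError` with the line
    number for an unparseable cell.  ``Author_List`` yields
    ``(AuthorInstance, and_id)`` pairs with ``and_id == 0`` for unassigned.
    """
    try:
        sch = SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}") from None
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header") from None
        if tuple(header) != sch.columns:
            bad = [c for c in header if c not in sch.columns]
            missing = [c for c in sch.columns if c not in header]
            detail = []
            if bad:
                detail.append(f"unknown column(s) {bad}")
            if missing:
                detail.append(f"missing column(s) {missing}")
            if not detail:
                detail.append("columns out of order")
            raise SchemaError(f"{path}: header does not match {schema}: " + "; ".join(detail))
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(sch.columns):
                raise RowParseError(
                    f"expected {len(sch.columns)} cells, got {len(row)}", lineno)
            cells = dict(zip(sch.columns, row))
            try:
                records.append(sch.from_cells(cells))
            except (ValueError, ValidationError) as exc:
                raise RowParseError(str(exc), lineno) from exc
    return records


def write_schema(records: Sequence, schema: str, path) -> None:
    """Write records to a schema file with the canonical header and column
    order.  Records are validated first; a violation raises
    :class:`~pkgraph.models.ValidationError` naming the record index.
    """
    try:
        sch = SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}") from None
    rows = []
    for i, rec in enumerate(records):
        try:
            rows.append(sch.to_cells(rec, i + 1))
        except (ValidationError, AttributeError, TypeError) as exc:
            raise ValidationError(f"record {i} failed {schema} validation: {exc}") from exc
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(sch.columns)
        writer.writerows(rows)


def author_list_from_parts(
    instances: Sequence[AuthorInstance], clustering: Clustering
) -> list[AuthorListEntry]:
    """Pair author instances with their cluster labels for Author_List IO."""
    return [(inst, clustering.label_of(inst.instance_id)) for inst in instances]


def author_list_to_parts(
    entries: Sequence[AuthorListEntry],
) -> tuple[list[AuthorInstance], Clustering]:
    """Split Author_List entries into instances and a Clustering."""
    instances = [inst for inst, _ in entries]
    clustering = Clustering({inst.instance_id: a for inst, a in entries if a > 0})
    return instances, clustering


def rows_to_projects(rows: Sequence[NihProjectRow]) -> list[ProjectRecord]:
    """Aggregate flat crosswalk rows back into project records.

    Rows are grouped by (project number, subproject number); PI identities
    and article PMIDs are collected in first-seen order.
    """
    grouped: dict[tuple[str, Optional[str]], ProjectRecord] = {}
    for row in rows:
        key = (row.project_number, row.subproject_number)
        proj = grouped.get(key)
        if proj is None:
            proj = ProjectRecord(project_number=row.project_number,
                                 subproject_number=row.subproject_number)
            grouped[key] = proj
        if row.pi_id not in proj.pi_ids:
            proj.pi_ids.append(row.pi_id)
            last, _, initial = row.pi_name.partition(", ")
            proj.pi_names.append((last, initial[:1]))
        if row.pmid not in proj.pmids:
            proj.pmids.append(row.pmid)
    return list(grouped.values())


def format_pi_name(last_name: str, first_initial: str) -> str:
    """Render a PI name as stored in the crosswalk schema (``"Last, F"``)."""
    return f"{last_name}, {first_initial}"
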