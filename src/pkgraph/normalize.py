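"""Dictionary-based multi-type bio-entity normalization.

An entity may be referred to by several synonymous surface forms, and one
surface form may map to several vocabulary IDs.  Normalization is an exact
lookup of the canonicalized mention against a per-entity-type dictionary
(a multimap name -> IDs); separate vocabularies for one type are combined
with :func:`merge_dictionaries`, which takes the union of (name, ID) pairs
— exactly how one merges, say, a second disease vocabulary into an
existing linking dictionary.  Within-type ambiguity (one name, several
IDs) is reported as such unless a tie-break policy is configured.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")
_PUNCT = string.punctuation + "–—"


@dataclass(frozen=True)
class CanonicalizationPolicy:
    """How surface forms are folded into dictionary keys.

    The default folds case, collapses internal whitespace and strips
    leading/trailing punctuation; ``exact`` mode disables all folding.
    """

    casefold: bool = True
    collapse_whitespace: bool = True
    strip_punctuation: bool = True

    def __call__(self, name: str) -> str:
        s = name
        if self.strip_punctuation:
            s = s.strip(_PUNCT + " \t")
        if self.collapse_whitespace:
            s = _WS.sub(" ", s).strip()
        if self.casefold:
            s = s.casefold()
        return s


EXACT = CanonicalizationPolicy(casefold=False, collapse_whitespace=False,
                               strip_punctuation=False)
DEFAULT_POLICY = CanonicalizationPolicy()


class TypedDictionary:
    """A per-entity-type multimap canonical-name -> set of IDs, with the
    inverse ID -> names view kept consistent."""

    def __init__(self, entity_type: str,
                 policy: CanonicalizationPolicy = DEFAULT_POLICY):
        self.entity_type = entity_type
        self.policy = policy
        self.names: dict[str, set[int]] = {}
        self.id_names: dict[int, set[str]] = {}

    def add(self, name: str, entity_id: int) -> bool:
        """Add one (name, ID) pair; returns False for an empty name."""
        key = self.policy(name)
        if not key:
            return False
        self.names.setdefault(key, set()).add(entity_id)
        self.id_names.setdefault(entity_id, set()).add(key)
        return True

    def lookup(self, mention: str) -> frozenset[int]:
        return frozenset(self.names.get(self.policy(mention), ()))

    @property
    def n_ids(self) -> int:
        return len(self.id_names)

    @property
    def n_names(self) -> int:
        return len(self.names)

    def pairs(self) -> set[tuple[str, int]]:
        """The canonical (name, ID) pair set — the dictionary's content."""
        return {(name, i) for name, ids in self.names.items() for i in ids}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedDictionary):
            return NotImplemented
        return (self.entity_type == other.entity_type
                and self.names == other.names)

    def __repr__(self) -> str:
        return (f"TypedDictionary({self.entity_type!r}, {self.n_ids} IDs, "
                f"{self.n_names} names)")


@dataclass
class NormalizationResult:
    """Outcome of normalizing one mention.

    ``status``: ``unique`` (one ID), ``ambiguous-resolved`` (several IDs,
    tie-break applied), ``ambiguous-unresolved`` (several IDs, no
    tie-break), or ``unknown`` (no dictionary hit).  ``entity_id`` is
    present exactly for the first two.
    """

    mention: str
    entity_type: str
    status: str
    entity_id: Optional[int] = None
    candidates: frozenset[int] = field(default_factory=frozenset)


@dataclass
class DictionaryStats:
    """Size statistics: ID count, name count, and names-per-ID average
    (rounded to one decimal; undefined for an empty dictionary)."""

    n_ids: int
    n_names: int
    avg_names_per_id: Optional[float]


def build_dictionary(
    entries: Iterable[tuple[str, int]],
    entity_type: str,
    policy: CanonicalizationPolicy = DEFAULT_POLICY,
) -> TypedDictionary:
    """Build a dictionary from (name, ID) pairs.

    Names canonicalize under ``policy``; duplicate pairs collapse; entries
    whose name canonicalizes to the empty string are rejected and counted
    in a log message.
    """
    d = TypedDictionary(entity_type, policy)
    rejected = 0
    for name, entity_id in entries:
        if not d.add(name, int(entity_id)):
            rejected += 1
    if rejected:
        logger.warning("%d entries with empty names rejected (%s)",
                       rejected, entity_type)
    return d


def merge_dictionaries(a: TypedDictionary, b: TypedDictionary) -> TypedDictionary:
    """Union of two same-type dictionaries' (name, ID) pair sets.

    Every lookup answerable in ``a`` or ``b`` is answerable in the merge;
    a name mapped to different IDs by the two inputs becomes ambiguous.
    """
    if a.entity_type != b.entity_type:
        raise ValueError(
            f"cannot merge dictionaries of types {a.entity_type!r} and "
            f"{b.entity_type!r}")
    out = TypedDictionary(a.entity_type, a.policy)
    for src in (a, b):
        for name, ids in src.names.items():
            for i in ids:
                out.names.setdefault(name, set()).add(i)
                out.id_names.setdefault(i, set()).add(name)
    return out


@dataclass(frozen=True)
class AmbiguityTieBreak:
    """Optional within-type ambiguity resolution: prefer the ID with more
    synonyms, then the smallest ID."""

    def __call__(self, candidates: frozenset[int], d: TypedDictionary) -> int:
        return max(candidates, key=lambda i: (len(d.id_names.get(i, ())), -i))


def normalize_mention(
    mention: str,
    entity_type: str,
    dictionary: TypedDictionary,
    tie_break: Optional[AmbiguityTieBreak] = None,
) -> NormalizationResult:
    """Normalize one mention against a dictionary of the same type."""
    if dictionary.entity_type != entity_type:
        raise ValueError(
            f"dictionary is for {dictionary.entity_type!r}, mention is "
            f"{entity_type!r}")
    candidates = dictionary.lookup(mention)
    if not candidates:
        return NormalizationResult(mention, entity_type, "unknown")
    if len(candidates) == 1:
        (eid,) = candidates
        return NormalizationResult(mention, entity_type, "unique", eid, candidates)
    if tie_break is not None:
        eid = tie_break(candidates, dictionary)
        return NormalizationResult(mention, entity_type, "ambiguous-resolved",
                                   eid, candidates)
    return NormalizationResult(mention, entity_type, "ambiguous-unresolved",
                               candidates=candidates)


def average_names_per_id(n_ids: int, n_names: int) -> Optional[float]:
    """Names-per-ID average, rounded to one decimal; None when undefined."""
    if n_ids == 0:
        return None
    return round(n_names / n_ids, 1)


def dictionary_stats(dictionary: TypedDictionary) -> DictionaryStats:
    """(#IDs, #names, avg names per ID) for one dictionary.

    The name count is the number of distinct canonical keys.  For an empty
    dictionary the average is undefined (``None``), not zero.
    """
    n_ids, n_names = dictionary.n_ids, dictionary.n_names
    return DictionaryStats(n_ids, n_names, average_names_per_id(n_ids, n_names))


def read_dictionary_tsv(path, entity_type: str,
                        policy: CanonicalizationPolicy = DEFAULT_POLICY) -> TypedDictionary:
    """Read a 2-column TSV (name, id) dictionary file."""
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            entries.append((cells[0], int(cells[1])))
    return build_dictionary(entries, entity_type, policy)
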