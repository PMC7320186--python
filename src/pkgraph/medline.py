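"""Minimal reader for a MEDLINE-style citation XML subset.

Understands the ``PubmedArticleSet / PubmedArticle / MedlineCitation``
element structure far enough to recover articles and their bylines: PMID,
ArticleTitle, Journal/Title, PubDate/Year, AbstractText and AuthorList.
Anything beyond that subset is ignored; citations without a PMID are
skipped and logged.
"""

from __future__ import annotations

import logging

from lxml import etree

from .models import ArticleRecord, AuthorInstance

logger = logging.getLogger(__name__)


class MedlineParseError(ValueError):
    """Malformed citation XML."""


def _text(node, path: str, default: str = "") -> str:
    found = node.find(path)
    if found is None or found.text is None:
        return default
    return found.text


def read_medline_subset(
    path, first_instance_id: int = 1
) -> list[tuple[ArticleRecord, list[AuthorInstance]]]:
    """Parse a citation XML file into (article, author instances) pairs.

    Author order is preserved as printed; every instance of one article
    shares ``au_num`` and ``pub_year``.  Instance IDs are assigned
    sequentially from ``first_instance_id`` in document order.

    Raises :class:`MedlineParseError` for malformed XML (the message carries
    the parser's position information).
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MedlineParseError(f"malformed XML in {path}: {exc}") from exc

    out: list[tuple[ArticleRecord, list[AuthorInstance]]] = []
    next_id = first_instance_id
    for citation in tree.iter("MedlineCitation"):
        pmid_text = _text(citation, "PMID")
        if not pmid_text.strip():
            logger.warning("citation without PMID skipped")
            continue
        try:
            pmid = int(pmid_text)
        except ValueError:
            logger.warning("citation with non-integer PMID %r skipped", pmid_text)
            continue
        art_el = citation.find("Article")
        if art_el is None:
            art_el = citation  # tolerate flattened fixtures
        title = _text(art_el, "ArticleTitle")
        journal = _text(art_el, "Journal/Title")
        year_text = _text(art_el, "Journal/JournalIssue/PubDate/Year")
        pub_year = int(year_text) if year_text.strip() else 0
        abstract_parts = [
            el.text for el in art_el.findall("Abstract/AbstractText") if el.text
        ]
        abstract = " ".join(abstract_parts)
        doi = None
        for el in art_el.findall("ELocationID"):
            if el.get("EIdType") == "doi" and el.text:
                doi = el.text
        article = ArticleRecord(pmid=pmid, title=title, journal=journal,
                                doi=doi, pub_year=pub_year, abstract=abstract)

        author_els = art_el.findall("AuthorList/Author")
        au_num = len(author_els)
        instances = []
        for order, au in enumerate(author_els, start=1):
            instances.append(AuthorInstance(
                instance_id=next_id, pmid=pmid, au_order=order,
                last_name=_text(au, "LastName"), fore_name=_text(au, "ForeName"),
                initials=_text(au, "Initials"),
                suffix=_text(au, "Suffix") or None,
                au_num=au_num, pub_year=pub_year,
            ))
            next_id += 1
        out.append((article, instances))
    return out
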