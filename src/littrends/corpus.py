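"""Corpus containers and readers/writers for literature records.

A corpus is an ordered list of documents, each carrying a PMID-like
identifier, a publication year, the title+abstract free text, and a set
of MeSH-like subject tags. Readers accept MEDLINE flat files (via
Bio.Medline) or delimited tables; all computation lives downstream.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

from Bio import Medline

logger = logging.getLogger(__name__)

_YEAR_RE = re.compile(r"\b(\d{4})\b")


@dataclass(frozen=True)
class Document:
    """One literature record.

    ``text`` is the title and abstract joined by a single space; ``tags``
    are MeSH-like headings with qualifier suffixes and major-topic
    asterisks already stripped.
    """

    doc_id: str
    year: int
    text: str
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not (1000 <= self.year <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year!r}")
        if not self.text.strip():
            raise ValueError(f"document {self.doc_id}: empty text")


@dataclass
class Corpus:
    """Ordered collection of documents."""

    documents: list[Document]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_id(s): {dup[:5]}")

    @property
    def M(self) -> int:
        return len(self.documents)

    def years(self) -> list[int]:
        return [d.year for d in self.documents]

    def __len__(self) -> int:
        return self.M

    def __iter__(self):
        return iter(self.documents)


def _clean_tag(raw: str) -> str:
    """Normalize one MeSH heading: drop qualifiers after '/', strip '*'."""
    return raw.split("/")[0].replace("*", "").strip()


def _extract_year(dp: str) -> int | None:
    m = _YEAR_RE.search(dp or "")
    return int(m.group(1)) if m else None


def read_medline(path: str) -> Corpus:
    """Parse a MEDLINE flat file (PMID-/DP-/TI-/AB-/MH- tags) into a Corpus.

    Records missing a PMID or a parseable 4-digit year are rejected with a
    logged warning; a file yielding zero valid records is an error.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID")
            if not pmid:
                logger.warning("rejected record without PMID: %s", dict(rec))
                continue
            year = _extract_year(rec.get("DP", ""))
            if year is None:
                logger.warning("rejected PMID %s: no 4-digit year in DP=%r",
                               pmid, rec.get("DP"))
                continue
            title = (rec.get("TI") or "").strip()
            abstract = (rec.get("AB") or "").strip()
            text = " ".join(part for part in (title, abstract) if part)
            if not text:
                logger.warning("rejected PMID %s: empty title and abstract", pmid)
                continue
            tags = frozenset(_clean_tag(t) for t in rec.get("MH", []) if _clean_tag(t))
            docs.append(Document(doc_id=pmid, year=year, text=text, tags=tags))
    if not docs:
        raise ValueError(f"no valid records in {path}")
    return Corpus(docs, provenance=f"medline:{path}")


_DEFAULT_COLUMNS = {
    "id": "doc_id", "year": "year", "title": "title",
    "abstract": "abstract", "tags": "tags",
}


def read_table(path: str, column_map: dict[str, str] | None = None,
               delimiter: str | None = None) -> Corpus:
    """Read a delimited table (CSV or TSV, header row required).

    ``column_map`` maps the logical fields id/year/title/abstract/tags to
    the file's column names; defaults expect columns named doc_id, year,
    title, abstract, tags (tags ';'-delimited within the cell).
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    docs: list[Document] = []
    with open(path, encoding="utf-8", newline="") as handle:
        if delimiter is None:
            sample = handle.readline()
            handle.seek(0)
            delimiter = "\t" if "\t" in sample else ","
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        for logical in ("id", "year", "title", "abstract", "tags"):
            if colmap[logical] not in header:
                raise ValueError(
                    f"missing column {colmap[logical]!r} (for {logical}) in {path}")
        for row in reader:
            doc_id = (row[colmap["id"]] or "").strip()
            if not doc_id:
                logger.warning("rejected row without id: %r", row)
                continue
            try:
                year = int((row[colmap["year"]] or "").strip())
                if not (1000 <= year <= 9999):
                    raise ValueError
            except ValueError:
                logger.warning("rejected %s: unparseable year %r",
                               doc_id, row[colmap["year"]])
                continue
            title = (row[colmap["title"]] or "").strip()
            abstract = (row[colmap["abstract"]] or "").strip()
            text = " ".join(p for p in (title, abstract) if p)
            if not text:
                logger.warning("rejected %s: empty text", doc_id)
                continue
            raw_tags = (row[colmap["tags"]] or "").strip()
            tags = frozenset(t.strip() for t in raw_tags.split(";") if t.strip())
            docs.append(Document(doc_id=doc_id, year=year, text=text, tags=tags))
    if not docs:
        raise ValueError(f"no valid records in {path}")
    return Corpus(docs, provenance=f"table:{path}")


def write_corpus(corpus: Corpus, path: str) -> None:
    """Write a corpus in the tabular dialect read_table accepts (TSV)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "year", "title", "abstract", "tags"])
        for d in corpus:
            writer.writerow([d.doc_id, d.year, d.text, "", ";".join(sorted(d.tags))])


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_table(rows, path: str, columns: list[str] | None = None) -> None:
    """Write a rectangular result table as TSV (header, UTF-8, 6 sig digits).

    ``rows`` may be a pandas DataFrame or a list of dicts sharing keys.
    """
    import pandas as pd

    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            handle.write("\t".join(_fmt(v) for v in row) + "\n")
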