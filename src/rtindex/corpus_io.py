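"""Article input: JATS XML / plain text readers and sentence segmentation.

The segmenter is deliberately rule-based and deterministic: the same string
always yields the same spans, sentence offsets are 0-based half-open
character coordinates into ``methods_text``, and splitting never happens
inside a known abbreviation ("Fig.", "et al.", "i.m.", ...) or an RRID token.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from lxml import etree

from .types import Document, Sentence

#: Case-insensitive section titles accepted as a methods section, alongside
#: any ``sec-type`` attribute containing "method".
METHODS_TITLES = frozenset(
    {
        "methods",
        "materials and methods",
        "experimental procedures",
        "star methods",
        "methods and materials",
        "subjects and methods",
        "online methods",
    }
)

# Tokens whose trailing period never ends a sentence.
_ABBREVIATIONS = frozenset(
    {
        "no.", "fig.", "figs.", "al.", "i.m.", "i.p.", "i.v.", "s.c.",
        "e.g.", "i.e.", "vs.", "dr.", "prof.", "st.", "ca.", "cf.",
        "approx.", "cat.", "inc.", "co.", "ltd.", "u.s.", "u.k.", "etc.",
        "ref.", "refs.", "vol.", "eq.", "eqs.", "resp.", "wk.", "hr.",
        "min.", "sec.", "mol.", "wt.",
    }
)

_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+)")


def segment_sentences(text: str) -> list[Sentence]:
    """Split *text* into sentences with exact character spans.

    Spans cover every non-whitespace character; concatenating them with the
    original inter-span whitespace reconstructs the input exactly.
    """
    if not text or not text.strip():
        return []

    split_points: list[tuple[int, int]] = []  # (sentence_end, next_start)
    for m in _BOUNDARY_RE.finditer(text):
        sent_end = m.end(1)
        next_start = m.end(2)
        if next_start >= len(text):
            continue
        nxt = text[next_start]
        if not (nxt.isupper() or nxt.isdigit()):
            continue
        prefix = text[: sent_end]
        token = prefix.rsplit(None, 1)[-1] if prefix.split() else prefix
        token_l = token.lstrip("([{\"'").lower()
        if token_l in _ABBREVIATIONS:
            continue
        # single-letter uppercase initials ("J. Smith") and RRID-adjacent
        # tokens; lowercase unit tokens like "2 h." do end sentences
        bare = token.lstrip("([{\"'").rstrip(".")
        if len(bare) == 1 and bare.isalpha() and bare.isupper():
            continue
        if "rrid" in token_l:
            continue
        split_points.append((sent_end, next_start))

    first = len(text) - len(text.lstrip())
    last = len(text.rstrip())
    sentences: list[Sentence] = []
    start = first
    for sent_end, next_start in split_points:
        if sent_end <= start:
            continue
        sentences.append(
            Sentence(index=len(sentences), start=start, end=sent_end, text=text[start:sent_end])
        )
        start = next_start
    if start < last:
        sentences.append(
            Sentence(index=len(sentences), start=start, end=last, text=text[start:last])
        )
    return sentences


def _sec_is_methods(sec: etree._Element, titles: frozenset[str]) -> bool:
    sec_type = (sec.get("sec-type") or "").lower()
    if "method" in sec_type:
        return True
    title_el = sec.find("title")
    if title_el is not None:
        title = " ".join("".join(title_el.itertext()).split()).lower()
        if title in titles:
            return True
    return False


def extract_methods_section(
    root: etree._Element, titles: frozenset[str] = METHODS_TITLES
) -> str:
    """Concatenate the paragraph text of every methods-like section.

    A section counts as methods when its ``sec-type`` contains "method" or
    its title is in the (case-insensitive) title lexicon.  Nested matches
    inside an already-matched section are not double-counted; text inside
    ``supplementary-material`` elements is ignored (a methods section that
    only points at a supplementary file is effectively empty).  Returns ""
    when nothing matches.
    """
    matched: list[etree._Element] = []
    for sec in root.iter("sec"):
        if any(anc in matched for anc in sec.iterancestors("sec")):
            continue
        if _sec_is_methods(sec, titles):
            matched.append(sec)

    paragraphs: list[str] = []
    for sec in matched:
        for p in sec.iter("p"):
            if any(anc.tag == "supplementary-material" for anc in p.iterancestors()):
                continue
            text = "".join(p.itertext())
            if text.strip():
                paragraphs.append(text)
    return "\n\n".join(paragraphs)


def read_jats(xml_bytes: bytes | str) -> Document:
    """Parse a JATS (PMC OA dialect) article into a :class:`Document`.

    Malformed XML raises ``lxml.etree.XMLSyntaxError``.  When no methods
    section is found the document is still returned, with empty
    ``methods_text`` and ``methods_missing=True``.
    """
    if isinstance(xml_bytes, str):
        xml_bytes = xml_bytes.encode("utf-8")
    root = etree.fromstring(xml_bytes)

    journal = _first_text(root, ".//journal-meta//journal-title") or ""
    issn = _first_text(root, ".//journal-meta/issn") or ""
    doc_id = (
        _first_text(root, ".//article-meta/article-id[@pub-id-type='pmc']")
        or _first_text(root, ".//article-meta/article-id")
        or "unknown"
    )
    year_text = _first_text(root, ".//article-meta/pub-date/year")
    if year_text is None:
        raise ValueError("JATS front matter lacks a publication year")
    year = int(year_text)

    body = root.find("body")
    methods_text = extract_methods_section(body if body is not None else root)
    missing = not methods_text.strip()
    return Document(
        doc_id=doc_id,
        journal=journal,
        issn=issn,
        year=year,
        methods_text=methods_text,
        sentences=segment_sentences(methods_text),
        methods_missing=missing,
    )


def _first_text(root: etree._Element, xpath: str) -> Optional[str]:
    el = root.find(xpath)
    if el is None:
        return None
    text = "".join(el.itertext()).strip()
    return text or None


def read_plaintext(
    methods_text: str, doc_id: str, journal: str, issn: str, year: int
) -> Document:
    """Build a Document from raw methods text plus explicit metadata."""
    return Document(
        doc_id=doc_id,
        journal=journal,
        issn=issn,
        year=year,
        methods_text=methods_text,
        sentences=segment_sentences(methods_text),
        methods_missing=not methods_text.strip(),
    )


def read_plaintext_file(path: str | Path) -> Document:
    """Read a ``.txt`` methods file with a ``.json`` metadata sidecar.

    The sidecar must provide ``doc_id``, ``journal`` and ``year``; ``issn``
    is optional.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    return read_plaintext(
        methods_text=path.read_text(encoding="utf-8"),
        doc_id=str(meta["doc_id"]),
        journal=meta["journal"],
        issn=meta.get("issn", ""),
        year=int(meta["year"]),
    )


class ImpactFactorTable:
    """Journal impact factors keyed by (ISSN, year) with name fallback."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame
        self._by_issn = {
            (r.issn, int(r.year)): float(r.jif)
            for r in frame.itertuples()
            if isinstance(r.issn, str) and r.issn.strip()
        }
        self._by_journal = {
            (str(r.journal).strip().lower(), int(r.year)): float(r.jif)
            for r in frame.itertuples()
        }

    def __len__(self) -> int:
        return len(self._frame)

    def lookup(self, journal: str, issn: str, year: int) -> Optional[float]:
        """ISSN is preferred as the join key when present."""
        if issn and (issn, year) in self._by_issn:
            return self._by_issn[(issn, year)]
        return self._by_journal.get((journal.strip().lower(), year))


def read_if_table(csv_path: str | Path) -> ImpactFactorTable:
    """Load an impact-factor CSV with columns journal, issn, year, jif."""
    frame = pd.read_csv(csv_path, dtype={"issn": str})
    required = {"journal", "issn", "year", "jif"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"impact-factor CSV missing columns: {sorted(missing)}")
    try:
        frame["jif"] = pd.to_numeric(frame["jif"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric jif value: {exc}") from exc
    dup = frame.duplicated(subset=["journal", "year"], keep=False)
    if dup.any():
        rows = frame.loc[dup, ["journal", "year"]].drop_duplicates()
        raise ValueError(
            "duplicate (journal, year) rows in impact-factor CSV: "
            + "; ".join(f"{r.journal}/{r.year}" for r in rows.itertuples())
        )
    frame["issn"] = frame["issn"].fillna("")
    return ImpactFactorTable(frame)
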