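"""Deterministic detection of rigor-criterion statements and key resources.

The engine is a set of per-criterion keyword/phrase lexicons with proximity
constraints (e.g. a blinding term must co-occur with an investigator or
analysis term in the same sentence), not a learned classifier: identical
text always yields identical hits, with confidence 1.0.  An optional
trainable IOB2 sequence tagger with the same output shape lives in
:mod:`rtindex.tagger`.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .config import load_lexicons, load_software_registry
from .identifiability import AUTHORITY_TYPE_MAP, CatalogExtractor, parse_rrids
from .types import (
    Criterion,
    CriterionHit,
    Document,
    ResourceMention,
    ResourceType,
)

# re-exported trainable-tagger interface (pattern engine remains the default)
from .tagger import TaggerModel, tag, train_tagger  # noqa: F401

_CLONE_RE = re.compile(r"\bclone\s+([A-Za-z0-9][\w.\-]*)")
_URL_RE = re.compile(r"https?://\S+", re.IGNORECASE)
_ANTIBODY_NOUN_RE = re.compile(r"(?:\b([A-Za-z0-9][\w.\-/]*)\s+)?antibod(?:y|ies)\b")
_ANTI_TARGET_RE = re.compile(r"\banti[-‐–][A-Za-z0-9.][\w.\-/]*")
_CELL_CODE_RE = re.compile(r"\b([A-Z][A-Za-z0-9.\-]*\d[A-Za-z0-9.\-]*)\s+cells?\b")
_CELL_LINE_APPOS_RE = re.compile(r"cell lines?,?\s+([A-Z][\w.\-]+)")
_PLASMID_NAME_RE = re.compile(r"\bp[A-Z][A-Za-z0-9]{2,}[\w().\-/]*")
_PLASMID_CONTEXT_RE = re.compile(
    r"plasmid|vector|subclon|\bclon(?:ed|ing)\b|construct|transfect|Addgene",
    re.IGNORECASE,
)
_OLIGO_CONTEXT_RE = re.compile(
    r"\boligonucleotides?\b|\bprimers?\b|\bsiRNAs?\b|\bshRNAs?\b|\bsgRNAs?\b",
    re.IGNORECASE,
)
_OLIGO_SEQ_RE = re.compile(r"[ACGTU]{8,}")
_SOFTWARE_TRIGGER_RE = re.compile(
    r"\b([A-Z][\w+.\-]*(?:\s+[A-Z][\w+.\-]*)?)\s+software\b"
)
_GENERIC_ANTIBODY_HEADS = {
    "the", "a", "an", "primary", "secondary", "following", "this", "each",
    "all", "other", "with", "and", "or", "using",
}
_GENERIC_SOFTWARE_HEADS = {"The", "This", "That", "Custom", "Commercial", "All", "A"}


def _word_bounded(needle: str) -> re.Pattern:
    return re.compile(r"(?<![\w])" + re.escape(needle) + r"(?![\w])")


class PatternEngine:
    """Compiled lexicons for criterion and resource detection."""

    def __init__(
        self,
        lexicons: Optional[dict] = None,
        software_registry: Optional[list[str]] = None,
    ):
        lex = lexicons or load_lexicons()
        self.lexicons = lex
        self.software_registry = (
            software_registry
            if software_registry is not None
            else load_software_registry()
        )
        self._criterion_patterns: dict[Criterion, list[re.Pattern]] = {
            Criterion(name): [re.compile(p, re.IGNORECASE) for p in pats]
            for name, pats in lex["criteria"].items()
        }
        self._blinding_terms = [re.compile(p, re.IGNORECASE) for p in lex["blinding_terms"]]
        self._blinding_context = [c.lower() for c in lex["blinding_context"]]
        self._sex_terms = [re.compile(p, re.IGNORECASE) for p in lex["sex_terms"]]
        self._sex_exclusions = [c.lower() for c in lex["sex_exclusions"]]
        self._vendors = sorted(lex["vendors"], key=len, reverse=True)
        self._vendor_patterns = [(_word_bounded(v), v) for v in self._vendors]
        self._cell_lines = sorted(lex["cell_lines"], key=len, reverse=True)
        self._cell_line_patterns = [(_word_bounded(c), c) for c in self._cell_lines]
        self._strain_patterns = [re.compile(p) for p in lex["organism_strains"]]
        self._species_patterns = [
            re.compile(p, re.IGNORECASE) for p in lex["organism_species"]
        ]
        self._registry_patterns = [
            (_word_bounded(name), name)
            for name in sorted(self.software_registry, key=len, reverse=True)
        ]
        self._catalog = CatalogExtractor(lex)

    # ------------------------------------------------------------------
    # rigor criteria
    # ------------------------------------------------------------------

    def criterion_hits_in_sentence(self, text: str, index: int) -> list[CriterionHit]:
        hits: list[CriterionHit] = []
        for criterion, patterns in self._criterion_patterns.items():
            for pat in patterns:
                m = pat.search(text)
                if m:
                    hits.append(CriterionHit(criterion, index, m.group(0)))
                    break
        hits.extend(self._blinding_hit(text, index))
        hits.extend(self._sex_hit(text, index))
        return hits

    def _blinding_hit(self, text: str, index: int) -> list[CriterionHit]:
        # lexicon BLINDING patterns (double/single-blind) are self-sufficient
        # and handled with the other criteria; bare blinding terms here
        # additionally require an investigator/analysis term in the sentence.
        low = text.lower()
        if not any(ctx in low for ctx in self._blinding_context):
            return []
        for pat in self._blinding_terms:
            m = pat.search(text)
            if m:
                return [CriterionHit(Criterion.BLINDING, index, m.group(0))]
        return []

    def _sex_hit(self, text: str, index: int) -> list[CriterionHit]:
        masked = text
        low = text.lower()
        for excl in self._sex_exclusions:
            start = 0
            while (pos := low.find(excl, start)) >= 0:
                masked = masked[:pos] + " " * len(excl) + masked[pos + len(excl):]
                start = pos + len(excl)
        for pat in self._sex_terms:
            m = pat.search(masked)
            if m:
                return [CriterionHit(Criterion.SEX, index, text[m.start(): m.end()])]
        return []

    def detect_rigor_criteria(self, document: Document) -> list[CriterionHit]:
        """All criterion statements; at most one hit per (criterion, sentence)."""
        hits: list[CriterionHit] = []
        for sent in document.sentences:
            seen: set[Criterion] = set()
            for hit in self.criterion_hits_in_sentence(sent.text, sent.index):
                if hit.criterion not in seen:
                    seen.add(hit.criterion)
                    hits.append(hit)
        return hits

    # ------------------------------------------------------------------
    # key resources
    # ------------------------------------------------------------------

    def _find_vendor(self, text: str) -> Optional[str]:
        for pat, vendor in self._vendor_patterns:
            if pat.search(text):
                return vendor
        return None

    def _mentions_in_sentence(self, text: str, index: int) -> list[ResourceMention]:
        candidates: list[tuple[ResourceMention, tuple[int, int]]] = []

        def add(mention: ResourceMention, span: tuple[int, int]) -> None:
            candidates.append((mention, span))

        vendor = self._find_vendor(text)
        clone_m = _CLONE_RE.search(text)
        clone = clone_m.group(1) if clone_m else None
        url_m = _URL_RE.search(text)

        # --- antibodies ---
        seen_spans: list[tuple[int, int]] = []
        for m in _ANTIBODY_NOUN_RE.finditer(text):
            head = m.group(1)
            if head is not None and head.lower() in _GENERIC_ANTIBODY_HEADS:
                head = None
            name = f"{head} antibody" if head else "antibody"
            add(
                ResourceMention(ResourceType.ANTIBODY, index, name, vendor=vendor, clone_id=clone),
                m.span(),
            )
            seen_spans.append(m.span())
        for m in _ANTI_TARGET_RE.finditer(text):
            if any(s <= m.start() < e for s, e in seen_spans):
                continue
            name = m.group(0)
            tail = text[m.end():].split(maxsplit=1)
            if tail:
                nxt = tail[0].strip(",;.:)")
                if nxt in {"antibody", "antibodies", "IgG"} or nxt.endswith("RNA"):
                    name = f"{name} {nxt}"
            add(
                ResourceMention(ResourceType.ANTIBODY, index, name, vendor=vendor, clone_id=clone),
                m.span(),
            )

        # --- organisms ---
        strain_found = False
        for pat in self._strain_patterns:
            for m in pat.finditer(text):
                strain_found = True
                add(
                    ResourceMention(ResourceType.ORGANISM, index, m.group(0), vendor=vendor),
                    m.span(),
                )
        if not strain_found:
            for pat in self._species_patterns:
                m = pat.search(text)
                if m:
                    add(
                        ResourceMention(ResourceType.ORGANISM, index, m.group(0), vendor=vendor),
                        m.span(),
                    )
                    break

        # --- cell lines ---
        cell_names: set[str] = set()
        for pat, name in self._cell_line_patterns:
            m = pat.search(text)
            if m and name not in cell_names:
                cell_names.add(name)
                add(
                    ResourceMention(ResourceType.CELL_LINE, index, name, vendor=vendor),
                    m.span(),
                )
        for pat in (_CELL_CODE_RE, _CELL_LINE_APPOS_RE):
            for m in pat.finditer(text):
                name = m.group(1)
                if name in cell_names or any(name in c for c in cell_names):
                    continue
                cell_names.add(name)
                add(
                    ResourceMention(ResourceType.CELL_LINE, index, name, vendor=vendor),
                    m.span(1),
                )

        # --- plasmids ---
        if _PLASMID_CONTEXT_RE.search(text):
            for m in _PLASMID_NAME_RE.finditer(text):
                add(
                    ResourceMention(ResourceType.PLASMID, index, m.group(0), vendor=vendor),
                    m.span(),
                )

        # --- oligonucleotides ---
        if _OLIGO_CONTEXT_RE.search(text):
            seqs = _OLIGO_SEQ_RE.findall(text)
            if seqs:
                for seq in dict.fromkeys(seqs):
                    add(ResourceMention(ResourceType.OLIGO, index, seq), (0, 0))
            else:
                add(ResourceMention(ResourceType.OLIGO, index, "oligonucleotide"), (0, 0))

        # --- software ---
        software_names: set[str] = set()
        for pat, name in self._registry_patterns:
            m = pat.search(text)
            if m and not any(name in s for s in software_names):
                software_names.add(name)
                add(
                    ResourceMention(
                        ResourceType.SOFTWARE, index, name,
                        url=url_m.group(0) if url_m else None,
                    ),
                    m.span(),
                )
        for m in _SOFTWARE_TRIGGER_RE.finditer(text):
            name = m.group(1)
            if name in software_names or name in _GENERIC_SOFTWARE_HEADS:
                continue
            software_names.add(name)
            add(
                ResourceMention(
                    ResourceType.SOFTWARE, index, name,
                    url=url_m.group(0) if url_m else None,
                ),
                m.span(1),
            )

        # --- catalog numbers and first-pass RRID attachment ---
        for mention, span in candidates:
            if span != (0, 0) and mention.resource_type is not ResourceType.SOFTWARE:
                mention.catalog_number = self._catalog.extract(text, span)
        rrids = parse_rrids(text)
        for record in rrids:
            rtype = AUTHORITY_TYPE_MAP.get(record.authority.upper())
            if rtype is None:
                continue
            pos = text.find(record.raw)
            best = None
            best_dist = None
            for mention, span in candidates:
                if mention.resource_type is not rtype or mention.rrid is not None:
                    continue
                dist = abs(pos - span[1]) if span[1] <= pos else (span[1] - pos) + 0.5
                if best_dist is None or dist < best_dist:
                    best, best_dist = mention, dist
            if best is not None:
                best.rrid = record

        return [m for m, _ in candidates]

    def detect_resources(self, document: Document) -> list[ResourceMention]:
        """First-pass resource mentions with co-occurring metadata attached."""
        mentions: list[ResourceMention] = []
        for sent in document.sentences:
            mentions.extend(self._mentions_in_sentence(sent.text, sent.index))
        return mentions


_DEFAULT_ENGINE: Optional[PatternEngine] = None


def _engine() -> PatternEngine:
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = PatternEngine()
    return _DEFAULT_ENGINE


def detect_rigor_criteria(document: Document) -> list[CriterionHit]:
    """Module-level convenience using the packaged default lexicons."""
    return _engine().detect_rigor_criteria(document)


def detect_resources(document: Document) -> list[ResourceMention]:
    """Module-level convenience using the packaged default lexicons."""
    return _engine().detect_resources(document)


def merge_hits(hits: Iterable[CriterionHit]) -> dict[Criterion, bool]:
    """Collapse hits into a presence map over all nine criteria."""
    presence = {c: False for c in Criterion}
    for hit in hits:
        presence[hit.criterion] = True
    return presence


def dedupe_mentions(mentions: Iterable[ResourceMention]) -> list[ResourceMention]:
    """Unique resource entities per document.

    Key: (resource_type, case-folded name, catalog-number-or-RRID).  Within
    a duplicate group the mention with the most identifying metadata wins.
    """

    def richness(m: ResourceMention) -> int:
        return sum(
            x is not None for x in (m.rrid, m.catalog_number, m.vendor, m.clone_id, m.url)
        )

    best: dict[tuple, ResourceMention] = {}
    order: list[tuple] = []
    for m in mentions:
        ident = m.rrid.normalized if m.rrid else m.catalog_number
        key = (m.resource_type, m.name.casefold(), ident)
        if key not in best:
            best[key] = m
            order.append(key)
        elif richness(m) > richness(best[key]):
            best[key] = m
    return [best[k] for k in order]
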