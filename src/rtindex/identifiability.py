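"""Resource identifiability: RRID parsing, catalog numbers, and the
relaxed second pass.

An RRID (Research Resource Identifier) is a persistent unique identifier of
the form ``RRID:AUTHORITY_ACCESSION`` (e.g. ``RRID:AB_777714`` for an
antibody, ``RRID:SCR_004166`` for software).  The grammar here is purely
syntactic — no live registry resolution is attempted; whether an accession
actually exists at SciCrunch is an extension point, not a build requirement.

A mention counts as *identifiable* when it carries metadata sufficient to
pin down the exact resource: for antibodies a catalog number or RRID; for
organisms, cell lines and plasmids an RRID or vendor+catalog pair; for
software an RRID, a URL, or a registry-listed distinct name.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from .config import ScoreConfig, load_lexicons, load_software_registry
from .types import Document, ResourceMention, ResourceType, RRIDRecord

# Case-insensitive "RRID:" tag, optional space, authority token, "_" or ":",
# accession possibly containing nested colons ("RRID:IMSR_JAX:000664").
RRID_RE = re.compile(r"RRID:\s*([A-Za-z]+)[_:]([A-Za-z0-9][A-Za-z0-9_:\-]*)", re.IGNORECASE)

#: RRID authority prefix → resource class implied by it.
AUTHORITY_TYPE_MAP: dict[str, ResourceType] = {
    "AB": ResourceType.ANTIBODY,
    "CVCL": ResourceType.CELL_LINE,
    "SCR": ResourceType.SOFTWARE,
    "ADDGENE": ResourceType.PLASMID,
    "IMSR": ResourceType.ORGANISM,
    "BDSC": ResourceType.ORGANISM,
    "MGI": ResourceType.ORGANISM,
    "ZFIN": ResourceType.ORGANISM,
    "MMRRC": ResourceType.ORGANISM,
    "RGD": ResourceType.ORGANISM,
    "WB": ResourceType.ORGANISM,
    "FLYBASE": ResourceType.ORGANISM,
    "DGGR": ResourceType.ORGANISM,
}

_URL_RE = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)


def parse_rrids(text: str) -> list[RRIDRecord]:
    """Extract all non-overlapping RRIDs, left to right.

    Both dialects seen in the literature are accepted: ``RRID:AB_777714``
    and ``RRID: AB_777714`` (space after the tag).
    """
    records = []
    for m in RRID_RE.finditer(text):
        records.append(
            RRIDRecord(authority=m.group(1), accession=m.group(2), raw=m.group(0))
        )
    return records


def rrid_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of every RRID match (used to mask catalog search)."""
    return [(m.start(), m.end()) for m in RRID_RE.finditer(text)]


def _parentheticals(text: str) -> list[tuple[int, int]]:
    """Top-level ``(...)`` spans, half-open, content coordinates included."""
    spans = []
    depth = 0
    start = -1
    for i, ch in enumerate(text):
        if ch == "(":
            if depth == 0:
                start = i
            depth += 1
        elif ch == ")" and depth > 0:
            depth -= 1
            if depth == 0:
                spans.append((start, i + 1))
    return spans


class CatalogExtractor:
    """Finds catalog-like tokens near a resource-name anchor."""

    def __init__(self, lexicons: Optional[dict] = None):
        lex = lexicons or load_lexicons()
        # case sensitivity is encoded per-pattern with inline (?i:) groups
        self._cue_patterns = [re.compile(p) for p in lex["catalog_cue_patterns"]]
        self._vendor_code = re.compile(lex["catalog_vendor_code_pattern"])
        self._vendors = sorted(lex["vendors"], key=len, reverse=True)

    def _region_has_vendor(self, region: str) -> bool:
        low = region.lower()
        return any(v.lower() in low for v in self._vendors)

    def extract(self, sentence: str, anchor_span: tuple[int, int]) -> Optional[str]:
        """Nearest catalog token in a parenthetical/clause after the anchor."""
        masked = _mask_spans(sentence, rrid_spans(sentence))
        regions: list[tuple[int, int]] = [
            (s, e) for s, e in _parentheticals(sentence) if e > anchor_span[0]
        ]
        # fall back to the clause from the anchor to the end of the sentence
        regions.append((anchor_span[1], len(sentence)))
        for rs, re_ in regions:
            region = masked[rs:re_]
            for pat in self._cue_patterns:
                m = pat.search(region)
                if m:
                    return m.group(1)
            if self._region_has_vendor(region):
                m = self._vendor_code.search(region)
                if m:
                    return m.group(1)
        return None


def _mask_spans(text: str, spans: Sequence[tuple[int, int]]) -> str:
    chars = list(text)
    for s, e in spans:
        for i in range(s, e):
            chars[i] = " "
    return "".join(chars)


def extract_catalog_number(
    sentence: str, anchor_span: tuple[int, int], lexicons: Optional[dict] = None
) -> Optional[str]:
    """Convenience wrapper over :class:`CatalogExtractor` for one call."""
    return CatalogExtractor(lexicons).extract(sentence, anchor_span)


def is_identifiable(
    mention: ResourceMention,
    software_registry: Optional[Iterable[str]] = None,
    config: Optional[ScoreConfig] = None,
) -> bool:
    """Decide whether a mention is uniquely identifiable.

    Rules by type: ANTIBODY — catalog number or RRID; ORGANISM, CELL_LINE,
    PLASMID — RRID, or vendor and catalog number together; SOFTWARE — RRID,
    URL, or a registry-listed distinct name; OLIGO — treated as identifiable
    for reporting, but oligos never enter the score.
    """
    cfg = config or ScoreConfig()
    t = mention.resource_type
    if t is ResourceType.ANTIBODY:
        if mention.catalog_number or mention.rrid:
            return True
        if (
            cfg.clone_with_vendor_identifies_antibody
            and mention.clone_id
            and mention.vendor
        ):
            return True
        return False
    if t in (ResourceType.ORGANISM, ResourceType.CELL_LINE, ResourceType.PLASMID):
        if mention.rrid:
            return True
        return bool(mention.vendor and mention.catalog_number)
    if t is ResourceType.SOFTWARE:
        if mention.rrid or mention.url or _URL_RE.search(mention.name):
            return True
        registry = list(software_registry) if software_registry is not None else load_software_registry()
        return mention.name in registry
    if t is ResourceType.OLIGO:
        return True
    raise ValueError(f"unknown resource type: {t}")


def annotate_identifiability(
    mentions: Iterable[ResourceMention],
    software_registry: Optional[Iterable[str]] = None,
    config: Optional[ScoreConfig] = None,
) -> list[ResourceMention]:
    """Set ``mention.identifiable`` in place for every mention; returns list."""
    registry = (
        list(software_registry)
        if software_registry is not None
        else load_software_registry()
    )
    out = []
    for m in mentions:
        m.identifiable = is_identifiable(m, registry, config)
        out.append(m)
    return out


def _nearest_preceding_name(sentence: str, rrid_start: int) -> Optional[str]:
    """Nearest resource-like noun phrase before an unattached RRID.

    Walks back over the parenthetical the RRID sits in (if any) and takes
    the short token run immediately preceding it.
    """
    prefix = sentence[:rrid_start]
    # position just before the opening paren of the RRID's parenthetical
    open_idx = prefix.rfind("(")
    head = prefix[:open_idx] if open_idx >= 0 else prefix
    head = head.strip().rstrip(",;:")
    if not head:
        return None
    tokens = head.split()
    chunk: list[str] = []
    for tok in reversed(tokens):
        cleaned = tok.strip(",;:")
        if not cleaned:
            break
        # stop at verbs/stopwords that clearly end a noun phrase
        if cleaned.lower() in {
            "the", "a", "an", "into", "from", "with", "using", "used",
            "was", "were", "and", "or", "in", "of", "by", "for", "to",
        }:
            break
        chunk.append(cleaned)
        if len(chunk) >= 4:
            break
    if not chunk:
        return None
    return " ".join(reversed(chunk))


def relaxed_second_pass(
    document: Document,
    mentions: list[ResourceMention],
    rrids: Optional[list[RRIDRecord]] = None,
) -> list[ResourceMention]:
    """Attach document RRIDs left unclaimed by the first pass.

    The first detection pass is precision-oriented; an RRID in the text is
    near-certain evidence that a key resource is being described, so a
    second, less stringent pass runs whenever unattached RRIDs remain.  For
    each such RRID the nearest preceding resource-like noun phrase in the
    same sentence becomes the mention name, and the RRID authority fixes the
    resource type.  Existing mentions are never removed or downgraded; new
    or augmented mentions are flagged ``second_pass=True``.
    """
    out = list(mentions)
    claimed = {m.rrid.normalized for m in out if m.rrid is not None}

    for sent in document.sentences:
        for record in parse_rrids(sent.text):
            if record.normalized in claimed:
                continue
            rtype = AUTHORITY_TYPE_MAP.get(record.authority.upper())
            # Prefer augmenting an RRID-less same-sentence mention of the
            # implied (or unknown) type.
            target = None
            for m in out:
                if m.sentence_index != sent.index or m.rrid is not None:
                    continue
                if rtype is None or m.resource_type is rtype:
                    target = m
                    break
            if target is not None:
                target.rrid = record
                target.second_pass = True
            else:
                start = sent.text.find(record.raw)
                name = _nearest_preceding_name(sent.text, max(start, 0)) or record.normalized
                out.append(
                    ResourceMention(
                        resource_type=rtype or ResourceType.SOFTWARE,
                        sentence_index=sent.index,
                        name=name,
                        rrid=record,
                        second_pass=True,
                    )
                )
            claimed.add(record.normalized)
    return out
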