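"""End-to-end per-document scoring: detect → second pass → dedupe → score."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .config import ScoreConfig
from .detectors import PatternEngine, dedupe_mentions, merge_hits
from .identifiability import annotate_identifiability, relaxed_second_pass
from .types import CriterionHit, Document, PaperScore, ResourceMention
from .scoring import score_paper


@dataclass
class DocumentAnalysis:
    score: PaperScore
    hits: list[CriterionHit]
    mentions: list[ResourceMention]


def analyze_document(
    document: Document,
    config: Optional[ScoreConfig] = None,
    engine: Optional[PatternEngine] = None,
) -> DocumentAnalysis:
    """Run the full pipeline on one document.

    Steps: pattern-engine detection of criteria and resources, the relaxed
    second pass for unattached RRIDs, entity de-duplication,
    identifiability classification, and composite scoring.  A document with
    empty methods text scores 0 and is flagged not applicable.
    """
    cfg = config or ScoreConfig()
    eng = engine or PatternEngine()
    hits = eng.detect_rigor_criteria(document)
    mentions = eng.detect_resources(document)
    mentions = relaxed_second_pass(document, mentions)
    mentions = dedupe_mentions(mentions)
    annotate_identifiability(mentions, eng.software_registry, cfg)
    score = score_paper(
        merge_hits(hits),
        mentions,
        cfg,
        doc_id=document.doc_id,
        journal=document.journal,
        issn=document.issn,
        year=document.year,
    )
    return DocumentAnalysis(score=score, hits=hits, mentions=mentions)


def score_document(
    document: Document,
    config: Optional[ScoreConfig] = None,
    engine: Optional[PatternEngine] = None,
) -> PaperScore:
    """Convenience wrapper returning only the :class:`PaperScore`."""
    return analyze_document(document, config, engine).score


def score_corpus(
    documents: Iterable[Document],
    config: Optional[ScoreConfig] = None,
    engine: Optional[PatternEngine] = None,
) -> list[DocumentAnalysis]:
    """Analyze many documents with one shared engine instance."""
    eng = engine or PatternEngine()
    cfg = config or ScoreConfig()
    return [analyze_document(doc, cfg, eng) for doc in documents]
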