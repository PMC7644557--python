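"""Core domain containers shared across the pipeline.

A :class:`Document` holds one article's methods-section text together with
journal/year metadata and its deterministic sentence segmentation.  Detector
outputs (:class:`CriterionHit`, :class:`ResourceMention`) point back into the
sentence list by index, so every piece of evidence stays anchored to a exact
character span of the original text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Criterion(str, Enum):
    """The nine scored rigor-reporting criteria.

    IRB/CONSENT cover human-subjects ethics, IACUC covers vertebrate-animal
    ethics; RANDOMIZATION, BLINDING, POWER and SEX are study-design items;
    CELL_AUTH/CELL_CONTAM cover cell-line authentication and mycoplasma
    contamination checks (conditional on a cell line being used).
    """

    IRB = "IRB"
    CONSENT = "CONSENT"
    IACUC = "IACUC"
    RANDOMIZATION = "RANDOMIZATION"
    BLINDING = "BLINDING"
    POWER = "POWER"
    SEX = "SEX"
    CELL_AUTH = "CELL_AUTH"
    CELL_CONTAM = "CELL_CONTAM"


class ResourceType(str, Enum):
    """Key biological resource classes whose identifiability is assessed."""

    ANTIBODY = "ANTIBODY"
    ORGANISM = "ORGANISM"
    CELL_LINE = "CELL_LINE"
    PLASMID = "PLASMID"
    OLIGO = "OLIGO"
    SOFTWARE = "SOFTWARE"


#: Resource types whose identifiability contributes to the 5-point resource
#: component.  Plasmids are detected and reported but unscored; oligos never
#: affect the score.
SCOREABLE_RESOURCE_TYPES = (
    ResourceType.ANTIBODY,
    ResourceType.ORGANISM,
    ResourceType.CELL_LINE,
    ResourceType.SOFTWARE,
)


@dataclass(frozen=True)
class Sentence:
    """One segmented sentence: 0-based half-open span into the methods text."""

    index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sentence span [{self.start}, {self.end})")


@dataclass
class Document:
    """One article's methods section plus journal/year metadata."""

    doc_id: str
    journal: str
    issn: str
    year: int
    methods_text: str
    sentences: list[Sentence] = field(default_factory=list)
    methods_missing: bool = False

    def __post_init__(self) -> None:
        if not (1900 <= self.year <= 2100):
            raise ValueError(f"implausible publication year: {self.year}")

    def validate_spans(self) -> None:
        """Check the sentence-span invariants against methods_text."""
        prev_end = -1
        for sent in self.sentences:
            if sent.start <= prev_end and prev_end >= 0:
                raise ValueError("overlapping or unordered sentence spans")
            if sent.end > len(self.methods_text):
                raise ValueError("sentence span exceeds text length")
            if self.methods_text[sent.start : sent.end] != sent.text:
                raise ValueError("sentence text does not match its span")
            prev_end = sent.end


@dataclass(frozen=True)
class RRIDRecord:
    """A parsed Research Resource Identifier (e.g. ``RRID:AB_777714``)."""

    authority: str
    accession: str
    raw: str

    @property
    def normalized(self) -> str:
        """Canonical ``AUTHORITY_ACCESSION`` form used in reports."""
        return f"{self.authority}_{self.accession}"

    @classmethod
    def from_normalized(cls, token: str) -> "RRIDRecord":
        m = re.fullmatch(r"([A-Za-z]+)[_:]([A-Za-z0-9_:\-]+)", token)
        if m is None:
            raise ValueError(f"not a normalized RRID token: {token!r}")
        return cls(authority=m.group(1), accession=m.group(2), raw=token)


@dataclass(frozen=True)
class CriterionHit:
    """One detected rigor-criterion statement with its evidence span."""

    criterion: Criterion
    sentence_index: int
    evidence: str
    confidence: float = 1.0


@dataclass
class ResourceMention:
    """One detected key-resource mention and its identifying metadata."""

    resource_type: ResourceType
    sentence_index: int
    name: str
    vendor: Optional[str] = None
    catalog_number: Optional[str] = None
    clone_id: Optional[str] = None
    rrid: Optional[RRIDRecord] = None
    url: Optional[str] = None
    second_pass: bool = False
    identifiable: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("resource mention requires a non-empty name")


@dataclass
class PaperScore:
    """Per-paper composite score: rigor (0-5) + resource (0-5) points."""

    doc_id: str
    journal: str
    issn: str
    year: int
    rigor_points: float
    resource_points: float
    total: float
    blocks: dict[str, dict[str, bool]]
    resource_counts: dict[ResourceType, dict[str, int]]
    criteria: dict[Criterion, bool]
    applicable: bool


@dataclass
class JournalYearSummary:
    """Journal-year aggregate: the RTI and its component rates."""

    journal: str
    issn: str
    year: int
    n_scored: int
    n_zero: int
    rti: float
    sd: float
    criterion_rates: dict[Criterion, float]
    identifiability_rates: dict[ResourceType, dict[str, float]]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    n: int
    coefficient: float
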