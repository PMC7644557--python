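"""Per-paper composite scoring: 5 rigor points + 5 resource points.

The rigor half scores block adherence: human-subjects ethics (IRB or
consent) and animal ethics (IACUC) — merged into one ethics block by
default — plus randomization, blinding, power analysis, sex reporting, and
cell-line authentication/contamination.  The authentication block is
conditional: it only applies when a cell line is actually detected, and
either an authentication or a contamination statement earns the full block.

The resource half scores identifiability: for each detected scoreable
resource type (antibody, organism, cell line, software) the fraction of
unique mentions that are identifiable, averaged over types and scaled to 5.
Plasmids are recorded but unscored; oligonucleotides never affect the score.

A paper with no criteria and no resource mentions is "not applicable" and
scores 0.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

from .config import ScoreConfig
from .identifiability import is_identifiable
from .types import (
    Criterion,
    PaperScore,
    ResourceMention,
    ResourceType,
    SCOREABLE_RESOURCE_TYPES,
)

MERGED_BLOCKS = ("ethics", "randomization", "blinding", "power", "sex", "cell_auth")
STRICT_BLOCKS = (
    "ethics_human", "iacuc", "randomization", "blinding", "power", "sex", "cell_auth"
)


def blocks_for_mode(ethics_mode: str) -> tuple[str, ...]:
    return MERGED_BLOCKS if ethics_mode == "merged" else STRICT_BLOCKS


def block_addressed(presence: dict[Criterion, bool], block: str) -> bool:
    """Map the 9-criterion presence map onto one rigor block."""
    if block == "ethics":
        return (
            presence.get(Criterion.IRB, False)
            or presence.get(Criterion.CONSENT, False)
            or presence.get(Criterion.IACUC, False)
        )
    if block == "ethics_human":
        return presence.get(Criterion.IRB, False) or presence.get(Criterion.CONSENT, False)
    if block == "iacuc":
        return presence.get(Criterion.IACUC, False)
    if block == "cell_auth":
        return presence.get(Criterion.CELL_AUTH, False) or presence.get(
            Criterion.CELL_CONTAM, False
        )
    return presence.get(Criterion(block.upper()), False)


def score_from_counts(
    blocks: dict[str, dict[str, bool]],
    resource_counts: dict[ResourceType, dict[str, int]],
    config: Optional[ScoreConfig] = None,
) -> tuple[float, float, float]:
    """(rigor_points, resource_points, total) from block flags and counts.

    Raises ``ValueError`` when a type reports more identifiable than
    detected mentions (or identifiable with nothing detected).
    """
    cfg = config or ScoreConfig()

    applicable = [b for b, f in blocks.items() if f["applicable"]]
    if applicable:
        weights = {b: cfg.block_weights.get(b, 1.0) for b in applicable}
        wsum = sum(weights.values())
        addressed_w = sum(weights[b] for b in applicable if blocks[b]["addressed"])
        rigor = 5.0 * addressed_w / wsum
    else:
        rigor = 0.0

    ratios: dict[ResourceType, float] = {}
    for rtype, counts in resource_counts.items():
        detected = counts.get("detected", 0)
        identifiable = counts.get("identifiable", 0)
        if identifiable > detected:
            raise ValueError(
                f"{rtype.value}: identifiable ({identifiable}) exceeds detected ({detected})"
            )
        if rtype in SCOREABLE_RESOURCE_TYPES and detected > 0:
            ratios[rtype] = identifiable / detected
    if ratios:
        weights = {t: cfg.type_weights.get(t.value, 1.0) for t in ratios}
        wsum = sum(weights.values())
        resource = 5.0 * sum(weights[t] * r for t, r in ratios.items()) / wsum
    else:
        resource = 0.0

    total = rigor + resource
    if cfg.rounding == "half_up":
        total = float(math.floor(total + 0.5))
    return rigor, resource, total


def score_paper(
    presence_map: dict[Criterion, bool],
    mentions: Iterable[ResourceMention],
    config: Optional[ScoreConfig] = None,
    *,
    doc_id: str = "",
    journal: str = "",
    issn: str = "",
    year: int = 1900,
) -> PaperScore:
    """Score one paper from its criterion presence map and unique mentions.

    Mentions are expected to be de-duplicated; any mention whose
    ``identifiable`` flag is unset is classified here with the default
    rules.
    """
    cfg = config or ScoreConfig()
    mentions = list(mentions)
    presence = {c: bool(presence_map.get(c, False)) for c in Criterion}

    counts: dict[ResourceType, dict[str, int]] = {
        t: {"detected": 0, "identifiable": 0} for t in ResourceType
    }
    for m in mentions:
        flag = m.identifiable if m.identifiable is not None else is_identifiable(m, config=cfg)
        counts[m.resource_type]["detected"] += 1
        counts[m.resource_type]["identifiable"] += int(flag)

    has_cell_line = counts[ResourceType.CELL_LINE]["detected"] > 0
    blocks = {}
    for b in blocks_for_mode(cfg.ethics_mode):
        blocks[b] = {
            "applicable": True if b != "cell_auth" else has_cell_line,
            "addressed": block_addressed(presence, b),
        }

    applicable = any(presence.values()) or len(mentions) > 0
    if applicable:
        rigor, resource, total = score_from_counts(blocks, counts, cfg)
    else:
        rigor = resource = total = 0.0

    return PaperScore(
        doc_id=doc_id,
        journal=journal,
        issn=issn,
        year=year,
        rigor_points=rigor,
        resource_points=resource,
        total=total,
        blocks=blocks,
        resource_counts=counts,
        criteria=presence,
        applicable=applicable,
    )


def score_rate(n_scored: int, n_total: int) -> float:
    """Percentage of analyzed papers that received a non-zero score.

    Reported to one decimal place (half-up), e.g. 1,381,072 scored of
    1,578,964 analyzed → 87.5.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_scored <= n_total:
        raise ValueError("n_scored must lie in [0, n_total]")
    return math.floor(1000.0 * n_scored / n_total + 0.5) / 10.0
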