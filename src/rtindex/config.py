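"""Configuration: pattern lexicons, software registry, and scoring options.

Lexicons ship as editable JSON inside the package (``rtindex/data``); every
loader accepts an optional path so a user can swap in their own lists without
touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional


def _load_packaged_json(name: str):
    with resources.files("rtindex.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_lexicons(path: Optional[str | Path] = None) -> dict:
    """Load the criterion/resource pattern lexicons (packaged default)."""
    if path is not None:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    return _load_packaged_json("lexicons.json")


def load_software_registry(path: Optional[str | Path] = None) -> list[str]:
    """Load the known-software registry; names on it count as identifiable."""
    if path is not None:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    return _load_packaged_json("software_registry.json")


@dataclass
class ScoreConfig:
    """Options controlling the 0-10 composite score.

    ethics_mode
        ``"merged"`` (default): IRB, consent and IACUC statements satisfy a
        single ethics block, so purely human or purely animal studies are not
        penalized for the ethics section they cannot have.  ``"strict"``:
        human ethics (IRB/consent) and animal ethics (IACUC) are separate
        blocks.
    rounding
        ``None`` keeps scores continuous; ``"half_up"`` rounds the total to
        the nearest integer (half away from zero).
    block_weights / type_weights
        Optional relative weights for rigor blocks / resource types; equal
        weighting by default.  Weights are renormalized over the applicable
        blocks (resp. detected types) so each section keeps its 5-point cap.
    """

    ethics_mode: str = "merged"
    rounding: Optional[str] = None
    block_weights: dict[str, float] = field(default_factory=dict)
    type_weights: dict[str, float] = field(default_factory=dict)
    clone_with_vendor_identifies_antibody: bool = False

    def __post_init__(self) -> None:
        if self.ethics_mode not in ("merged", "strict"):
            raise ValueError(f"unknown ethics_mode: {self.ethics_mode!r}")
        if self.rounding not in (None, "half_up"):
            raise ValueError(f"unknown rounding mode: {self.rounding!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)
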