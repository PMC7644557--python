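"""Composite 0-10 scoring: endpoints, caps, block rules, monotonicity."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtindex.config import ScoreConfig
from rtindex.scoring import (
    MERGED_BLOCKS,
    STRICT_BLOCKS,
    score_from_counts,
    score_paper,
    score_rate,
)
from rtindex.types import Criterion, ResourceMention, ResourceType


def _mention(rtype: ResourceType, name: str, identifiable: bool) -> ResourceMention:
    m = ResourceMention(rtype, 0, name)
    m.identifiable = identifiable
    return m


ALL_PRESENT = {c: True for c in Criterion}
NONE_PRESENT = {c: False for c in Criterion}


class TestEndpoints:
    def test_everything_addressed_and_identifiable_scores_ten(self):
        mentions = [
            _mention(ResourceType.ANTIBODY, "a", True),
            _mention(ResourceType.CELL_LINE, "c", True),
            _mention(ResourceType.SOFTWARE, "s", True),
        ]
        ps = score_paper(ALL_PRESENT, mentions)
        assert ps.total == 10.0
        assert ps.rigor_points == 5.0
        assert ps.resource_points == 5.0

    def test_empty_paper_scores_zero_not_applicable(self):
        ps = score_paper(NONE_PRESENT, [])
        assert ps.total == 0.0
        assert not ps.applicable

    def test_rigor_section_caps_at_exactly_five(self):
        ps = score_paper(ALL_PRESENT, [_mention(ResourceType.CELL_LINE, "c", False)])
        assert ps.rigor_points == 5.0

    def test_resource_section_caps_at_exactly_five(self):
        mentions = [
            _mention(ResourceType.ANTIBODY, f"ab{i}", True) for i in range(5)
        ] + [_mention(ResourceType.SOFTWARE, "ImageJ", True)]
        ps = score_paper(NONE_PRESENT, mentions)
        assert ps.resource_points == 5.0


class TestBlockRules:
    def test_merged_ethics_no_cell_lines_two_of_five(self):
        # SEX and RANDOMIZATION addressed; 5 applicable blocks (no cell line
        # detected, so the authentication block is dropped) -> 5 * 2/5 = 2.0
        presence = dict(NONE_PRESENT)
        presence[Criterion.SEX] = True
        presence[Criterion.RANDOMIZATION] = True
        ps = score_paper(presence, [])
        assert ps.rigor_points == pytest.approx(2.0)
        assert ps.total == pytest.approx(2.0)

    def test_cell_auth_block_applicable_only_with_cell_line(self):
        presence = dict(NONE_PRESENT)
        presence[Criterion.CELL_AUTH] = True
        without = score_paper(presence, [])
        assert not without.blocks["cell_auth"]["applicable"]
        with_line = score_paper(presence, [_mention(ResourceType.CELL_LINE, "c", False)])
        assert with_line.blocks["cell_auth"]["applicable"]
        assert with_line.blocks["cell_auth"]["addressed"]

    def test_either_contamination_or_auth_fills_the_block(self):
        for crit in (Criterion.CELL_AUTH, Criterion.CELL_CONTAM):
            presence = dict(NONE_PRESENT)
            presence[crit] = True
            ps = score_paper(presence, [_mention(ResourceType.CELL_LINE, "c", False)])
            assert ps.blocks["cell_auth"]["addressed"]

    def test_merged_mode_any_ethics_statement_suffices(self):
        for crit in (Criterion.IRB, Criterion.CONSENT, Criterion.IACUC):
            presence = dict(NONE_PRESENT)
            presence[crit] = True
            ps = score_paper(presence, [])
            assert ps.blocks["ethics"]["addressed"]

    def test_strict_mode_separates_human_and_animal_ethics(self):
        cfg = ScoreConfig(ethics_mode="strict")
        presence = dict(NONE_PRESENT)
        presence[Criterion.IACUC] = True
        ps = score_paper(presence, [], cfg)
        assert ps.blocks["iacuc"]["addressed"]
        assert not ps.blocks["ethics_human"]["addressed"]

    def test_half_antibodies_identifiable_scores_half_section(self):
        mentions = [_mention(ResourceType.ANTIBODY, f"ab{i}", i < 2) for i in range(4)]
        ps = score_paper(NONE_PRESENT, mentions)
        assert ps.resource_points == pytest.approx(2.5)

    def test_plasmids_and_oligos_recorded_but_unscored(self):
        mentions = [
            _mention(ResourceType.PLASMID, "pX", False),
            _mention(ResourceType.OLIGO, "ACGT", True),
            _mention(ResourceType.ANTIBODY, "ab", True),
        ]
        ps = score_paper(NONE_PRESENT, mentions)
        assert ps.resource_points == pytest.approx(5.0)  # only the antibody counts
        assert ps.resource_counts[ResourceType.PLASMID]["detected"] == 1


class TestExhaustiveOracle:
    def test_all_block_patterns_match_closed_form(self):
        """All 2^7 strict-mode block patterns, no resources, vs brute force."""
        bit_to_criterion = {
            "ethics_human": Criterion.IRB,
            "iacuc": Criterion.IACUC,
            "randomization": Criterion.RANDOMIZATION,
            "blinding": Criterion.BLINDING,
            "power": Criterion.POWER,
            "sex": Criterion.SEX,
            "cell_auth": Criterion.CELL_AUTH,
        }
        cfg = ScoreConfig(ethics_mode="strict")
        for bits in itertools.product([False, True], repeat=7):
            pattern = dict(zip(STRICT_BLOCKS, bits))
            presence = dict(NONE_PRESENT)
            for block, bit in pattern.items():
                if bit:
                    presence[bit_to_criterion[block]] = True
            ps = score_paper(presence, [], cfg)
            # brute force: cell_auth inapplicable without a cell line
            applicable = [b for b in STRICT_BLOCKS if b != "cell_auth"]
            expected = 5.0 * sum(pattern[b] for b in applicable) / len(applicable)
            if not any(presence.values()):
                expected = 0.0
            assert ps.total == pytest.approx(expected), pattern


class TestScoreRate:
    def test_published_corpus_counts(self):
        assert score_rate(1_381_072, 1_578_964) == 87.5

    @pytest.mark.parametrize("n, total, expected", [(0, 10, 0.0), (7, 8, 87.5), (10, 10, 100.0)])
    def test_simple_fractions(self, n, total, expected):
        assert score_rate(n, total) == expected

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            score_rate(0, 0)


class TestInvariants:
    def test_identifiable_exceeding_detected_errors(self):
        blocks = {b: {"applicable": True, "addressed": False} for b in MERGED_BLOCKS}
        with pytest.raises(ValueError):
            score_from_counts(blocks, {ResourceType.ANTIBODY: {"detected": 0, "identifiable": 1}})

    @given(
        bits=st.lists(st.booleans(), min_size=9, max_size=9),
        detected=st.integers(0, 6),
        identifiable=st.integers(0, 6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_structure(self, bits, detected, identifiable):
        presence = dict(zip(Criterion, bits))
        identifiable = min(identifiable, detected)
        mentions = [
            _mention(ResourceType.ANTIBODY, f"m{i}", i < identifiable)
            for i in range(detected)
        ]
        ps = score_paper(presence, mentions)
        assert 0.0 <= ps.rigor_points <= 5.0
        assert 0.0 <= ps.resource_points <= 5.0
        assert ps.total == pytest.approx(ps.rigor_points + ps.resource_points)
        assert 0.0 <= ps.total <= 10.0
        if not ps.applicable:
            assert ps.total == 0.0

    @given(
        bits=st.lists(st.booleans(), min_size=9, max_size=9),
        flip=st.integers(0, 8),
        detected=st.integers(0, 5),
        identifiable=st.integers(0, 5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_addressing_a_block_never_decreases_total(self, bits, flip, detected, identifiable):
        presence = dict(zip(Criterion, bits))
        identifiable = min(identifiable, detected)
        mentions = [
            _mention(ResourceType.SOFTWARE, f"tool{i}", i < identifiable)
            for i in range(detected)
        ]
        base = score_paper(presence, mentions).total
        upgraded = dict(presence)
        upgraded[list(Criterion)[flip]] = True
        assert score_paper(upgraded, mentions).total >= base - 1e-12

    @given(
        bits=st.lists(st.booleans(), min_size=9, max_size=9),
        detected=st.integers(1, 5),
        identifiable=st.integers(0, 4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_identifiable_flip_never_decreases_total(self, bits, detected, identifiable):
        presence = dict(zip(Criterion, bits))
        identifiable = min(identifiable, detected - 1)
        mentions = [
            _mention(ResourceType.ORGANISM, f"org{i}", i < identifiable)
            for i in range(detected)
        ]
        base = score_paper(presence, mentions).total
        mentions[identifiable].identifiable = True  # flip one more to identifiable
        assert score_paper(presence, mentions).total >= base - 1e-12

    def test_ten_requires_perfection(self):
        presence = dict(ALL_PRESENT)
        mentions = [
            _mention(ResourceType.ANTIBODY, "a", True),
            _mention(ResourceType.ANTIBODY, "b", False),
        ]
        assert score_paper(presence, mentions).total < 10.0
        mentions[1].identifiable = True
        assert score_paper(presence, mentions).total == 10.0
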