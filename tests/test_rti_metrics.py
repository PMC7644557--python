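"""Journal-year aggregation, rates, correlations, percentiles, trends."""

from __future__ import annotations

import numpy as np
import pytest

from rtindex.corpus_io import read_if_table
from rtindex.rti_metrics import (
    NoDenominatorError,
    aggregate_journal_year,
    authentication_rate,
    compare_with_jif,
    identifiability_rate,
    pearson,
    percentile_ranks,
    spearman,
    trend_table,
    vertebrate_subset,
)
from rtindex.scoring import score_paper
from rtindex.types import Criterion, CriterionHit, Document, PaperScore, ResourceType


def _paper(journal="J", year=2018, total=4.0, issn="", criteria=None) -> PaperScore:
    presence = {c: False for c in Criterion}
    presence.update(criteria or {})
    return PaperScore(
        doc_id="d",
        journal=journal,
        issn=issn,
        year=year,
        rigor_points=total,
        resource_points=0.0,
        total=total,
        blocks={},
        resource_counts={t: {"detected": 0, "identifiable": 0} for t in ResourceType},
        criteria=presence,
        applicable=total > 0,
    )


class TestAggregate:
    def test_mean_of_three(self):
        papers = [_paper(total=t) for t in (2, 4, 6)]
        (summary,) = aggregate_journal_year(papers, min_n=1)
        assert summary.rti == pytest.approx(4.0)
        assert summary.n_scored == 3

    def test_zero_only_group_not_emitted(self):
        papers = [_paper(total=0.0) for _ in range(5)]
        assert aggregate_journal_year(papers, min_n=1) == []

    def test_zero_scores_excluded_but_counted(self):
        papers = [_paper(total=t) for t in (0, 0, 3, 5)]
        (summary,) = aggregate_journal_year(papers, min_n=1)
        assert summary.rti == pytest.approx(4.0)
        assert summary.n_zero == 2

    def test_order_invariance(self):
        papers = [_paper(journal=j, total=t) for j, t in
                  [("A", 2), ("B", 6), ("A", 4), ("B", 2), ("A", 6)]]
        fwd = aggregate_journal_year(papers, min_n=1)
        rev = aggregate_journal_year(list(reversed(papers)), min_n=1)
        assert [(s.journal, s.rti, s.n_scored) for s in fwd] == [
            (s.journal, s.rti, s.n_scored) for s in rev
        ]

    def test_min_n_suppression(self):
        papers = [_paper(total=3.0) for _ in range(4)]
        assert aggregate_journal_year(papers, min_n=5) == []
        assert len(aggregate_journal_year(papers, min_n=4)) == 1

    def test_weighted_journal_means_recover_global_mean(self):
        rng = np.random.default_rng(11)
        papers = [
            _paper(journal=f"J{rng.integers(0, 4)}", total=float(rng.integers(1, 11)))
            for _ in range(200)
        ]
        summaries = aggregate_journal_year(papers, min_n=1)
        weighted = sum(s.rti * s.n_scored for s in summaries) / sum(
            s.n_scored for s in summaries
        )
        assert weighted == pytest.approx(np.mean([p.total for p in papers]))


class TestRates:
    @pytest.mark.parametrize(
        "detected, identifiable, expected",
        [(242, 236, 98), (2476, 2218, 90), (5, 5, 100), (200, 1, 1)],
    )
    def test_identifiability_rate_league_rounding(self, detected, identifiable, expected):
        assert identifiability_rate(detected, identifiable) == expected

    def test_identifiability_rate_no_denominator(self):
        with pytest.raises(NoDenominatorError):
            identifiability_rate(0, 0)

    @pytest.mark.parametrize("n_cell, n_auth, expected", [(10, 5, 50.0), (4, 0, 0.0)])
    def test_authentication_rate(self, n_cell, n_auth, expected):
        assert authentication_rate(n_cell, n_auth) == expected

    def test_authentication_rate_no_denominator(self):
        with pytest.raises(NoDenominatorError):
            authentication_rate(0, 0)


class TestVertebrateSubset:
    def _doc(self, doc_id):
        return Document(doc_id, "J", "", 2018, "text", [])

    def test_empty_and_identity(self):
        docs = [self._doc("a"), self._doc("b")]
        assert vertebrate_subset(docs, {}) == []
        hits = {d.doc_id: [CriterionHit(Criterion.IACUC, 0, "IACUC")] for d in docs}
        assert vertebrate_subset(docs, hits) == docs

    def test_mixed(self):
        docs = [self._doc(x) for x in "abc"]
        hits = {
            "a": [CriterionHit(Criterion.IACUC, 0, "IACUC")],
            "b": [CriterionHit(Criterion.SEX, 0, "male")],
        }
        assert [d.doc_id for d in vertebrate_subset(docs, hits)] == ["a"]


def _brute_ranks(v):
    """Average ranks from first principles (independent of scipy)."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x) ** 0.5
    vy = sum((b - my) ** 2 for b in y) ** 0.5
    return cov / (vx * vy)


class TestCorrelations:
    def test_spearman_monotone_and_reversed(self):
        assert spearman([1, 2, 3], [10, 20, 30]).coefficient == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).coefficient == pytest.approx(-1.0)

    def test_spearman_no_ties_formula(self):
        # 1 - 6*4/(4*15) = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]).coefficient == pytest.approx(0.6)

    def test_pearson_trivials(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson(x, x).coefficient == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).coefficient == pytest.approx(-1.0)

    def test_against_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            x = list(rng.integers(0, 5, size=n).astype(float))
            y = list(rng.integers(0, 5, size=n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert pearson(x, y).coefficient == pytest.approx(
                _brute_pearson(x, y), abs=1e-12
            )
            assert spearman(x, y).coefficient == pytest.approx(
                _brute_pearson(_brute_ranks(x), _brute_ranks(y)), abs=1e-12
            )

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).coefficient
        assert spearman(np.exp(x), y).coefficient == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7).coefficient == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman([1], [2])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])  # zero rank variance


class TestPercentiles:
    def test_single_value_is_q1(self):
        frame = percentile_ranks([5.0])
        assert frame["percentile"].iloc[0] == 100.0
        assert frame["quartile"].iloc[0] == "Q1"

    def test_top_q1_bottom_q4(self):
        frame = percentile_ranks([1, 2, 3, 4])
        assert frame["quartile"].tolist() == ["Q4", "Q3", "Q2", "Q1"]

    def test_ties_share_percentiles(self):
        frame = percentile_ranks([2, 2, 2])
        assert frame["percentile"].nunique() == 1


class TestTrend:
    def test_single_year_mean_and_sd(self):
        papers = [_paper(year=2018, total=2.0) for _ in range(3)]
        frame = trend_table(papers)
        assert len(frame) == 1
        assert frame["mean_score"].iloc[0] == pytest.approx(2.0)
        assert frame["sd_score"].iloc[0] == pytest.approx(0.0)

    def test_empty_year_dropped(self):
        papers = [_paper(year=2018, total=3.0), _paper(year=2019, total=0.0)]
        frame = trend_table(papers)
        assert frame["year"].tolist() == [2018]

    def test_rising_adherence_raises_yearly_means(self):
        papers = []
        for year, frac in [(2015, 0.2), (2017, 0.5), (2019, 0.9)]:
            for i in range(40):
                addressed = {Criterion.RANDOMIZATION: True} if i < 40 * frac else {}
                total = 1.0 + 4.0 * (i < 40 * frac)
                papers.append(_paper(year=year, total=total, criteria=addressed))
        frame = trend_table(papers)
        means = frame["mean_score"].tolist()
        rates = frame["rate_randomization"].tolist()
        assert means == sorted(means)
        assert rates == sorted(rates)


class TestCompareWithJif:
    def test_join_and_correlation(self, tmp_path):
        papers = []
        rtis = {"A": 2.0, "B": 4.0, "C": 6.0}
        for j, t in rtis.items():
            for year in (2016, 2017):
                papers.extend(_paper(journal=j, issn=f"{j}-issn", year=year, total=t) for _ in range(3))
        summaries = aggregate_journal_year(papers, min_n=1)
        jif_csv = tmp_path / "jif.csv"
        jif_csv.write_text(
            "journal,issn,year,jif\n"
            "A,A-issn,2018,30.0\nB,B-issn,2018,20.0\nC,C-issn,2018,10.0\n"
        )
        table = read_if_table(jif_csv)
        frame, corr = compare_with_jif(summaries, table, jif_year=2018)
        assert len(frame) == 3
        assert corr.method == "spearman"
        assert corr.coefficient == pytest.approx(-1.0)  # perfectly anti-ranked
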