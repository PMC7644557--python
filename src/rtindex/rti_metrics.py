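"""Journal-level aggregation: the Rigor and Transparency Index (RTI).

The RTI of a journal in a given year is the mean composite score of its
scored papers that year.  Papers scoring 0 are treated as "not applicable"
and excluded from the mean (their count is reported as ``n_zero``).
Rank correlations against citation metrics (e.g. the Journal Impact
Factor) use Spearman's rank-order correlation with average ranks for ties.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import ImpactFactorTable
from .types import (
    CorrelationResult,
    Criterion,
    CriterionHit,
    Document,
    JournalYearSummary,
    PaperScore,
    ResourceType,
    SCOREABLE_RESOURCE_TYPES,
)


class NoDenominatorError(ZeroDivisionError):
    """Raised when a rate has an empty denominator."""


def identifiability_rate(detected: int, identifiable: int) -> int:
    """League-table identifiability percentage, rounded half-up to integer.

    E.g. 236 of 242 antibodies identifiable → 98; 2,218 of 2,476 → 90.
    """
    if detected <= 0:
        raise NoDenominatorError("no detected resources ('no-denominator')")
    if not 0 <= identifiable <= detected:
        raise ValueError("identifiable must lie in [0, detected]")
    return int(math.floor(100.0 * identifiable / detected + 0.5))


def authentication_rate(papers_with_cell_lines: int, papers_with_auth_or_contam: int) -> float:
    """Percent of cell-line papers with an authentication or contamination
    statement."""
    if papers_with_cell_lines <= 0:
        raise NoDenominatorError("no cell-line papers ('no-denominator')")
    return 100.0 * papers_with_auth_or_contam / papers_with_cell_lines


def aggregate_journal_year(
    paper_scores: Iterable[PaperScore], min_n: int = 10
) -> list[JournalYearSummary]:
    """Aggregate per-paper scores into journal-year RTI summaries.

    Zero-score papers are excluded from the RTI and all rates but counted in
    ``n_zero``; groups with fewer than *min_n* scored papers are suppressed.
    Output order is deterministic (journal, year).
    """
    groups: dict[tuple[str, str, int], list[PaperScore]] = defaultdict(list)
    for ps in paper_scores:
        groups[(ps.journal, ps.issn, ps.year)].append(ps)

    summaries = []
    for (journal, issn, year) in sorted(groups):
        papers = groups[(journal, issn, year)]
        scored = [p for p in papers if p.total > 0]
        n_zero = len(papers) - len(scored)
        if len(scored) < max(min_n, 1):
            continue
        totals = np.array([p.total for p in scored])
        criterion_rates = {
            c: float(np.mean([p.criteria.get(c, False) for p in scored]))
            for c in Criterion
        }
        ident_rates: dict[ResourceType, dict[str, float]] = {}
        for t in ResourceType:
            det = sum(p.resource_counts.get(t, {}).get("detected", 0) for p in scored)
            idf = sum(p.resource_counts.get(t, {}).get("identifiable", 0) for p in scored)
            ident_rates[t] = {
                "detected": det,
                "identifiable": idf,
                "rate": (idf / det) if det else float("nan"),
            }
        summaries.append(
            JournalYearSummary(
                journal=journal,
                issn=issn,
                year=year,
                n_scored=len(scored),
                n_zero=n_zero,
                rti=float(totals.mean()),
                sd=float(totals.std(ddof=0)),
                criterion_rates=criterion_rates,
                identifiability_rates=ident_rates,
            )
        )
    return summaries


def vertebrate_subset(
    documents: Sequence[Document],
    hits_by_doc: dict[str, Sequence[CriterionHit]],
) -> list[Document]:
    """Documents with at least one IACUC statement (vertebrate-animal proxy)."""
    out = []
    for doc in documents:
        hits = hits_by_doc.get(doc.doc_id, ())
        if any(h.criterion is Criterion.IACUC for h in hits):
            out.append(doc)
    return out


def _check_vectors(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in input")
    return xa, ya


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank-order correlation (average ranks for ties).

    Equals 1 − 6Σd²/(n(n²−1)) when there are no ties.  Zero rank variance
    in either vector is undefined and raises ``ValueError``.
    """
    xa, ya = _check_vectors(x, y)
    rx = stats.rankdata(xa)  # average ranks
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    coef = float(stats.pearsonr(rx, ry).statistic)
    return CorrelationResult(method="spearman", n=int(xa.size), coefficient=coef)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation."""
    xa, ya = _check_vectors(x, y)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance: correlation undefined")
    coef = float(stats.pearsonr(xa, ya).statistic)
    return CorrelationResult(method="pearson", n=int(xa.size), coefficient=coef)


def percentile_ranks(values: Sequence[float]) -> pd.DataFrame:
    """Percentiles (100·rank/n, average ranks for ties) and quartile labels.

    The highest value gets the highest percentile; the top quartile is
    labeled Q1 (league-table convention).
    """
    va = np.asarray(values, dtype=float)
    if va.size == 0:
        raise ValueError("need at least one value")
    ranks = stats.rankdata(va)
    pct = 100.0 * ranks / va.size

    def quartile(p: float) -> str:
        if p > 75:
            return "Q1"
        if p > 50:
            return "Q2"
        if p > 25:
            return "Q3"
        return "Q4"

    return pd.DataFrame(
        {"value": va, "percentile": pct, "quartile": [quartile(p) for p in pct]}
    )


def trend_table(paper_scores: Iterable[PaperScore]) -> pd.DataFrame:
    """Per-year corpus means and rates (zero-score papers excluded).

    One row per year with the mean ± sd of totals, the fraction of scored
    papers addressing each criterion, and per-type identifiability rates.
    Years with no scored papers are dropped.
    """
    by_year: dict[int, list[PaperScore]] = defaultdict(list)
    for ps in paper_scores:
        if ps.total > 0:
            by_year[ps.year].append(ps)

    rows = []
    for year in sorted(by_year):
        papers = by_year[year]
        totals = np.array([p.total for p in papers])
        row: dict[str, float] = {
            "year": year,
            "n": len(papers),
            "mean_score": float(totals.mean()),
            "sd_score": float(totals.std(ddof=0)),
        }
        for c in Criterion:
            row[f"rate_{c.value.lower()}"] = float(
                np.mean([p.criteria.get(c, False) for p in papers])
            )
        for t in SCOREABLE_RESOURCE_TYPES:
            det = sum(p.resource_counts.get(t, {}).get("detected", 0) for p in papers)
            idf = sum(p.resource_counts.get(t, {}).get("identifiable", 0) for p in papers)
            row[f"ident_{t.value.lower()}"] = (idf / det) if det else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_with_jif(
    summaries: Sequence[JournalYearSummary],
    jif_table: ImpactFactorTable,
    jif_year: int,
    window: tuple[int, int] = (-2, -1),
    use_percentiles: bool = False,
) -> tuple[pd.DataFrame, Optional[CorrelationResult]]:
    """Join journal RTIs against impact factors and rank-correlate.

    The RTI for each journal is averaged (weighted by ``n_scored``) over the
    years ``jif_year + window[0] .. jif_year + window[1]``, mirroring the
    convention of comparing a year's impact factor against the scores of the
    two preceding publication years.  Returns the joined table and the
    Spearman result (None when fewer than two journals match).
    """
    lo, hi = jif_year + window[0], jif_year + window[1]
    per_journal: dict[tuple[str, str], list[JournalYearSummary]] = defaultdict(list)
    for s in summaries:
        if lo <= s.year <= hi:
            per_journal[(s.journal, s.issn)].append(s)

    rows = []
    for (journal, issn), group in sorted(per_journal.items()):
        n = sum(s.n_scored for s in group)
        rti = sum(s.rti * s.n_scored for s in group) / n
        jif = jif_table.lookup(journal, issn, jif_year)
        if jif is not None:
            rows.append({"journal": journal, "issn": issn, "rti": rti, "jif": jif, "n": n})
    frame = pd.DataFrame(rows)
    if len(frame) < 2:
        return frame, None
    if use_percentiles:
        x = percentile_ranks(frame["rti"].to_numpy())["percentile"].to_numpy()
        y = percentile_ranks(frame["jif"].to_numpy())["percentile"].to_numpy()
    else:
        x, y = frame["rti"].to_numpy(), frame["jif"].to_numpy()
    try:
        corr = spearman(x, y)
    except ValueError:
        corr = None
    return frame, corr


def summaries_to_frame(summaries: Sequence[JournalYearSummary]) -> pd.DataFrame:
    """Flatten summaries to one CSV-ready row per journal-year."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "journal": s.journal,
            "issn": s.issn,
            "year": s.year,
            "n_scored": s.n_scored,
            "n_zero": s.n_zero,
            "rti": s.rti,
            "sd": s.sd,
        }
        for c, r in s.criterion_rates.items():
            row[f"rate_{c.value.lower()}"] = r
        for t, d in s.identifiability_rates.items():
            row[f"detected_{t.value.lower()}"] = d["detected"]
            row[f"identifiable_{t.value.lower()}"] = d["identifiable"]
            row[f"ident_rate_{t.value.lower()}"] = d["rate"]
        rows.append(row)
    return pd.DataFrame(rows)
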