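"""Time-to-onset and seriousness-outcome analysis.

Time-to-onset is the number of days from the start of therapy with a
suspect drug to the date of the adverse event.  Spontaneous reports record
both dates with variable precision; onset is computed only when both dates
are complete (year, month and day), and negative intervals — event before
therapy start — are dropped and logged rather than imputed.

Onset distributions are heavily skewed, so groups are compared
nonparametrically: Mann–Whitney U for two drug groups, Kruskal–Wallis H for
three or more, both with tie correction, at a two-sided 0.05 level.
Seriousness outcomes (death, disability, hospitalization, …) are compared
between groups with Pearson's chi-square, falling back to Fisher's exact
test whenever an expected cell count drops below 5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import pct
from .faers_io import PartialDate
from .preprocess import AnalysisDataset, OUTCOME_CODES, SUSPECT_ROLES

logger = logging.getLogger(__name__)

__all__ = [
    "OnsetRecord",
    "OnsetSummary",
    "GroupComparison",
    "OutcomeSummary",
    "OUTCOME_LABELS",
    "compute_onset",
    "summarize_onset",
    "compare_onset",
    "summarize_outcomes",
    "compare_outcomes",
]

#: Outcome-code labels in report-table order.
OUTCOME_LABELS = {
    "DE": "death",
    "DS": "disability",
    "HO": "hospitalization-initial or prolonged",
    "LT": "life-threatening",
    "RI": "required intervention",
    "CA": "congenital anomaly",
    "OT": "other serious (important medical event)",
}


@dataclass(frozen=True)
class OnsetRecord:
    """Days from suspect-therapy start to event for one (report, group, PT)."""

    primaryid: str
    drug_group: str
    pt: str
    onset_days: int

    def __post_init__(self) -> None:
        if self.onset_days < 0:
            raise ValueError("onset_days must be non-negative")


@dataclass(frozen=True)
class OnsetSummary:
    """Per-group distribution summary of onset days for one PT."""

    drug_group: str
    pt: str
    n: int
    median_days: float
    iqr_low: float
    iqr_high: float
    mean_days: float
    mean_rank: float        # average pooled rank across all groups for the PT


@dataclass(frozen=True)
class GroupComparison:
    """Nonparametric comparison of one quantity across drug groups."""

    pt: str
    groups_included: tuple[str, ...]
    test_name: str          # "Mann-Whitney" | "Kruskal-Wallis" | "not-performed"
    statistic: float
    p_value: float
    performed: bool = True

    @property
    def significant(self) -> bool:
        return self.performed and self.p_value < 0.05


@dataclass(frozen=True)
class OutcomeSummary:
    """Outcome-code counts and percentages for one drug group.

    Each report counts at most once per category; percentages use the
    group's total (deduplicated) report count as denominator, so a report
    with several different outcome codes appears in several categories.
    ``unknown`` counts reports with no outcome row at all.
    """

    drug_group: str
    total_reports: int
    counts: dict[str, int]          # label -> report count
    unknown: int

    def proportions(self) -> dict[str, float]:
        out = {label: pct(n, self.total_reports)
               for label, n in self.counts.items()}
        out["unknown"] = pct(self.unknown, self.total_reports)
        return out


# ---------------------------------------------------------------------------
# onset computation
# ---------------------------------------------------------------------------

def compute_onset(dataset: AnalysisDataset, *, start_rule: str = "earliest"
                  ) -> tuple[list[OnsetRecord], list[dict[str, str]]]:
    """Derive onset records from therapy start dates and event dates.

    One record per (report, exposed drug group, PT), emitted only when both
    the therapy start date and the event date are complete 8-digit dates
    and the event does not precede the start.  Negative intervals are
    returned in the drop log, never silently discarded.

    start_rule
        "earliest": earliest complete suspect start date of the group;
        "latest-before-event": the latest complete start date not after
        the event date (for multi-course therapy records).
    """
    if start_rule not in ("earliest", "latest-before-event"):
        raise ValueError("start_rule must be 'earliest' or "
                         "'latest-before-event'")
    # complete suspect start dates per (report, drug group)
    starts: dict[tuple[str, str], list[PartialDate]] = {}
    for m in dataset.drug_mentions:
        if (m.drug_group is not None and m.role in SUSPECT_ROLES
                and m.start_date.is_complete):
            starts.setdefault((m.primaryid, m.drug_group), []).append(
                m.start_date)

    # earliest complete event date per (report, pt)
    event_dates: dict[tuple[str, str], PartialDate] = {}
    for m in dataset.event_mentions:
        if not m.event_date.is_complete:
            continue
        key = (m.primaryid, m.pt_name)
        if key not in event_dates or (m.event_date.sort_key()
                                      < event_dates[key].sort_key()):
            event_dates[key] = m.event_date

    records: list[OnsetRecord] = []
    dropped: list[dict[str, str]] = []
    for pid, groups in sorted(dataset.exposures.items()):
        for group in sorted(groups):
            date_list = starts.get((pid, group))
            if not date_list:
                continue
            for pt in sorted(dataset.events[pid]):
                event = event_dates.get((pid, pt))
                if event is None:
                    continue
                if start_rule == "earliest":
                    start = min(date_list, key=PartialDate.sort_key)
                else:
                    eligible = [s for s in date_list
                                if s.sort_key() <= event.sort_key()]
                    if not eligible:
                        dropped.append({"PRIMARYID": pid, "DRUG_GROUP": group,
                                        "PT": pt,
                                        "REASON": "no start date on or before event"})
                        continue
                    start = max(eligible, key=PartialDate.sort_key)
                days = (event.to_date() - start.to_date()).days
                if days < 0:
                    dropped.append({"PRIMARYID": pid, "DRUG_GROUP": group,
                                    "PT": pt,
                                    "REASON": f"event precedes start by {-days} d"})
                    continue
                records.append(OnsetRecord(primaryid=pid, drug_group=group,
                                           pt=pt, onset_days=days))
    if dropped:
        logger.info("dropped %d onset interval(s) (negative or unanchored)",
                    len(dropped))
    return records, dropped


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float, float]:
    if method == "linear":
        q1, med, q3 = np.percentile(values, [25, 50, 75])
    elif method == "tukey":
        # Tukey hinges: medians of the lower/upper halves (median included
        # in both halves when n is odd)
        v = np.sort(values)
        n = len(v)
        half = (n + 1) // 2
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[n - half:]))
        med = float(np.median(v))
    else:
        raise ValueError("quantile method must be 'linear' or 'tukey'")
    return float(q1), float(med), float(q3)


def summarize_onset(records: Sequence[OnsetRecord], pt: str, *,
                    quantile_method: str = "linear") -> list[OnsetSummary]:
    """Median (IQR), mean days and pooled mean rank per drug group.

    The mean rank is the group's average rank when all groups' onset values
    for the PT are ranked together (midranks for ties) — the quantity a
    rank-based group comparison actually tests.
    """
    by_group: dict[str, list[int]] = {}
    for r in records:
        if r.pt == pt:
            by_group.setdefault(r.drug_group, []).append(r.onset_days)
    if not by_group:
        return []
    groups = sorted(by_group)
    pooled = np.concatenate([np.asarray(by_group[g], dtype=float)
                             for g in groups])
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(by_group[g]) for g in groups])
    out = []
    for i, g in enumerate(groups):
        vals = np.asarray(by_group[g], dtype=float)
        q1, med, q3 = _quartiles(vals, quantile_method)
        out.append(OnsetSummary(
            drug_group=g, pt=pt, n=len(vals),
            median_days=med, iqr_low=q1, iqr_high=q3,
            mean_days=float(vals.mean()),
            mean_rank=float(ranks[offsets[i]:offsets[i + 1]].mean()),
        ))
    return out


def compare_onset(records: Sequence[OnsetRecord], pt: str, *,
                  min_n: int = 2) -> GroupComparison:
    """Compare onset distributions across drug groups for one PT.

    Groups with fewer than ``min_n`` onset records are excluded before
    testing.  Exactly two eligible groups are compared with the
    Mann–Whitney U test (normal approximation, tie and continuity
    correction); three or more with the Kruskal–Wallis H test (tie
    corrected).  Fewer than two eligible groups: the comparison is marked
    not performed.
    """
    by_group: dict[str, list[int]] = {}
    for r in records:
        if r.pt == pt:
            by_group.setdefault(r.drug_group, []).append(r.onset_days)
    eligible = {g: v for g, v in sorted(by_group.items()) if len(v) >= min_n}
    if len(eligible) < 2:
        return GroupComparison(pt=pt, groups_included=tuple(eligible),
                               test_name="not-performed",
                               statistic=float("nan"), p_value=float("nan"),
                               performed=False)
    samples = [np.asarray(v, dtype=float) for v in eligible.values()]
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        name = "Mann-Whitney"
    else:
        res = stats.kruskal(*samples)
        name = "Kruskal-Wallis"
    return GroupComparison(pt=pt, groups_included=tuple(eligible),
                           test_name=name, statistic=float(res.statistic),
                           p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# outcome summarization
# ---------------------------------------------------------------------------

def summarize_outcomes(dataset: AnalysisDataset,
                       drug_groups: Sequence[str] | None = None
                       ) -> list[OutcomeSummary]:
    """Outcome-code counts and percentages per drug group.

    A report contributes once per distinct category even when the same code
    repeats; the denominator is the group's total report count.
    """
    if drug_groups is None:
        drug_groups = dataset.drug_groups
    codes_by_report: dict[str, set[str]] = {}
    for m in dataset.outcome_mentions:
        codes_by_report.setdefault(m.primaryid, set()).add(m.outcome_code)

    summaries = []
    for group in drug_groups:
        ids = [pid for pid, gs in dataset.exposures.items() if group in gs]
        counts = {OUTCOME_LABELS[code]: 0 for code in OUTCOME_CODES}
        unknown = 0
        for pid in ids:
            codes = codes_by_report.get(pid)
            if not codes:
                unknown += 1
                continue
            for code in codes:
                counts[OUTCOME_LABELS[code]] += 1
        summaries.append(OutcomeSummary(drug_group=group,
                                        total_reports=len(ids),
                                        counts=counts, unknown=unknown))
    return summaries


def _compare_category(k1: int, n1: int, k2: int, n2: int
                      ) -> tuple[str, float, float]:
    """Chi-square (or Fisher when any expected count < 5) on a 2x2
    category-vs-rest table for two groups."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        odds, p = stats.fisher_exact(table.astype(int))
        return "Fisher", float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(chi2), float(p)


def compare_outcomes(summaries: Sequence[OutcomeSummary]
                     ) -> pd.DataFrame:
    """Pairwise between-group comparison of each outcome category.

    For every pair of drug groups and every category, tests the 2x2 table
    (category count vs rest) with Pearson's chi-square, or Fisher's exact
    test when any expected cell is below 5.  Pairs where either group has
    no reports are skipped.
    """
    rows = []
    for s1, s2 in itertools.combinations(summaries, 2):
        if s1.total_reports == 0 or s2.total_reports == 0:
            continue
        for label in list(OUTCOME_LABELS.values()):
            test, statistic, p = _compare_category(
                s1.counts[label], s1.total_reports,
                s2.counts[label], s2.total_reports)
            rows.append({
                "category": label,
                "group_1": s1.drug_group, "group_2": s2.drug_group,
                "count_1": s1.counts[label], "total_1": s1.total_reports,
                "count_2": s2.counts[label], "total_2": s2.total_reports,
                "test": test, "statistic": statistic, "p_value": p,
                "significant": bool(p < 0.05),
            })
    return pd.DataFrame(rows, columns=[
        "category", "group_1", "group_2", "count_1", "total_1",
        "count_2", "total_2", "test", "statistic", "p_value", "significant"])
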