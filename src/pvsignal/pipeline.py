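"""End-to-end analysis pipeline: ingest → deduplicate → detect → compare.

Given a directory of FAERS-style ASCII tables, a drug-synonym dictionary and
a run configuration, produces the four report tables of a disproportionality
study — descriptive characteristics, signal table, time-to-onset table,
outcome table — plus an audit trail (deduplication removals, orphan rows,
unmatched drug names, dropped onset intervals).  The analysis path contains
no randomness: rerunning on the same inputs yields byte-identical outputs,
and the outputs are invariant under permutation of input file rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import pct, round_half_up
from .faers_io import read_bundle
from .onset_outcome import (compare_onset, compare_outcomes, compute_onset,
                            summarize_onset, summarize_outcomes)
from .preprocess import (AnalysisDataset, SynonymDictionary, SUSPECT_ROLES,
                         assemble_dataset)
from .signal_stats import PriorConfig, SignalOptions, detect_signals

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "CharacteristicsTable",
    "EmptyDatasetError",
    "run",
    "summarize_characteristics",
]

#: Reporting-year bands of the descriptive table.
YEAR_BANDS = ((2004, 2007), (2008, 2011), (2012, 2015),
              (2016, 2019), (2020, 2022))

REPORTER_LEVELS = ("consumer", "health-professional", "lawyer", "physician",
                   "other health-professional", "pharmacist", "unknown")


class EmptyDatasetError(RuntimeError):
    """No reports remain after filtering — nothing to analyze."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``pts = None`` analyzes every PT whose co-occurrence count with some
    drug group reaches ``min_a``.  Year bounds restrict by FDA receipt
    year; ``None`` disables the window.
    """

    input_dir: str
    dict_path: str
    out_dir: str | None = None
    drug_groups: tuple[str, ...] | None = None
    pts: tuple[str, ...] | None = None
    min_a: int = 1
    year_start: int | None = None
    year_end: int | None = None
    # algorithm options
    yates: bool = False
    continuity_correction: bool = False
    ic_smoothing: bool = True
    ic025_method: str = "closed_form"
    quantile_method: str = "linear"
    start_rule: str = "earliest"
    min_onset_n: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.year_start is not None and self.year_end is not None
                and self.year_start > self.year_end):
            raise ValueError("year_start must not exceed year_end")

    def signal_options(self) -> SignalOptions:
        return SignalOptions(yates=self.yates,
                             continuity_correction=self.continuity_correction,
                             ic_smoothing=self.ic_smoothing,
                             ic025_method=self.ic025_method)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("drug_groups", "pts"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# descriptive characteristics
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicsTable:
    """Counts per drug group (plus the union Total column) for the
    descriptive variables: age bands, sex, country, reporter occupation,
    indications and reporting-year bands, with group means for age/weight.

    Percentages are always recomputed from the stored counts, never stored.
    """

    groups: tuple[str, ...]
    totals: dict[str, int]                       # group -> report count
    counts: dict[str, dict[str, dict[str, int]]]  # variable -> level -> group
    means: dict[str, dict[str, float]]           # variable -> group -> mean

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.groups) + ["Total"]
        rows = []
        for variable, levels in self.counts.items():
            for level, by_group in levels.items():
                row = {"characteristic": variable, "level": level}
                for g in cols:
                    n = by_group.get(g, 0)
                    row[f"{g}_n"] = n
                    row[f"{g}_pct"] = pct(n, self.totals.get(g, 0))
                rows.append(row)
        for variable, by_group in self.means.items():
            row = {"characteristic": variable, "level": "mean"}
            for g in cols:
                v = by_group.get(g)
                row[f"{g}_n"] = round_half_up(v, 2) if v is not None else np.nan
                row[f"{g}_pct"] = np.nan
            rows.append(row)
        for g in cols:
            pass
        frame = pd.DataFrame(rows)
        total_row = {"characteristic": "Total", "level": "n"}
        for g in cols:
            total_row[f"{g}_n"] = self.totals.get(g, 0)
            total_row[f"{g}_pct"] = 100.0 if self.totals.get(g, 0) else 0.0
        return pd.concat([frame, pd.DataFrame([total_row])],
                         ignore_index=True)


def _age_band(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 18:
        return "<18"
    if age <= 64:
        return "18-64"
    return ">=65"


def _year_band(year: int | None) -> str:
    if year is not None:
        for lo, hi in YEAR_BANDS:
            if lo <= year <= hi:
                return f"{lo}-{hi}"
    return "other"


def summarize_characteristics(dataset: AnalysisDataset,
                              drug_groups: Sequence[str] | None = None
                              ) -> CharacteristicsTable:
    """Descriptive characteristics per drug group.

    Age bands are <18 / 18–64 / ≥65 with both 18 and 64 in the middle band;
    the Total column is the union of reports exposed to any of the groups.
    """
    if drug_groups is None:
        drug_groups = dataset.drug_groups
    groups = tuple(drug_groups)

    members: dict[str, list[str]] = {
        g: [pid for pid, gs in dataset.exposures.items() if g in gs]
        for g in groups}
    members["Total"] = sorted({pid for g in groups for pid in members[g]})

    indications: dict[str, set[str]] = {}
    for m in dataset.drug_mentions:
        if (m.drug_group in groups and m.role in SUSPECT_ROLES
                and m.indication_pt):
            indications.setdefault(m.primaryid, set()).add(m.indication_pt)

    counts: dict[str, dict[str, dict[str, int]]] = {
        "age_band": {}, "sex": {}, "country": {}, "reporter": {},
        "indication": {}, "reporting_year": {}}
    means: dict[str, dict[str, float]] = {"age_years": {}, "weight_kg": {}}
    totals: dict[str, int] = {}

    def bump(variable: str, level: str, col: str) -> None:
        counts[variable].setdefault(level, {}).setdefault(col, 0)
        counts[variable][level][col] += 1

    for col, ids in members.items():
        totals[col] = len(ids)
        ages, weights = [], []
        for pid in ids:
            r = dataset.reports[pid]
            bump("age_band", _age_band(r.age_years), col)
            bump("sex", r.sex or "unknown", col)
            bump("country", r.country or "unknown", col)
            bump("reporter", r.reporter, col)
            bump("reporting_year", _year_band(r.receipt_year), col)
            for ind in sorted(indications.get(pid, ())):
                bump("indication", ind, col)
            if r.age_years is not None:
                ages.append(r.age_years)
            if r.weight_kg is not None:
                weights.append(r.weight_kg)
        if ages:
            means["age_years"][col] = float(np.mean(ages))
        if weights:
            means["weight_kg"][col] = float(np.mean(weights))

    # stable level order: fixed vocabularies first, then alphabetical
    def _ordered(variable: str, fixed: Sequence[str] = ()) -> dict:
        levels = counts[variable]
        order = [l for l in fixed if l in levels] + sorted(
            l for l in levels if l not in fixed)
        return {l: levels[l] for l in order}

    counts["age_band"] = _ordered("age_band", ("<18", "18-64", ">=65",
                                               "unknown"))
    counts["sex"] = _ordered("sex", ("F", "M", "unknown"))
    counts["reporter"] = _ordered("reporter", REPORTER_LEVELS)
    counts["reporting_year"] = _ordered(
        "reporting_year", tuple(f"{lo}-{hi}" for lo, hi in YEAR_BANDS))
    counts["country"] = _ordered("country")
    counts["indication"] = _ordered("indication")

    return CharacteristicsTable(groups=groups, totals=totals,
                                counts=counts, means=means)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _onset_table(dataset: AnalysisDataset, config: RunConfig
                 ) -> tuple[pd.DataFrame, list[dict[str, str]]]:
    records, dropped = compute_onset(dataset, start_rule=config.start_rule)
    pts = sorted({r.pt for r in records})
    rows = []
    for pt in pts:
        comparison = compare_onset(records, pt, min_n=config.min_onset_n)
        for s in summarize_onset(records, pt,
                                 quantile_method=config.quantile_method):
            rows.append({
                "soc": dataset.pt_to_soc.get(pt, ""),
                "pt": pt,
                "drug_group": s.drug_group,
                "n": s.n,
                "median_days": s.median_days,
                "q1": s.iqr_low, "q3": s.iqr_high,
                "mean_days": round_half_up(s.mean_days, 2),
                "mean_rank": round_half_up(s.mean_rank, 2),
                "test": comparison.test_name,
                "statistic": comparison.statistic,
                "p_value": comparison.p_value,
                "significant": comparison.significant,
            })
    frame = pd.DataFrame(rows, columns=[
        "soc", "pt", "drug_group", "n", "median_days", "q1", "q3",
        "mean_days", "mean_rank", "test", "statistic", "p_value",
        "significant"])
    if len(frame):
        frame = frame.sort_values(["soc", "pt", "drug_group"],
                                  kind="mergesort").reset_index(drop=True)
    return frame, dropped


def _outcome_tables(dataset: AnalysisDataset, groups: Sequence[str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    summaries = summarize_outcomes(dataset, groups)
    rows = []
    for s in summaries:
        props = s.proportions()
        for label, count in list(s.counts.items()) + [("unknown", s.unknown)]:
            rows.append({"drug_group": s.drug_group,
                         "total_reports": s.total_reports,
                         "category": label, "n": count,
                         "pct": props[label]})
    summary_frame = pd.DataFrame(rows, columns=[
        "drug_group", "total_reports", "category", "n", "pct"])
    tests = compare_outcomes(summaries)
    return summary_frame, tests


def run(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline; return (and optionally write) all tables.

    Returns a dict with keys ``characteristics``, ``signals``, ``onset``,
    ``outcomes``, ``outcome_tests`` (DataFrames), ``dataset`` and ``audit``.
    Raises :class:`EmptyDatasetError` when no report survives filtering.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    dictionary = SynonymDictionary.from_file(config.dict_path)
    bundle = read_bundle(config.input_dir)
    dataset = assemble_dataset(bundle, dictionary)
    n_before_window = dataset.n_reports
    if config.year_start is not None or config.year_end is not None:
        dataset = dataset.filter_years(config.year_start or 0,
                                       config.year_end or 9999)
    if dataset.n_reports == 0:
        raise EmptyDatasetError(
            f"no reports remain (parsed {n_before_window} deduplicated "
            f"reports before the year window)")

    groups = config.drug_groups or dataset.drug_groups
    if not groups:
        raise EmptyDatasetError("no report matched any drug group")

    signals = detect_signals(dataset, groups, config.pts,
                             prior=PriorConfig(),
                             options=config.signal_options())
    if config.min_a > 1 and len(signals):
        signals = signals[signals["a"] >= config.min_a].reset_index(drop=True)

    characteristics = summarize_characteristics(dataset, groups).to_frame()
    onset, dropped_onsets = _onset_table(dataset, config)
    outcomes, outcome_tests = _outcome_tables(dataset, groups)

    audit = {
        "n_demo_rows": len(bundle.demo_rows),
        "n_deduplicated_reports": n_before_window,
        "n_reports_in_window": dataset.n_reports,
        "n_duplicate_versions_removed": len(dataset.removal_log),
        "orphan_rows": dataset.orphan_counts,
        "n_unmatched_drug_names": int(sum(dataset.unmatched_drug_names.values())),
        "unmatched_drug_names_top": dict(
            dataset.unmatched_drug_names.most_common(20)),
        "n_dropped_onset_intervals": len(dropped_onsets),
        "drug_groups": list(groups),
    }

    result = {
        "characteristics": characteristics,
        "signals": signals,
        "onset": onset,
        "outcomes": outcomes,
        "outcome_tests": outcome_tests,
        "dataset": dataset,
        "audit": audit,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("characteristics", "signals", "onset", "outcomes",
                     "outcome_tests"):
            result[name].to_csv(out / f"{name}.csv", index=False,
                                lineterminator="\n")
        pd.DataFrame(dataset.removal_log).to_csv(
            out / "removal_log.csv", index=False, lineterminator="\n")
        pd.DataFrame(dropped_onsets).to_csv(
            out / "dropped_onsets.csv", index=False, lineterminator="\n")
        (out / "audit.json").write_text(json.dumps(audit, indent=2,
                                                   sort_keys=True) + "\n")
    return result
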