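"""Report deduplication, drug-name normalization and dataset assembly.

Spontaneous-report databases contain multiple versions of the same case
(follow-up reports share a CASEID but get new PRIMARYIDs and receipt dates).
The counting unit of a disproportionality analysis is the deduplicated case,
so before any statistics we keep, per CASEID, only the most recent version:
the row with the maximal FDA_DT, ties broken by the maximal PRIMARYID.

Drug exposure is established by text-string matching of the verbatim
DRUGNAME against a synonym dictionary (generic names, brand names,
abbreviations), restricted to suspect roles (PS/SS).  Reports that mention a
study drug only as concomitant (C) or interacting (I) contribute no exposure
to that drug group — they stay in the background.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import cmp_to_key
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import PartialDate, RawTableBundle, parse_partial_date

logger = logging.getLogger(__name__)

__all__ = [
    "Report",
    "DrugMention",
    "EventMention",
    "OutcomeMention",
    "SynonymDictionary",
    "AnalysisDataset",
    "deduplicate",
    "normalize_drug_name",
    "filter_suspect",
    "assemble_dataset",
    "DEFAULT_SUFFIX_TOKENS",
    "OUTCOME_CODES",
    "SUSPECT_ROLES",
]

#: FAERS ROLE_COD vocabulary: primary suspect, secondary suspect,
#: concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")
SUSPECT_ROLES = ("PS", "SS")

#: FAERS OUTC_COD vocabulary.
OUTCOME_CODES = ("DE", "DS", "HO", "LT", "RI", "CA", "OT")

#: OCCP_COD to reporter-occupation label.
_REPORTER_BY_OCCP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "HP": "health-professional",
    "CN": "consumer",
    "LW": "lawyer",
}

#: Trailing dosage/form tokens stripped from drug names before lookup.
#: Editable: pass your own list to SynonymDictionary / normalize_drug_name.
DEFAULT_SUFFIX_TOKENS = frozenset({
    "mg", "ml", "mcg", "g", "gm", "kg", "iu",
    "injection", "inj", "infusion", "solution", "suspension",
    "tablet", "tablets", "tab", "capsule", "capsules", "cap",
    "oral", "iv", "intravenous", "topical",
    "hcl", "hydrochloride", "sodium", "sulfate", "citrate",
    "unknown", "nos",
})

#: A purely numeric/dose token such as "20mg", "10ml", "0.9", "100".
_DOSE_TOKEN = re.compile(r"^\d+(\.\d+)?(mg|ml|mcg|g|gm|kg|iu|%)?$")

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Report:
    """One deduplicated safety report (the counting unit)."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    age_years: float | None = None
    sex: str | None = None            # "F" | "M" | None
    weight_kg: float | None = None
    country: str | None = None
    reporter: str = "unknown"
    event_dt: PartialDate = PartialDate()

    @property
    def receipt_year(self) -> int | None:
        return self.fda_dt.year


@dataclass(frozen=True)
class DrugMention:
    """One DRUG row: a drug as reported on one report, with its role."""

    primaryid: str
    raw_name: str
    drug_group: str | None          # analysis group after normalization
    role: str                       # PS | SS | C | I
    start_date: PartialDate = PartialDate()
    indication_pt: str | None = None
    drug_seq: str | None = None

    @property
    def is_suspect(self) -> bool:
        return self.role in SUSPECT_ROLES


@dataclass(frozen=True)
class EventMention:
    """One REAC row: a MedDRA preferred term reported on one report."""

    primaryid: str
    pt_name: str
    pt_code: int | None = None
    event_date: PartialDate = PartialDate()
    soc_name: str | None = None


@dataclass(frozen=True)
class OutcomeMention:
    """One OUTC row: a seriousness outcome code for one report."""

    primaryid: str
    outcome_code: str               # DE | DS | HO | LT | RI | CA | OT


# ---------------------------------------------------------------------------
# synonym dictionary and name normalization
# ---------------------------------------------------------------------------

def _normalize_text(raw: str) -> str:
    """Case-fold, strip punctuation, collapse internal whitespace."""
    return _NON_ALNUM.sub(" ", str(raw).casefold()).strip()


def _strip_suffix_tokens(name: str, suffixes: frozenset[str]) -> str:
    tokens = name.split()
    while len(tokens) > 1 and (tokens[-1] in suffixes
                               or _DOSE_TOKEN.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


class SynonymDictionary:
    """Maps normalized drug-name synonyms to analysis group labels.

    The lookup is deterministic: a name maps to at most one group.  When
    several synonyms are contained in a raw name, the longest synonym wins,
    so "doxorubicin hcl liposome" beats "doxorubicin" for a liposomal entry.
    """

    def __init__(self, synonym_to_group: Mapping[str, str],
                 suffix_tokens: Iterable[str] = DEFAULT_SUFFIX_TOKENS):
        self._map: dict[str, str] = {}
        self.suffix_tokens = frozenset(s.casefold() for s in suffix_tokens)
        for syn, group in synonym_to_group.items():
            norm = _normalize_text(syn)
            if not norm:
                continue
            if norm in self._map and self._map[norm] != group:
                raise ValueError(
                    f"synonym {syn!r} maps to both {self._map[norm]!r} "
                    f"and {group!r}")
            self._map[norm] = str(group)
        # longest-first so the first containment hit is the winner
        self._by_length = sorted(self._map, key=lambda s: (-len(s), s))

    def __len__(self) -> int:
        return len(self._map)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._map.values())))

    def lookup(self, raw_name: str) -> str | None:
        """Resolve a verbatim DRUGNAME to a group label, or None."""
        norm = _normalize_text(raw_name)
        if not norm:
            return None
        stripped = _strip_suffix_tokens(norm, self.suffix_tokens)
        for candidate in (stripped, norm):
            if candidate in self._map:
                return self._map[candidate]
        for syn in self._by_length:   # substring containment, longest first
            if syn in norm:
                return self._map[syn]
        return None

    @classmethod
    def from_file(cls, path: str | Path, *, delimiter: str = "\t",
                  suffix_tokens: Iterable[str] = DEFAULT_SUFFIX_TOKENS
                  ) -> "SynonymDictionary":
        """Load a two-column delimited file: synonym <delim> drug_group.

        Lines starting with ``#`` and blank lines are ignored.  A comma is
        accepted as an alternative delimiter when no tab is present.
        """
        mapping: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = delimiter if delimiter in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: line {i}: expected "
                                 f"'synonym{delimiter}drug_group', got {line!r}")
            mapping[parts[0]] = parts[1]
        return cls(mapping, suffix_tokens=suffix_tokens)


def normalize_drug_name(raw: str, dictionary: SynonymDictionary) -> str | None:
    """Resolve a verbatim drug name to its analysis group (or None)."""
    return dictionary.lookup(raw)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _cmp_maybe_numeric(x: str | None, y: str | None) -> int:
    """Compare two field values: numerically when both parse as integers,
    else lexicographically; absent values sort first."""
    if x == y:
        return 0
    if x is None:
        return -1
    if y is None:
        return 1
    try:
        xi, yi = int(x), int(y)
    except ValueError:
        return -1 if x < y else 1
    return (xi > yi) - (xi < yi)


def _cmp_demo_rows(r1: Mapping[str, str | None],
                   r2: Mapping[str, str | None]) -> int:
    c = _cmp_maybe_numeric(r1.get("FDA_DT"), r2.get("FDA_DT"))
    if c != 0:
        return c
    return _cmp_maybe_numeric(r1.get("PRIMARYID"), r2.get("PRIMARYID"))


def deduplicate(demo_rows: Sequence[Mapping[str, str | None]]
                ) -> tuple[list[dict[str, str | None]], list[dict[str, str]]]:
    """Keep one DEMO row per CASEID; return (survivors, removal_log).

    Per CASEID the survivor is the row with the maximal FDA_DT; among ties
    on FDA_DT, the maximal PRIMARYID (numeric comparison when both values
    parse as integers, else lexicographic).  The removal log records every
    dropped PRIMARYID with its reason.  Output order is deterministic and
    independent of input row order: survivors sorted by CASEID, the log by
    dropped PRIMARYID.
    """
    groups: dict[str, list[dict[str, str | None]]] = {}
    for i, row in enumerate(demo_rows):
        caseid = row.get("CASEID")
        primaryid = row.get("PRIMARYID")
        if caseid is None or primaryid is None:
            raise ValueError(f"DEMO row {i} is missing CASEID or PRIMARYID")
        groups.setdefault(str(caseid), []).append(dict(row))

    key = cmp_to_key(_cmp_demo_rows)
    survivors: list[dict[str, str | None]] = []
    removal_log: list[dict[str, str]] = []
    for caseid in sorted(groups, key=cmp_to_key(_cmp_maybe_numeric)):
        rows = groups[caseid]
        winner = max(rows, key=key)
        survivors.append(winner)
        for row in rows:
            if row is winner:
                continue
            if _cmp_maybe_numeric(row.get("FDA_DT"), winner.get("FDA_DT")) < 0:
                reason = "earlier FDA_DT than retained version"
            else:
                reason = "same FDA_DT, lesser PRIMARYID than retained version"
            removal_log.append({
                "PRIMARYID": str(row["PRIMARYID"]),
                "CASEID": caseid,
                "FDA_DT": row.get("FDA_DT") or "",
                "RETAINED_PRIMARYID": str(winner["PRIMARYID"]),
                "REASON": reason,
            })
    removal_log.sort(key=lambda r: cmp_to_key(_cmp_maybe_numeric)(r["PRIMARYID"]))
    return survivors, removal_log


# ---------------------------------------------------------------------------
# suspect-role filtering
# ---------------------------------------------------------------------------

def filter_suspect(drug_mentions: Sequence[DrugMention]) -> list[DrugMention]:
    """Retain only primary/secondary-suspect mentions (roles PS, SS).

    Unknown role codes are logged as warnings and excluded, leaving the
    retained count unaffected.
    """
    unknown = Counter(m.role for m in drug_mentions
                      if m.role not in ROLE_CODES)
    for role, n in sorted(unknown.items()):
        logger.warning("unknown ROLE_COD %r on %d drug mention(s)", role, n)
    return [m for m in drug_mentions if m.is_suspect]


# ---------------------------------------------------------------------------
# field conversions
# ---------------------------------------------------------------------------

#: AGE_COD conversion factors to years.
_AGE_FACTORS = {"YR": 1.0, "MON": 1 / 12, "DEC": 10.0,
                "DY": 1 / 365.25, "WK": 1 / 52.18}

#: WT_COD conversion factors to kilograms.
_WT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359, "GMS": 1e-3}


def _convert_age(age: str | None, age_cod: str | None) -> float | None:
    if age is None:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    code = (age_cod or "YR").strip().upper()
    factor = _AGE_FACTORS.get(code)
    if factor is None:       # HR and anything unrecognized -> absent
        return None
    years = value * factor
    return years if years >= 0 else None


def _convert_weight(wt: str | None, wt_cod: str | None) -> float | None:
    if wt is None:
        return None
    try:
        value = float(wt)
    except ValueError:
        return None
    factor = _WT_FACTORS.get((wt_cod or "KG").strip().upper())
    if factor is None:
        return None
    kg = value * factor
    return kg if kg > 0 else None


def _convert_sex(sex: str | None) -> str | None:
    s = (sex or "").strip().upper()
    return s if s in ("F", "M") else None


def _convert_reporter(occp: str | None) -> str:
    return _REPORTER_BY_OCCP.get((occp or "").strip().upper(), "unknown")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class AnalysisDataset:
    """Deduplicated reports joined to their drug, event and outcome rows.

    ``exposures`` maps each report to the set of drug groups it is exposed
    to — witnessed by at least one suspect-role mention whose raw name
    matched the synonym dictionary.  ``events`` maps each report to its set
    of preferred terms (a PT counts at most once per report).
    """

    reports: dict[str, Report]
    drug_mentions: list[DrugMention]
    event_mentions: list[EventMention]
    outcome_mentions: list[OutcomeMention]
    exposures: dict[str, frozenset[str]]
    events: dict[str, frozenset[str]]
    removal_log: list[dict[str, str]] = field(default_factory=list)
    orphan_counts: dict[str, int] = field(default_factory=dict)
    unmatched_drug_names: Counter = field(default_factory=Counter)
    pt_to_soc: dict[str, str] = field(default_factory=dict)
    pt_to_code: dict[str, int] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def drug_groups(self) -> tuple[str, ...]:
        return tuple(sorted({g for gs in self.exposures.values() for g in gs}))

    @property
    def all_pts(self) -> tuple[str, ...]:
        return tuple(sorted({p for ps in self.events.values() for p in ps}))

    def report_ids(self) -> list[str]:
        return list(self.reports)

    def exposure_matrix(self, groups: Sequence[str] | None = None) -> pd.DataFrame:
        """Boolean reports x drug-groups matrix."""
        groups = list(groups) if groups is not None else list(self.drug_groups)
        ids = self.report_ids()
        data = {g: [g in self.exposures[i] for i in ids] for g in groups}
        return pd.DataFrame(data, index=ids, dtype=bool)

    def event_matrix(self, pts: Sequence[str] | None = None) -> pd.DataFrame:
        """Boolean reports x preferred-terms matrix."""
        pts = list(pts) if pts is not None else list(self.all_pts)
        ids = self.report_ids()
        data = {p: [p in self.events[i] for i in ids] for p in pts}
        return pd.DataFrame(data, index=ids, dtype=bool)

    def filter_years(self, start: int, end: int) -> "AnalysisDataset":
        """Restrict to reports whose receipt year lies in [start, end]."""
        keep = {pid for pid, r in self.reports.items()
                if r.receipt_year is not None and start <= r.receipt_year <= end}
        return AnalysisDataset(
            reports={p: r for p, r in self.reports.items() if p in keep},
            drug_mentions=[m for m in self.drug_mentions if m.primaryid in keep],
            event_mentions=[m for m in self.event_mentions if m.primaryid in keep],
            outcome_mentions=[m for m in self.outcome_mentions if m.primaryid in keep],
            exposures={p: s for p, s in self.exposures.items() if p in keep},
            events={p: s for p, s in self.events.items() if p in keep},
            removal_log=self.removal_log,
            orphan_counts=self.orphan_counts,
            unmatched_drug_names=self.unmatched_drug_names,
            pt_to_soc=self.pt_to_soc,
            pt_to_code=self.pt_to_code,
        )


def _int_or_none(text: str | None) -> int | None:
    if text is None:
        return None
    try:
        return int(text)
    except ValueError:
        return None


def assemble_dataset(bundle: RawTableBundle,
                     dictionary: SynonymDictionary) -> AnalysisDataset:
    """Deduplicate, normalize and join a raw bundle into an AnalysisDataset.

    Joins DRUG/REAC/OUTC/THER/INDI rows by PRIMARYID, restricted to the
    deduplication survivors.  THER start dates and INDI indications attach
    to drug mentions via DRUG_SEQ when the seq columns are present, else to
    every mention of the report.  Orphan rows (PRIMARYID absent from DEMO)
    are counted and surfaced, never silently dropped.
    """
    survivors, removal_log = deduplicate(bundle.demo_rows)
    orphan_counts = bundle.orphan_counts

    reports: dict[str, Report] = {}
    for row in survivors:
        pid = str(row["PRIMARYID"])
        reports[pid] = Report(
            primaryid=pid,
            caseid=str(row["CASEID"]),
            fda_dt=parse_partial_date(row.get("FDA_DT")),
            age_years=_convert_age(row.get("AGE"), row.get("AGE_COD")),
            sex=_convert_sex(row.get("SEX")),
            weight_kg=_convert_weight(row.get("WT"), row.get("WT_COD")),
            country=row.get("REPORTER_COUNTRY"),
            reporter=_convert_reporter(row.get("OCCP_COD")),
            event_dt=parse_partial_date(row.get("EVENT_DT")),
        )
    keep = set(reports)

    # therapy start dates and indications, keyed by (primaryid, drug_seq)
    ther_by_key: dict[tuple[str, str | None], list[PartialDate]] = {}
    for row in bundle.ther_rows:
        pid = str(row.get("PRIMARYID"))
        if pid not in keep:
            continue
        seq = row.get("DSG_DRUG_SEQ")
        ther_by_key.setdefault((pid, seq), []).append(
            parse_partial_date(row.get("START_DT")))
    indi_by_key: dict[tuple[str, str | None], str] = {}
    for row in bundle.indi_rows:
        pid = str(row.get("PRIMARYID"))
        if pid not in keep:
            continue
        seq = row.get("INDI_DRUG_SEQ")
        if row.get("INDI_PT") is not None:
            indi_by_key.setdefault((pid, seq), row["INDI_PT"])

    def _start_date(pid: str, seq: str | None) -> PartialDate:
        dates = ther_by_key.get((pid, seq))
        if dates is None and seq is not None:   # no seq-matched row
            dates = ther_by_key.get((pid, None))
        if dates is None:
            # fall back to any therapy row of the report
            dates = [d for (p, _), ds in ther_by_key.items() if p == pid
                     for d in ds]
        complete = [d for d in dates if d.is_complete] if dates else []
        if complete:
            return min(complete, key=PartialDate.sort_key)
        return min(dates, key=PartialDate.sort_key) if dates else PartialDate()

    unmatched: Counter = Counter()
    drug_mentions: list[DrugMention] = []
    for row in bundle.drug_rows:
        pid = str(row.get("PRIMARYID"))
        if pid not in keep:
            continue
        raw_name = row.get("DRUGNAME") or ""
        group = dictionary.lookup(raw_name)
        if group is None and raw_name:
            unmatched[raw_name] += 1
        seq = row.get("DRUG_SEQ")
        drug_mentions.append(DrugMention(
            primaryid=pid,
            raw_name=raw_name,
            drug_group=group,
            role=(row.get("ROLE_COD") or "").strip().upper(),
            start_date=_start_date(pid, seq),
            indication_pt=indi_by_key.get((pid, seq),
                                          indi_by_key.get((pid, None))),
            drug_seq=seq,
        ))

    pt_to_soc: dict[str, str] = {}
    pt_to_code: dict[str, int] = {}
    event_mentions: list[EventMention] = []
    for row in bundle.reac_rows:
        pid = str(row.get("PRIMARYID"))
        if pid not in keep:
            continue
        pt = row.get("PT")
        if not pt:
            continue
        code = _int_or_none(row.get("PT_CODE"))
        soc = row.get("SOC")
        if soc:
            pt_to_soc.setdefault(pt, soc)
        if code is not None:
            pt_to_code.setdefault(pt, code)
        event_date = parse_partial_date(row.get("EVENT_DT"))
        if event_date.is_empty:
            event_date = reports[pid].event_dt
        event_mentions.append(EventMention(
            primaryid=pid, pt_name=pt, pt_code=code,
            event_date=event_date, soc_name=soc))

    outcome_mentions: list[OutcomeMention] = []
    for row in bundle.outc_rows:
        pid = str(row.get("PRIMARYID"))
        if pid not in keep:
            continue
        code = (row.get("OUTC_COD") or "").strip().upper()
        if code in OUTCOME_CODES:
            outcome_mentions.append(OutcomeMention(primaryid=pid,
                                                   outcome_code=code))
        elif code:
            logger.warning("unknown OUTC_COD %r on report %s", code, pid)

    suspect = filter_suspect(drug_mentions)
    exposures = {pid: frozenset() for pid in reports}
    for m in suspect:
        if m.drug_group is not None:
            exposures[m.primaryid] = exposures[m.primaryid] | {m.drug_group}
    events = {pid: frozenset() for pid in reports}
    for m in event_mentions:
        events[m.primaryid] = events[m.primaryid] | {m.pt_name}

    return AnalysisDataset(
        reports=reports,
        drug_mentions=drug_mentions,
        event_mentions=event_mentions,
        outcome_mentions=outcome_mentions,
        exposures=exposures,
        events=events,
        removal_log=removal_log,
        orphan_counts=orphan_counts,
        unmatched_drug_names=unmatched,
        pt_to_soc=pt_to_soc,
        pt_to_code=pt_to_code,
    )
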