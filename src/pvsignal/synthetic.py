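"""Synthetic FAERS-style data with known ground truth.

Real spontaneous-report quarters cannot ship with a test suite, so this
module generates bundles with the same structure — one case = a DEMO row
(possibly several versions sharing a CASEID), suspect/concomitant DRUG rows,
REAC rows with MedDRA preferred terms, OUTC rows and THER therapy-date rows
— from a sampling model whose parameters are the quantities the pipeline is
supposed to recover:

* drug–event signals are planted on the odds scale: for an exposed report
  the reporting odds of a signal PT are multiplied by θ, so the true
  reporting odds ratio of the pair equals θ exactly under the model;
* a configurable fraction of cases is emitted as 2–3 DEMO versions with
  increasing FDA_DT (and occasionally tied FDA_DT) so the deduplication
  rule's choice is observable;
* time-to-onset is log-normal per (drug group, PT) in days;
* dates are degraded to partial precision and demographics blanked at
  configurable rates, as in real FAERS.

The default configuration emulates the scale and mix of an oncology
pharmacovigilance study: three doxorubicin formulation groups (conventional,
pegylated-liposomal, non-pegylated-liposomal) over a background of hallmark
anthracycline-toxicity preferred terms, receipt years 2004–2022.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .faers_io import RawTableBundle, write_bundle

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "Cohort",
    "sample_cohort",
    "generate",
    "expected_table",
    "toy_config",
]

# MedDRA preferred terms used as the default background, with a flat
# PT -> (code, system organ class) lookup.
_DEFAULT_PT_INFO: dict[str, tuple[int, str]] = {
    "Anaemia": (10002034, "Blood and lymphatic system disorders"),
    "Neutropenia": (10029354, "Blood and lymphatic system disorders"),
    "Thrombocytopenia": (10043554, "Blood and lymphatic system disorders"),
    "Cardiotoxicity": (10048610, "Cardiac disorders"),
    "Cardiomyopathy": (10007636, "Cardiac disorders"),
    "Nausea": (10028813, "Gastrointestinal disorders"),
    "Vomiting": (10047700, "Gastrointestinal disorders"),
    "Febrile neutropenia": (10016288,
                            "General disorders and administration site conditions"),
    "Mucosal inflammation": (10028116,
                             "General disorders and administration site conditions"),
    "Pyrexia": (10037660,
                "General disorders and administration site conditions"),
    "Sepsis": (10040047, "Infections and infestations"),
    "Pneumonia": (10035664, "Respiratory, thoracic and mediastinal disorders"),
    "Interstitial lung disease": (10022611,
                                  "Respiratory, thoracic and mediastinal disorders"),
    "Malignant neoplasm progression": (
        10051398,
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)"),
    "Palmar-plantar erythrodysaesthesia syndrome": (
        10033553, "Skin and subcutaneous tissue disorders"),
    "Drug ineffective": (10017947,
                         "General disorders and administration site conditions"),
}

_BACKGROUND_DRUGS = ("CYCLOPHOSPHAMIDE", "CARBOPLATIN", "PACLITAXEL",
                     "RITUXIMAB", "VINCRISTINE", "PREDNISONE")

_INDICATIONS = ("Malignant lymphoma", "Breast cancer", "Ovarian cancer",
                "Multiple myeloma", "Acute lymphocytic leukaemia")

_COUNTRIES = (("US", 0.35), ("CA", 0.08), ("DE", 0.07), ("FR", 0.06),
              ("GB", 0.06), ("JP", 0.06), ("IT", 0.05), ("ES", 0.03),
              ("CN", 0.02), ("PL", 0.02), ("AT", 0.01), ("OTHER", 0.19))

_OCCP = (("MD", 0.43), ("OT", 0.23), ("HP", 0.13), ("CN", 0.10),
         ("PH", 0.05), ("LW", 0.01), ("", 0.05))


def _default_exposure() -> dict[str, float]:
    return {"CDOX": 0.08, "DOXIL": 0.05, "MYOCET": 0.03}


def _default_background_pts() -> dict[str, float]:
    return {
        "Anaemia": 0.020, "Neutropenia": 0.010, "Thrombocytopenia": 0.010,
        "Cardiotoxicity": 0.002, "Cardiomyopathy": 0.002,
        "Nausea": 0.030, "Vomiting": 0.020,
        "Febrile neutropenia": 0.006, "Mucosal inflammation": 0.004,
        "Pyrexia": 0.020, "Sepsis": 0.008, "Pneumonia": 0.010,
        "Interstitial lung disease": 0.006,
        "Malignant neoplasm progression": 0.005,
        "Palmar-plantar erythrodysaesthesia syndrome": 0.005,
    }


def _default_signals() -> dict[tuple[str, str], float]:
    return {
        ("CDOX", "Febrile neutropenia"): 8.0,
        ("CDOX", "Cardiotoxicity"): 8.0,
        ("CDOX", "Neutropenia"): 4.0,
        ("CDOX", "Anaemia"): 2.0,
        ("DOXIL", "Palmar-plantar erythrodysaesthesia syndrome"): 8.0,
        ("DOXIL", "Interstitial lung disease"): 4.0,
        ("DOXIL", "Febrile neutropenia"): 4.0,
        ("DOXIL", "Mucosal inflammation"): 4.0,
        ("MYOCET", "Febrile neutropenia"): 8.0,
        ("MYOCET", "Cardiotoxicity"): 4.0,
        ("MYOCET", "Neutropenia"): 4.0,
        ("MYOCET", "Palmar-plantar erythrodysaesthesia syndrome"): 2.0,
    }


def _default_onset() -> dict[tuple[str, str], tuple[float, float]]:
    ln = np.log
    return {
        ("CDOX", "Neutropenia"): (float(ln(35)), 1.2),
        ("DOXIL", "Neutropenia"): (float(ln(17)), 1.1),
        ("MYOCET", "Neutropenia"): (float(ln(30)), 1.1),
        ("CDOX", "Palmar-plantar erythrodysaesthesia syndrome"): (float(ln(60)), 0.8),
        ("DOXIL", "Palmar-plantar erythrodysaesthesia syndrome"): (float(ln(46)), 0.8),
        ("MYOCET", "Palmar-plantar erythrodysaesthesia syndrome"): (float(ln(72)), 0.6),
        ("CDOX", "Pneumonia"): (float(ln(159)), 1.3),
        ("DOXIL", "Pneumonia"): (float(ln(17)), 1.3),
        ("MYOCET", "Pneumonia"): (float(ln(90)), 1.0),
        ("CDOX", "Febrile neutropenia"): (float(ln(33)), 1.1),
        ("DOXIL", "Febrile neutropenia"): (float(ln(34)), 1.1),
        ("MYOCET", "Febrile neutropenia"): (float(ln(12)), 1.0),
    }


def _default_outcomes() -> dict[str, dict[str, float]]:
    return {
        "CDOX": {"DE": 0.18, "DS": 0.006, "HO": 0.37, "LT": 0.07,
                 "OT": 0.35, "": 0.024},
        "DOXIL": {"DE": 0.17, "DS": 0.010, "HO": 0.31, "LT": 0.055,
                  "OT": 0.375, "": 0.080},
        "MYOCET": {"DE": 0.13, "DS": 0.013, "HO": 0.44, "LT": 0.096,
                   "OT": 0.320, "": 0.001},
        "": {"DE": 0.10, "DS": 0.010, "HO": 0.30, "LT": 0.05,
             "OT": 0.30, "": 0.240},
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic reporting model.

    ``signals`` maps (drug_group, pt) to the planted odds multiplier θ ≥ 0:
    for a report taking the drug, the odds of listing the PT are
    ``θ·p/(1−p)`` instead of ``p/(1−p)``.  ``onset`` maps (drug_group, pt)
    to (μ, σ) of a log-normal onset-time distribution in days.
    ``outcome_probs`` maps drug group (``""`` = background) to probabilities
    over outcome codes, ``""`` meaning no outcome row.
    """

    n_reports: int = 20_000
    drug_groups: dict[str, float] = field(default_factory=_default_exposure)
    background_pts: dict[str, float] = field(
        default_factory=_default_background_pts)
    signals: dict[tuple[str, str], float] = field(
        default_factory=_default_signals)
    duplication_rate: float = 0.20
    partial_date_rate: float = 0.20
    missing_demo_rate: float = 0.30
    concomitant_drug_rate: float = 0.10
    onset: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_onset)
    default_onset: tuple[float, float] = (4.0943445622221, 1.0)  # ln 60
    outcome_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_outcomes)
    start_year: int = 2004
    end_year: int = 2022
    filler_pt: str = "Drug ineffective"
    pt_info: dict[str, tuple[int, str]] = field(
        default_factory=lambda: dict(_DEFAULT_PT_INFO))
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for name in ("duplication_rate", "partial_date_rate",
                     "missing_demo_rate", "concomitant_drug_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for g, p in self.drug_groups.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"exposure probability for {g!r}: {p}")
        for pt, p in self.background_pts.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline probability for {pt!r}: {p}")
        for pair, theta in self.signals.items():
            if theta < 0:
                raise ValueError(f"odds multiplier for {pair}: {theta}")
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.drug_groups))

    @property
    def pt_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.background_pts))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from YAML; nested mappings group→pt→value stand in
        for the (group, pt)-keyed fields."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for pair_field, leaf in (("signals", float), ("onset", tuple)):
            if pair_field in raw:
                flat = {}
                for group, by_pt in raw[pair_field].items():
                    for pt, v in by_pt.items():
                        flat[(group, pt)] = leaf(v)
                raw[pair_field] = flat
        if "pt_info" in raw:
            raw["pt_info"] = {pt: tuple(v) for pt, v in raw["pt_info"].items()}
        if "default_onset" in raw:
            raw["default_onset"] = tuple(raw["default_onset"])
        return cls(**raw)


def toy_config(seed: int = 42) -> SyntheticConfig:
    """The documented toy quarter: 200 reports, 3 drug groups, 10 PTs."""
    pts = ["Anaemia", "Neutropenia", "Febrile neutropenia", "Cardiotoxicity",
           "Nausea", "Pyrexia", "Sepsis", "Pneumonia",
           "Palmar-plantar erythrodysaesthesia syndrome",
           "Malignant neoplasm progression"]
    return SyntheticConfig(
        n_reports=200,
        drug_groups={"CDOX": 0.25, "DOXIL": 0.15, "MYOCET": 0.10},
        background_pts={pt: 0.05 for pt in pts},
        signals={("CDOX", "Febrile neutropenia"): 8.0,
                 ("DOXIL", "Palmar-plantar erythrodysaesthesia syndrome"): 8.0,
                 ("MYOCET", "Cardiotoxicity"): 4.0},
        duplication_rate=0.2,
        partial_date_rate=0.2,
        missing_demo_rate=0.3,
        concomitant_drug_rate=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort sampling (vectorized core of the model)
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory sampled cohort, before serialization to FAERS files.

    ``taking`` is actual drug intake; ``suspect`` additionally requires the
    mention not to have been demoted to a concomitant role — only
    ``suspect`` constitutes analysis exposure.
    """

    groups: tuple[str, ...]
    pts: tuple[str, ...]
    taking: np.ndarray        # (n, G) bool
    suspect: np.ndarray       # (n, G) bool
    secondary: np.ndarray     # (n, G) bool: suspect mention has role SS
    events: np.ndarray        # (n, P) bool

    @property
    def n(self) -> int:
        return self.taking.shape[0]

    def contingency(self, group: str, pt: str) -> tuple[int, int, int, int]:
        """Observed a/b/c/d for one pair under suspect-role exposure."""
        g = self.groups.index(group)
        p = self.pts.index(pt)
        exp = self.suspect[:, g]
        evt = self.events[:, p]
        a = int(np.sum(exp & evt))
        b = int(np.sum(~exp & evt))
        c = int(np.sum(exp & ~evt))
        d = int(np.sum(~exp & ~evt))
        return a, b, c, d


def sample_cohort(config: SyntheticConfig,
                  rng: np.random.Generator | None = None) -> Cohort:
    """Sample exposures, roles and events for all cases at once.

    Signal pairs tilt the reporting odds multiplicatively: a report taking
    several signal drugs for the same PT multiplies their θs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_reports
    groups = config.group_names
    pts = config.pt_names
    g_probs = np.array([config.drug_groups[g] for g in groups])
    taking = rng.random((n, len(groups))) < g_probs
    demoted = rng.random((n, len(groups))) < config.concomitant_drug_rate
    suspect = taking & ~demoted
    secondary = suspect & (rng.random((n, len(groups))) < 0.2)

    p0 = np.array([config.background_pts[pt] for pt in pts])
    log_theta = np.zeros((len(groups), len(pts)))
    for (g, pt), theta in config.signals.items():
        if g in groups and pt in pts:
            gi, pi = groups.index(g), pts.index(pt)
            log_theta[gi, pi] = np.log(theta) if theta > 0 else -np.inf
    odds = p0 / (1 - p0)
    tilt = np.exp(taking.astype(float) @ log_theta)   # (n, P)
    p = odds * tilt / (1 + odds * tilt)
    events = rng.random((n, len(pts))) < p
    return Cohort(groups=groups, pts=pts, taking=taking, suspect=suspect,
                  secondary=secondary, events=events)


# ---------------------------------------------------------------------------
# closed-form expectations
# ---------------------------------------------------------------------------

def _event_prob(config: SyntheticConfig, pt: str,
                pattern: tuple[bool, ...]) -> float:
    p0 = config.background_pts[pt]
    odds = p0 / (1 - p0)
    for g, on in zip(config.group_names, pattern):
        if on:
            odds *= config.signals.get((g, pt), 1.0)
    return odds / (1 + odds)


def expected_table(config: SyntheticConfig, drug_group: str, pt: str
                   ) -> tuple[float, float, float, float]:
    """Exact expected a/b/c/d for one pair under the sampling model.

    Enumerates all drug-intake patterns (groups are independent); a report
    counts as exposed when it takes the drug *and* the mention keeps a
    suspect role (probability 1 − concomitant_drug_rate); demoted reports
    still have tilted event odds but fall into the background.
    """
    if drug_group not in config.drug_groups:
        raise KeyError(f"unknown drug group {drug_group!r}")
    if pt not in config.background_pts:
        raise KeyError(f"unknown preferred term {pt!r}")
    groups = config.group_names
    gi = groups.index(drug_group)
    probs = [config.drug_groups[g] for g in groups]
    keep = 1.0 - config.concomitant_drug_rate
    e_a = e_b = e_c = e_d = 0.0
    for pattern in itertools.product((False, True), repeat=len(groups)):
        p_pattern = 1.0
        for on, pg in zip(pattern, probs):
            p_pattern *= pg if on else (1 - pg)
        if p_pattern == 0.0:
            continue
        pe = _event_prob(config, pt, pattern)
        if pattern[gi]:
            # exposed iff this group's mention keeps its suspect role
            e_a += p_pattern * keep * pe
            e_c += p_pattern * keep * (1 - pe)
            e_b += p_pattern * (1 - keep) * pe
            e_d += p_pattern * (1 - keep) * (1 - pe)
        else:
            e_b += p_pattern * pe
            e_d += p_pattern * (1 - pe)
    n = config.n_reports
    return n * e_a, n * e_b, n * e_c, n * e_d


# ---------------------------------------------------------------------------
# serialization to FAERS files
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of one generated bundle.

    ``exposure`` and ``events`` are keyed by the surviving PRIMARYID of
    each case, so they can be compared field-for-field with the output of
    dataset assembly after deduplication.
    """

    config: SyntheticConfig
    n_cases: int
    n_demo_rows: int
    surviving_primaryid: dict[str, str]          # caseid -> primaryid
    exposure: dict[str, frozenset[str]]          # primaryid -> drug groups
    events: dict[str, frozenset[str]]            # primaryid -> PTs
    role_counts: Counter                         # study-drug mention roles
    onset_params: dict[tuple[str, str], tuple[float, float]]

    def contingency(self, drug_group: str, pt: str
                    ) -> tuple[int, int, int, int]:
        """Observed a/b/c/d from the planted exposure/event sets."""
        a = b = c = d = 0
        for pid in self.exposure:
            exp = drug_group in self.exposure[pid]
            evt = pt in self.events[pid]
            a += exp and evt
            b += (not exp) and evt
            c += exp and not evt
            d += (not exp) and not evt
        return a, b, c, d

    def expected(self, drug_group: str, pt: str
                 ) -> tuple[float, float, float, float]:
        return expected_table(self.config, drug_group, pt)


def _random_date(rng: np.random.Generator, start_year: int,
                 end_year: int) -> np.datetime64:
    start = np.datetime64(f"{start_year}-01-01")
    end = np.datetime64(f"{end_year}-12-31")
    span = int((end - start) / np.timedelta64(1, "D"))
    return start + np.timedelta64(int(rng.integers(0, span + 1)), "D")


def _fmt_date(d: np.datetime64) -> str:
    return str(d).replace("-", "")


def _degrade_date(text: str, rng: np.random.Generator, rate: float) -> str:
    """With probability ``rate``, truncate YYYYMMDD to YYYYMM (or YYYY)."""
    if text and rng.random() < rate:
        return text[:6] if rng.random() < 0.7 else text[:4]
    return text


def _choice(rng: np.random.Generator, pairs) -> str:
    labels = [x[0] for x in pairs]
    probs = np.array([x[1] for x in pairs], dtype=float)
    probs = probs / probs.sum()
    return labels[int(rng.choice(len(labels), p=probs))]


def generate(config: SyntheticConfig, out_dir: str | Path | None = None
             ) -> tuple[RawTableBundle, SyntheticTruth]:
    """Generate one synthetic quarter; optionally write the six ASCII files
    (plus delimited truth files) to ``out_dir``.

    Deterministic: the same config (including seed) yields byte-identical
    files.
    """
    rng = np.random.default_rng(config.seed)
    cohort = sample_cohort(config, rng)
    groups, pts = cohort.groups, cohort.pts
    study_names = {g: g for g in groups}    # DRUGNAME == group label

    bundle = RawTableBundle()
    surviving: dict[str, str] = {}
    exposure: dict[str, frozenset[str]] = {}
    truth_events: dict[str, frozenset[str]] = {}
    role_counts: Counter = Counter()

    for i in range(config.n_reports):
        caseid = str(10_000_000 + i)
        n_versions = 1
        if rng.random() < config.duplication_rate:
            n_versions = int(rng.integers(2, 4))
        base_date = _random_date(rng, config.start_year, config.end_year)
        fda_dts = []
        for v in range(n_versions - 1, 0, -1):
            back = int(rng.integers(30, 400))
            fda_dts.append(base_date - np.timedelta64(back * v, "D"))
        fda_dts.append(base_date)
        if n_versions > 1 and rng.random() < 0.3:
            fda_dts[-2] = fda_dts[-1]       # tie: PRIMARYID must decide
        primaryids = [f"{caseid}{v + 1}" for v in range(n_versions)]
        pid = primaryids[-1]                # survivor: max FDA_DT, max PID
        surviving[caseid] = pid

        # demographics
        age_missing = rng.random() < config.missing_demo_rate
        age_years = float(np.clip(rng.normal(55, 15), 1, 95))
        age_kind = rng.random()
        if age_kind < 0.04:
            age, age_cod = str(int(rng.integers(1, 25))), "MON"
        elif age_kind < 0.08:
            age, age_cod = str(int(age_years // 10)), "DEC"
        else:
            age, age_cod = str(int(round(age_years))), "YR"
        sex = "" if rng.random() < config.missing_demo_rate else \
            ("F" if rng.random() < 0.55 else "M")
        wt_missing = rng.random() < config.missing_demo_rate
        wt_kg = float(np.clip(rng.normal(70, 15), 30, 150))
        if rng.random() < 0.1:
            wt, wt_cod = f"{wt_kg / 0.45359:.1f}", "LBS"
        else:
            wt, wt_cod = f"{wt_kg:.1f}", "KG"
        country = _choice(rng, _COUNTRIES)
        occp = _choice(rng, _OCCP)

        # drug rows: one background primary-suspect drug plus study drugs
        taking_idx = [g for g in range(len(groups)) if cohort.taking[i, g]]
        drug_rows = []       # (seq, name, role)
        seq = 1
        drug_rows.append((seq, str(rng.choice(_BACKGROUND_DRUGS)), "PS"))
        seq += 1
        exposed_groups = []
        for g in taking_idx:
            if cohort.suspect[i, g]:
                role = "SS" if cohort.secondary[i, g] else "PS"
                exposed_groups.append(groups[g])
            else:
                role = "C"
            role_counts[role] += 1
            drug_rows.append((seq, study_names[groups[g]], role))
            seq += 1
        if rng.random() < 0.3:
            drug_rows.append((seq, str(rng.choice(_BACKGROUND_DRUGS)), "C"))
            seq += 1
        exposure[pid] = frozenset(exposed_groups)

        # therapy start: one base date per report, before the receipt date
        therapy = base_date - np.timedelta64(int(rng.integers(30, 1200)), "D")
        therapy_txt = _fmt_date(therapy)

        # events and their dates
        pt_list = [pts[p] for p in range(len(pts)) if cohort.events[i, p]]
        if not pt_list:
            pt_list = [config.filler_pt]
        truth_events[pid] = frozenset(pt_list)
        event_dates = {}
        for pt in pt_list:
            params = config.default_onset
            for g in sorted(exposed_groups):
                if (g, pt) in config.onset:
                    params = config.onset[(g, pt)]
                    break
            days = int(round(float(rng.lognormal(params[0], params[1]))))
            event_dates[pt] = _fmt_date(therapy + np.timedelta64(days, "D"))

        # outcome
        first_group = sorted(exposed_groups)[0] if exposed_groups else ""
        probs = config.outcome_probs.get(first_group,
                                         config.outcome_probs.get("", {"": 1.0}))
        outc = _choice(rng, sorted(probs.items()))

        indication = str(rng.choice(_INDICATIONS))

        event_dt_demo = min(event_dates.values()) if event_dates else None
        for v, (pid_v, fda_dt) in enumerate(zip(primaryids, fda_dts)):
            bundle.demo_rows.append({
                "PRIMARYID": pid_v, "CASEID": caseid,
                "FDA_DT": _fmt_date(fda_dt),
                "AGE": None if age_missing else age,
                "AGE_COD": None if age_missing else age_cod,
                "SEX": sex or None,
                "WT": None if wt_missing else wt,
                "WT_COD": None if wt_missing else wt_cod,
                "REPORTER_COUNTRY": country, "OCCP_COD": occp or None,
                "EVENT_DT": event_dt_demo,
            })
            for s, name, role in drug_rows:
                bundle.drug_rows.append({
                    "PRIMARYID": pid_v, "CASEID": caseid,
                    "DRUG_SEQ": str(s), "ROLE_COD": role, "DRUGNAME": name,
                })
                if role in ("PS", "SS"):
                    bundle.ther_rows.append({
                        "PRIMARYID": pid_v, "CASEID": caseid,
                        "DSG_DRUG_SEQ": str(s),
                        "START_DT": _degrade_date(therapy_txt, rng,
                                                  config.partial_date_rate),
                    })
                    bundle.indi_rows.append({
                        "PRIMARYID": pid_v, "CASEID": caseid,
                        "INDI_DRUG_SEQ": str(s), "INDI_PT": indication,
                    })
            for pt in pt_list:
                code, soc = config.pt_info.get(pt, (0, ""))
                bundle.reac_rows.append({
                    "PRIMARYID": pid_v, "CASEID": caseid, "PT": pt,
                    "PT_CODE": str(code) if code else None, "SOC": soc or None,
                    "EVENT_DT": _degrade_date(event_dates[pt], rng,
                                              config.partial_date_rate),
                })
            if outc:
                bundle.outc_rows.append({
                    "PRIMARYID": pid_v, "CASEID": caseid, "OUTC_COD": outc,
                })

    truth = SyntheticTruth(
        config=config,
        n_cases=config.n_reports,
        n_demo_rows=len(bundle.demo_rows),
        surviving_primaryid=surviving,
        exposure=exposure,
        events=truth_events,
        role_counts=role_counts,
        onset_params=dict(config.onset),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_bundle(bundle, out_dir)
        _write_truth_files(truth, out_dir)
    return bundle, truth


def _write_truth_files(truth: SyntheticTruth, out_dir: Path) -> None:
    """Delimited-text ground-truth tables alongside the FAERS files."""
    lines = ["drug_group\tpt\ttheta\te_a\te_b\te_c\te_d\tobs_a\tobs_b\tobs_c\tobs_d"]
    cfg = truth.config
    for g in cfg.group_names:
        for pt in cfg.pt_names:
            theta = cfg.signals.get((g, pt), 1.0)
            e = truth.expected(g, pt)
            o = truth.contingency(g, pt)
            lines.append("\t".join(
                [g, pt, f"{theta:g}"] + [f"{x:.3f}" for x in e]
                + [str(x) for x in o]))
    (out_dir / "TRUTH_cells.tsv").write_text("\n".join(lines) + "\n")

    lines = ["primaryid\tcaseid\tdrug_groups\tpts"]
    pid_to_case = {p: c for c, p in truth.surviving_primaryid.items()}
    for pid in sorted(truth.exposure, key=int):
        lines.append("\t".join([
            pid, pid_to_case[pid],
            ";".join(sorted(truth.exposure[pid])),
            ";".join(sorted(truth.events[pid]))]))
    (out_dir / "TRUTH_reports.tsv").write_text("\n".join(lines) + "\n")
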