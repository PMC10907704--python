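"""Time-to-onset computation, rank-based comparisons, outcome summaries."""

import dataclasses
import itertools
import math
import statistics

import numpy as np
import pytest
from scipy import stats

from pvsignal.faers_io import RawTableBundle
from pvsignal.onset_outcome import (OnsetRecord, compare_onset,
                                    compare_outcomes, compute_onset,
                                    summarize_onset, summarize_outcomes)
from pvsignal.preprocess import SynonymDictionary, assemble_dataset
from pvsignal.synthetic import SyntheticConfig, generate


def _bundle(start_dt, event_dt, role="PS"):
    return RawTableBundle(
        demo_rows=[{"PRIMARYID": "10", "CASEID": "1", "FDA_DT": "20200601"}],
        drug_rows=[{"PRIMARYID": "10", "DRUG_SEQ": "1", "DRUGNAME": "DOXIL",
                    "ROLE_COD": role}],
        ther_rows=[{"PRIMARYID": "10", "DSG_DRUG_SEQ": "1",
                    "START_DT": start_dt}],
        reac_rows=[{"PRIMARYID": "10", "PT": "Nausea",
                    "EVENT_DT": event_dt}])


@pytest.fixture(scope="module")
def doxil_dict():
    return SynonymDictionary({"DOXIL": "DOXIL"})


class TestComputeOnset:
    def test_calendar_arithmetic(self, doxil_dict):
        ds = assemble_dataset(_bundle("20200101", "20200131"), doxil_dict)
        records, dropped = compute_onset(ds)
        assert len(records) == 1 and not dropped
        assert records[0].onset_days == 30

    def test_partial_start_date_yields_no_record(self, doxil_dict):
        ds = assemble_dataset(_bundle("202001", "20200131"), doxil_dict)
        records, dropped = compute_onset(ds)
        assert records == [] and dropped == []   # date never complete

    def test_negative_interval_dropped_and_logged(self, doxil_dict):
        ds = assemble_dataset(_bundle("20200301", "20200101"), doxil_dict)
        records, dropped = compute_onset(ds)
        assert records == []
        assert len(dropped) == 1 and "precedes" in dropped[0]["REASON"]

    def test_concomitant_role_gives_no_exposure_no_onset(self, doxil_dict):
        ds = assemble_dataset(_bundle("20200101", "20200131", role="C"),
                              doxil_dict)
        assert compute_onset(ds)[0] == []

    def test_earliest_start_used_for_multiple_therapy_rows(self, doxil_dict):
        b = _bundle("20200110", "20200131")
        b.drug_rows.append({"PRIMARYID": "10", "DRUG_SEQ": "2",
                            "DRUGNAME": "DOXIL", "ROLE_COD": "SS"})
        b.ther_rows.append({"PRIMARYID": "10", "DSG_DRUG_SEQ": "2",
                            "START_DT": "20200101"})
        ds = assemble_dataset(b, doxil_dict)
        records, _ = compute_onset(ds)
        assert records[0].onset_days == 30
        latest, _ = compute_onset(ds, start_rule="latest-before-event")
        assert latest[0].onset_days == 21

    def test_lognormal_median_recovered(self, doxil_dict):
        # plant log-normal onsets, no date degradation: the empirical median
        # of the recovered intervals must sit near exp(mu)
        mu, sigma = math.log(30.0), 0.5
        config = SyntheticConfig(
            n_reports=600, drug_groups={"DOXIL": 0.9},
            background_pts={"Nausea": 0.9},
            signals={}, onset={("DOXIL", "Nausea"): (mu, sigma)},
            duplication_rate=0.0, partial_date_rate=0.0,
            concomitant_drug_rate=0.0, seed=5)
        bundle, _ = generate(config)
        ds = assemble_dataset(bundle, doxil_dict)
        records, _ = compute_onset(ds)
        days = [r.onset_days for r in records
                if r.drug_group == "DOXIL" and r.pt == "Nausea"]
        assert len(days) >= 200
        assert np.median(days) == pytest.approx(30.0, rel=0.10)

    def test_negative_onset_never_emitted(self, doxil_dict):
        config = SyntheticConfig(n_reports=300, seed=9)
        bundle, _ = generate(config)
        ds = assemble_dataset(bundle, SynonymDictionary(
            {g: g for g in ("CDOX", "DOXIL", "MYOCET")}))
        records, _ = compute_onset(ds)
        assert all(r.onset_days >= 0 for r in records)


def _records(by_group, pt="PT"):
    out = []
    i = 0
    for g, values in by_group.items():
        for v in values:
            out.append(OnsetRecord(str(i), g, pt, int(v)))
            i += 1
    return out


class TestSummarizeOnset:
    def test_median_of_three(self):
        s = summarize_onset(_records({"A": [10, 20, 30]}), "PT")
        assert s[0].median_days == 20 and s[0].n == 3

    def test_mean_ranks(self):
        s = summarize_onset(_records({"A": [1, 2, 3], "B": [4, 5, 6]}), "PT")
        by = {x.drug_group: x.mean_rank for x in s}
        assert by == {"A": 2.0, "B": 5.0}

    def test_quartiles_match_independent_routine(self):
        values = [14, 8, 91, 33]
        s = summarize_onset(_records({"A": values}), "PT")[0]
        q1, med, q3 = statistics.quantiles(values, n=4, method="inclusive")
        assert (s.iqr_low, s.median_days, s.iqr_high) == (q1, med, q3)

    def test_tukey_hinges_option(self):
        s = summarize_onset(_records({"A": [8, 14, 33, 91]}), "PT",
                            quantile_method="tukey")[0]
        assert (s.iqr_low, s.iqr_high) == (11.0, 62.0)

    def test_unknown_pt_empty(self):
        assert summarize_onset(_records({"A": [1]}), "OTHER") == []


class TestCompareOnset:
    def test_identical_samples_not_significant(self):
        c = compare_onset(_records({"A": [5, 9, 13], "B": [5, 9, 13]}), "PT")
        assert c.test_name == "Mann-Whitney"
        assert c.p_value > 0.9 and not c.significant

    def test_complete_separation(self):
        c = compare_onset(_records({"A": [1, 2, 3, 4, 5],
                                    "B": [10, 11, 12, 13, 14]}), "PT")
        assert c.statistic == 0.0       # U of first group: zero pairwise wins
        assert c.significant

    def test_three_groups_use_kruskal_wallis(self):
        c = compare_onset(_records({"A": [1, 2, 3], "B": [2, 3, 4],
                                    "C": [3, 4, 5]}), "PT")
        assert c.test_name == "Kruskal-Wallis"

    def test_small_groups_excluded_then_not_performed(self):
        c = compare_onset(_records({"A": [1, 2, 3], "B": [9]}), "PT")
        assert not c.performed and c.test_name == "not-performed"
        c2 = compare_onset(_records({"A": [1, 2, 3], "B": [9],
                                     "C": [4, 5]}), "PT")
        assert c2.test_name == "Mann-Whitney"
        assert c2.groups_included == ("A", "C")

    def test_u_statistic_equals_pairwise_win_count(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            nx, ny = rng.integers(2, 13), rng.integers(2, 13)
            x = rng.integers(0, 20, size=nx)
            y = rng.integers(0, 20, size=ny)
            c = compare_onset(_records({"A": x, "B": y}), "PT")
            u_brute = sum((xi > yi) + 0.5 * (xi == yi)
                          for xi in x for yi in y)
            assert c.statistic == pytest.approx(u_brute)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 100, size=20)
        y = rng.integers(1, 100, size=25)
        c1 = compare_onset(_records({"A": x, "B": y}), "PT")
        c2 = compare_onset(_records({"A": x ** 2, "B": y ** 2}), "PT")
        assert c1.statistic == pytest.approx(c2.statistic)
        assert c1.p_value == pytest.approx(c2.p_value)


def _outcome_dataset(codes_by_group):
    """Dataset with one drug group per key; values: per-report outcome
    code lists (None = no outcome row)."""
    from pvsignal.preprocess import (AnalysisDataset, OutcomeMention, Report)
    from pvsignal.faers_io import PartialDate
    reports, exposures, events, outcomes = {}, {}, {}, []
    i = 0
    for group, per_report in codes_by_group.items():
        for codes in per_report:
            pid = str(i)
            i += 1
            reports[pid] = Report(primaryid=pid, caseid=pid,
                                  fda_dt=PartialDate(2020, 1, 1))
            exposures[pid] = frozenset({group})
            events[pid] = frozenset()
            if codes:
                outcomes.extend(OutcomeMention(pid, c) for c in codes)
    return AnalysisDataset(reports=reports, drug_mentions=[],
                           event_mentions=[], outcome_mentions=outcomes,
                           exposures=exposures, events=events)


class TestOutcomes:
    def test_counting_and_percentages(self):
        ds = _outcome_dataset({"G": [["DE"], ["DE"], ["HO"], None]})
        s = summarize_outcomes(ds, ["G"])[0]
        assert s.total_reports == 4
        assert s.counts["death"] == 2
        assert s.counts["hospitalization-initial or prolonged"] == 1
        assert s.unknown == 1
        props = s.proportions()
        assert props["death"] == 50.00
        assert props["hospitalization-initial or prolonged"] == 25.00

    def test_repeated_code_counts_once_per_report(self):
        ds = _outcome_dataset({"G": [["DE", "DE", "HO"]]})
        s = summarize_outcomes(ds, ["G"])[0]
        assert s.counts["death"] == 1 and s.counts[
            "hospitalization-initial or prolonged"] == 1

    def test_percentages_equal_counts_over_total(self):
        rng = np.random.default_rng(8)
        codes = ["DE", "DS", "HO", "LT", "OT", None]
        per_report = [[rng.choice(codes[:-1])] if rng.random() > 0.2 else None
                      for _ in range(57)]
        s = summarize_outcomes(_outcome_dataset({"G": per_report}), ["G"])[0]
        for label, n in s.counts.items():
            assert s.proportions()[label] == pytest.approx(
                100 * n / s.total_reports, abs=0.005)

    def test_fisher_matches_hypergeometric_enumeration(self):
        ds = _outcome_dataset({
            "G1": [["DE"]] * 1 + [None] * 11,
            "G2": [["DE"]] * 7 + [None] * 1})
        tests = compare_outcomes(summarize_outcomes(ds, ["G1", "G2"]))
        row = tests[tests["category"] == "death"].iloc[0]
        assert row["test"] == "Fisher"
        # brute-force two-sided Fisher: condition on margins (8 deaths
        # among 20 reports, 12 in G1) and sum hypergeometric probabilities
        # of tables no more likely than the observed k1 = 1
        p_obs = stats.hypergeom.pmf(1, 20, 8, 12)
        p_exact = sum(stats.hypergeom.pmf(k, 20, 8, 12)
                      for k in range(9)
                      if stats.hypergeom.pmf(k, 20, 8, 12) <= p_obs + 1e-12)
        assert row["p_value"] == pytest.approx(p_exact, rel=1e-8)

    def test_chi_square_used_when_expected_counts_large(self):
        ds = _outcome_dataset({
            "G1": [["DE"]] * 30 + [None] * 70,
            "G2": [["DE"]] * 50 + [None] * 50})
        tests = compare_outcomes(summarize_outcomes(ds, ["G1", "G2"]))
        row = tests[tests["category"] == "death"].iloc[0]
        assert row["test"] == "chi-square"
        chi2, p, _, _ = stats.chi2_contingency(
            [[30, 70], [50, 50]], correction=False)
        assert row["statistic"] == pytest.approx(chi2)
        assert row["p_value"] == pytest.approx(p)

    def test_empty_group_comparison_skipped(self):
        ds = _outcome_dataset({"G1": [["DE"]], "G2": []})
        tests = compare_outcomes(summarize_outcomes(ds, ["G1", "G2"]))
        assert len(tests) == 0
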