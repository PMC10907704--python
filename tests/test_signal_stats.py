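"""ROR / PRR / BCPNN estimators, contingency construction and flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.preprocess import AnalysisDataset, Report
from pvsignal.faers_io import PartialDate
from pvsignal.signal_stats import (ContingencyTable, PriorConfig,
                                   SignalOptions, build_contingency,
                                   compute_ic, compute_prr, compute_ror,
                                   contingency_from_masks, detect_signals,
                                   ic_stats, prr_stats, ror_stats,
                                   signal_flags)
from pvsignal.synthetic import SyntheticConfig, sample_cohort


def scalar_ror(a, b, c, d):
    """Independent longhand evaluation of the ROR formulas."""
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, math.exp(math.log(ror) - 1.959963984540054 * se),
            math.exp(math.log(ror) + 1.959963984540054 * se))


def scalar_prr_chi2(a, b, c, d):
    """Independent longhand PRR and four-cell Pearson chi-square."""
    n = a + b + c + d
    prr = (a / (a + c)) / (b / (b + d))
    chi2 = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        e = row * col / n
        chi2 += (obs - e) ** 2 / e
    return prr, chi2


def scalar_ic(a, b, c, d):
    """Independent evaluation of the printed IC point formula."""
    n = a + b + c + d
    return math.log2(a * n / ((a + c) * (a + b)))


def _dataset(reports):
    """Build an AnalysisDataset from {pid: (groups, pts)}."""
    return AnalysisDataset(
        reports={pid: Report(primaryid=pid, caseid=pid,
                             fda_dt=PartialDate(2020, 1, 1, raw_text="20200101"))
                 for pid in reports},
        drug_mentions=[], event_mentions=[], outcome_mentions=[],
        exposures={pid: frozenset(g) for pid, (g, _) in reports.items()},
        events={pid: frozenset(p) for pid, (_, p) in reports.items()},
    )


class TestContingencyTable:
    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_margins(self):
        t = ContingencyTable(10, 20, 30, 240)
        assert t.n == 300 and t.as_tuple() == (10, 20, 30, 240)


class TestRor:
    def test_symmetric_table(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 20, 30, 240))
        assert ror == pytest.approx(4.0)
        assert lo == pytest.approx(1.71, abs=0.005)
        assert hi == pytest.approx(9.35, abs=0.005)

    def test_zero_cell_non_estimable(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 10, 10))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_continuity_correction_mode(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 10, 10),
                                  continuity_correction=True)
        assert 0 < ror < 1 and lo < ror < hi

    def test_ci_brackets_estimate_and_d_monotonicity(self):
        rng = np.random.default_rng(1)
        cells = rng.integers(1, 50, size=(500, 4))
        ror, lo, hi = ror_stats(*cells.T)
        assert np.all(lo <= ror) and np.all(ror <= hi)
        ror2, _, _ = ror_stats(cells[:, 0], cells[:, 1], cells[:, 2],
                               cells[:, 3] + 7)
        assert np.all(ror2 > ror)     # strictly increasing in d


class TestPrr:
    def test_independence_table(self):
        prr, chi2 = compute_prr(ContingencyTable(4, 26, 36, 234))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        prr, chi2 = compute_prr(ContingencyTable(10, 20, 30, 240))
        assert prr == pytest.approx(3.25)
        assert chi2 == pytest.approx(11.538461538461538, rel=1e-12)

    def test_zero_b_non_estimable(self):
        prr, chi2 = compute_prr(ContingencyTable(3, 0, 7, 90))
        assert math.isnan(prr)
        assert np.isfinite(chi2)

    def test_yates_reduces_chi2(self):
        plain = compute_prr(ContingencyTable(10, 20, 30, 240))[1]
        yates = compute_prr(ContingencyTable(10, 20, 30, 240), yates=True)[1]
        assert yates < plain


class TestIc:
    def test_independence_is_zero_unsmoothed(self):
        # a*N == (a+c)(a+b): (4,26,36,234) has E_a = 4 = a
        ic, _ = compute_ic(ContingencyTable(4, 26, 36, 234), smoothing=False)
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_unsmoothed(self):
        ic, _ = compute_ic(ContingencyTable(10, 20, 30, 240), smoothing=False)
        assert ic == pytest.approx(math.log2(2.5), rel=1e-12)

    def test_smoothing_keeps_zero_a_finite(self):
        ic, ic025 = compute_ic(ContingencyTable(0, 10, 10, 10))
        assert np.isfinite(ic) and np.isfinite(ic025)

    def test_ic025_below_ic(self):
        rng = np.random.default_rng(2)
        cells = rng.integers(1, 200, size=(2000, 4))
        ic, ic025 = ic_stats(*cells.T)
        assert np.all(ic025 <= ic)

    def test_monotone_in_a_with_margins_fixed(self):
        rng = np.random.default_rng(3)
        cells = rng.integers(2, 100, size=(1000, 4))
        a, b, c, d = cells.T
        ic1, lo1 = ic_stats(a, b, c, d)
        ic2, lo2 = ic_stats(a + 1, b - 1, c - 1, d + 1)
        assert np.all(ic2 >= ic1) and np.all(lo2 >= lo1)

    def test_monte_carlo_agrees_with_closed_form(self):
        _, cf = compute_ic(ContingencyTable(40, 200, 160, 9600))
        _, mc = compute_ic(ContingencyTable(40, 200, 160, 9600),
                           ic025_method="monte_carlo", mc_samples=100_000,
                           mc_seed=5)
        assert mc == pytest.approx(cf, abs=0.1)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(gamma11=0.0)


class TestOracleEquivalence:
    def test_random_tables_match_scalar_oracle(self):
        rng = np.random.default_rng(4)
        cells = rng.integers(1, 51, size=(3000, 4))
        ror, lo, hi = ror_stats(*cells.T)
        prr, chi2 = prr_stats(*cells.T)
        ic, _ = ic_stats(*cells.T, smoothing=False)
        for i, (a, b, c, d) in enumerate(cells):
            r, l, h = scalar_ror(a, b, c, d)
            p, x2 = scalar_prr_chi2(a, b, c, d)
            assert ror[i] == pytest.approx(r, rel=1e-10)
            assert lo[i] == pytest.approx(l, rel=1e-10)
            assert hi[i] == pytest.approx(h, rel=1e-10)
            assert prr[i] == pytest.approx(p, rel=1e-10)
            assert chi2[i] == pytest.approx(x2, rel=1e-10, abs=1e-10)
            assert ic[i] == pytest.approx(scalar_ic(a, b, c, d), rel=1e-10)


class TestFlags:
    @settings(max_examples=300, deadline=None)
    @given(a=st.integers(0, 60), b=st.integers(0, 60),
           c=st.integers(0, 60), d=st.integers(0, 600))
    def test_flag_logic_matches_criteria(self, a, b, c, d):
        if a + b + c + d == 0 or a + b == 0 or a + c == 0:
            return
        ror, lo, hi = ror_stats(a, b, c, d)
        prr, chi2 = prr_stats(a, b, c, d)
        ic, ic025 = ic_stats(a, b, c, d)
        f_ror, f_prr, f_bcpnn = signal_flags(a, lo, prr, chi2, ic025)
        assert bool(f_ror) == (np.isfinite(lo) and lo > 1 and a >= 2)
        assert bool(f_prr) == (np.isfinite(prr) and np.isfinite(chi2)
                               and prr >= 2 and chi2 >= 4 and a >= 3)
        assert bool(f_bcpnn) == (np.isfinite(ic025) and ic025 > 0)


class TestBuildContingency:
    def test_four_report_enumeration(self):
        ds = _dataset({
            "1": ({"G"}, {"E"}), "2": ({"G"}, set()),
            "3": (set(), {"E"}), "4": (set(), set())})
        t = build_contingency(ds, "G", "E")
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_multi_group_report_counts_in_a_for_both(self):
        ds = _dataset({"1": ({"G1", "G2"}, {"E"}),
                       "2": (set(), set())})
        assert build_contingency(ds, "G1", "E").a == 1
        assert build_contingency(ds, "G2", "E").a == 1
        assert build_contingency(ds, "G1", "E").b == 0
        assert build_contingency(ds, "G2", "E").b == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_contingency(_dataset({}), "G", "E")

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            contingency_from_masks(np.ones(3, bool), np.ones(4, bool))

    def test_toy_quarter_matches_truth_for_all_pairs(self, toy_dataset,
                                                     toy_bundle_truth):
        _, truth = toy_bundle_truth
        cfg = truth.config
        for g in cfg.group_names:
            for pt in cfg.pt_names:
                t = build_contingency(toy_dataset, g, pt)
                assert t.as_tuple() == truth.contingency(g, pt)


class TestDetectSignals:
    def test_single_report_never_flags(self):
        ds = _dataset({"1": ({"G"}, {"E1", "E2"})})
        frame = detect_signals(ds, ["G"], ["E1", "E2"])
        assert len(frame) == 2
        assert not frame[["flag_ror", "flag_prr", "flag_bcpnn"]].any().any()

    def test_sorted_by_soc_then_pt(self, toy_dataset):
        frame = detect_signals(toy_dataset)
        keys = list(zip(frame["soc"], frame["pt"]))
        assert keys == sorted(keys)

    def test_planted_strong_signal_flagged_by_all_three(self):
        # odds multiplier 8 with expected a ~ 60: all algorithms fire
        config = SyntheticConfig(
            n_reports=20_000,
            drug_groups={"DRUG": 0.15},
            background_pts={"Event": 0.005, "Other": 0.02},
            signals={("DRUG", "Event"): 8.0},
            concomitant_drug_rate=0.1, seed=0)
        rng = np.random.default_rng(11)
        flags = []
        for _ in range(40):
            cohort = sample_cohort(config, rng)
            a, b, c, d = cohort.contingency("DRUG", "Event")
            _, lo, _ = ror_stats(a, b, c, d)
            prr, chi2 = prr_stats(a, b, c, d)
            _, ic025 = ic_stats(a, b, c, d)
            f = signal_flags(a, lo, prr, chi2, ic025)
            flags.append(all(bool(x) for x in f))
        assert np.mean(flags) >= 0.95

    def test_null_flag_rate_small(self):
        config = SyntheticConfig(
            n_reports=20_000,
            drug_groups={"DRUG": 0.15},
            background_pts={f"E{i}": 0.01 for i in range(5)},
            signals={}, concomitant_drug_rate=0.1, seed=0)
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(40):
            cohort = sample_cohort(config, rng)
            for pt in cohort.pts:
                a, b, c, d = cohort.contingency("DRUG", pt)
                _, lo, _ = ror_stats(a, b, c, d)
                hits += bool(np.isfinite(lo) and lo > 1 and a >= 2)
                total += 1
        assert hits / total < 0.10
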