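"""Disproportionality statistics on 2x2 report-count tables.

For one (drug group, preferred term) pair the whole database collapses to

    =============  =========  ==============
    .              event      other events
    =============  =========  ==============
    drug           a          c
    other drugs    b          d
    =============  =========  ==============

with N = a+b+c+d deduplicated reports.  Three classical signal-detection
statistics are computed:

* **ROR** (reporting odds ratio) ``(a/b)/(c/d) = ad/bc`` with the Woolf
  95% interval ``exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d))``; signal when the
  interval's lower bound exceeds 1 and a ≥ 2.
* **PRR** (proportional reporting ratio) ``(a/(a+c))/(b/(b+d))`` together
  with the four-cell Pearson chi-square; signal when PRR ≥ 2, chi2 ≥ 4 and
  a ≥ 3.
* **BCPNN information component** ``IC = log2[ a·N / ((a+c)(a+b)) ]``, the
  log ratio of observed to expected co-reporting, with IC025 the lower 95%
  credibility bound from the closed-form Beta/Dirichlet posterior moments
  (E(IC) − 2·sqrt(V(IC))); signal when IC025 > 0.

Zero cells make ROR/PRR non-estimable and are reported as NaN rather than
continuity-corrected, matching how such rows are conventionally shown as
"–"; an optional 0.5 continuity correction exists for sensitivity analysis.
All estimators are vectorized over arrays of tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import AnalysisDataset

__all__ = [
    "ContingencyTable",
    "PriorConfig",
    "SignalOptions",
    "SignalResult",
    "build_contingency",
    "contingency_from_masks",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "detect_signals",
    "ror_stats",
    "prr_stats",
    "ic_stats",
    "signal_flags",
]

_Z95 = 1.959963984540054          # two-sided 95% normal quantile
_LOG2 = math.log(2.0)

#: Column order of the signal table written by :func:`detect_signals`.
SIGNAL_COLUMNS = [
    "soc", "pt_code", "pt", "drug_group", "a", "b", "c", "d",
    "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2", "ic", "ic025",
    "flag_ror", "flag_prr", "flag_bcpnn",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a/b/c/d for one (drug group, PT) pair vs background."""

    a: int     # drug & event
    b: int     # other drugs, event
    c: int     # drug, other events
    d: int     # other drugs, other events

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative "
                                 f"integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class PriorConfig:
    """BCPNN Beta/Dirichlet hyperparameters (Bate-style defaults).

    ``gamma11`` is the prior weight on the joint (drug, event) cell,
    ``alpha1/beta1`` on the two margins, ``alpha/beta`` the corresponding
    prior totals.  The defaults (1, 1, 1, 2, 2) give prior expectation
    IC = 0 for an empty database.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma11", "alpha1", "beta1", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be strictly positive")


@dataclass(frozen=True)
class SignalOptions:
    """Algorithm switches for sensitivity analyses.

    yates
        apply the Yates continuity correction to the Pearson chi-square.
    continuity_correction
        add 0.5 to every cell for ROR/PRR instead of reporting zero-cell
        tables as non-estimable.
    ic_smoothing
        compute the IC point estimate with ``a + gamma11`` in place of
        ``a`` so that a = 0 stays finite (the credibility bound always
        uses the full posterior and is unaffected).
    ic025_method
        "closed_form" (E(IC) − 2·sqrt(V(IC))) or "monte_carlo"
        (posterior 2.5% quantile by sampling).
    """

    yates: bool = False
    continuity_correction: bool = False
    ic_smoothing: bool = True
    ic025_method: str = "closed_form"
    mc_samples: int = 20_000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if self.ic025_method not in ("closed_form", "monte_carlo"):
            raise ValueError("ic025_method must be 'closed_form' or "
                             "'monte_carlo'")


@dataclass(frozen=True)
class SignalResult:
    """All three statistics and signal flags for one (drug group, PT)."""

    drug_group: str
    pt: str
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    soc: str | None = None
    pt_code: int | None = None

    @property
    def n_cooccurrence(self) -> int:
        return self.table.a

    @property
    def flag_ror(self) -> bool:
        return bool(np.isfinite(self.ror_ci_low) and self.ror_ci_low > 1
                    and self.table.a >= 2)

    @property
    def flag_prr(self) -> bool:
        return bool(np.isfinite(self.prr) and np.isfinite(self.chi2)
                    and self.prr >= 2 and self.chi2 >= 4 and self.table.a >= 3)

    @property
    def flag_bcpnn(self) -> bool:
        return bool(np.isfinite(self.ic025) and self.ic025 > 0)


# ---------------------------------------------------------------------------
# vectorized estimators
# ---------------------------------------------------------------------------

def _asfloat(*arrays):
    return [np.asarray(x, dtype=float) for x in arrays]


def ror_stats(a, b, c, d, *, continuity_correction: bool = False):
    """Vectorized ROR with Woolf 95% CI.

    Returns ``(ror, ci_low, ci_high)`` arrays; tables with any zero cell
    are NaN (non-estimable) unless ``continuity_correction`` adds 0.5 to
    every cell.
    """
    a, b, c, d = _asfloat(a, b, c, d)
    if continuity_correction:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a, b, c, d = (np.where(zero, x + 0.5, x) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_ror = np.log(ror)
        lo = np.exp(log_ror - _Z95 * se)
        hi = np.exp(log_ror + _Z95 * se)
    bad = ~np.isfinite(ror) | (a * b * c * d == 0)
    ror = np.where(bad, np.nan, ror)
    lo = np.where(bad, np.nan, lo)
    hi = np.where(bad, np.nan, hi)
    return ror, lo, hi


def prr_stats(a, b, c, d, *, yates: bool = False,
              continuity_correction: bool = False):
    """Vectorized PRR and four-cell Pearson chi-square.

    PRR is NaN when b = 0 or a margin is empty.  chi2 uses expecteds from
    the table margins (E_a = (a+b)(a+c)/N); Yates subtracts 0.5 from each
    |O − E| when requested.  chi2 is NaN when any margin is zero.
    """
    a, b, c, d = _asfloat(a, b, c, d)
    if continuity_correction:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        ap, bp, cp, dp = (np.where(zero, x + 0.5, x) for x in (a, b, c, d))
    else:
        ap, bp, cp, dp = a, b, c, d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (ap / (ap + cp)) / (bp / (bp + dp))
    prr = np.where((ap + cp == 0) | (bp + dp == 0) | (bp == 0), np.nan, prr)

    n = a + b + c + d
    row1, row2 = a + b, c + d     # event / non-event margins
    col1, col2 = a + c, b + d     # drug / other-drug margins
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.zeros_like(a)
        for obs, rm, cm in ((a, row1, col1), (b, row1, col2),
                            (c, row2, col1), (d, row2, col2)):
            e = rm * cm / n
            dev = np.abs(obs - e)
            if yates:
                dev = np.maximum(dev - 0.5, 0.0)
            chi2 = chi2 + np.where(e > 0, dev ** 2 / np.where(e > 0, e, 1.0),
                                   np.nan)
    chi2 = np.where((row1 == 0) | (row2 == 0) | (col1 == 0) | (col2 == 0),
                    np.nan, chi2)
    return prr, chi2


def ic_stats(a, b, c, d, prior: PriorConfig = PriorConfig(), *,
             smoothing: bool = True, ic025_method: str = "closed_form",
             mc_samples: int = 20_000, mc_seed: int = 0):
    """Vectorized information component and IC025 credibility bound.

    ``ic`` is the point estimate log2[a·N / ((a+c)(a+b))], computed with
    ``a + gamma11`` in place of ``a`` when ``smoothing`` so that a = 0 is
    finite.  ``ic025`` is E(IC) − 2·sqrt(V(IC)) from the closed-form
    posterior moments of the Beta/Dirichlet model (or the Monte-Carlo
    posterior 2.5% quantile).  Both are NaN when a margin is zero.
    """
    a, b, c, d = _asfloat(a, b, c, d)
    n = a + b + c + d
    m_event = a + b               # reports with the event
    m_drug = a + c                # reports with the drug
    bad = (m_event == 0) | (m_drug == 0)

    a_pt = a + prior.gamma11 if smoothing else a
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = np.log2(a_pt * n / (m_drug * m_event))
    ic = np.where(bad, np.nan, ic)

    g11, a1, b1 = prior.gamma11, prior.alpha1, prior.beta1
    al, be = prior.alpha, prior.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = g11 * (n + al) * (n + be) / ((m_drug + a1) * (m_event + b1))
        e_ic = np.log2((a + g11) * (n + al) * (n + be)
                       / ((n + gamma) * (m_drug + a1) * (m_event + b1)))
        v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
                + (n - m_drug + al - a1) / ((m_drug + a1) * (1 + n + al))
                + (n - m_event + be - b1) / ((m_event + b1) * (1 + n + be))
                ) / _LOG2 ** 2
    if ic025_method == "closed_form":
        ic025 = e_ic - 2.0 * np.sqrt(v_ic)
    elif ic025_method == "monte_carlo":
        rng = np.random.default_rng(mc_seed)
        shape = np.broadcast(a, b, c, d).shape or (1,)
        af, nf = np.broadcast_to(a, shape), np.broadcast_to(n, shape)
        mdf = np.broadcast_to(m_drug, shape)
        mef = np.broadcast_to(m_event, shape)
        gf = np.broadcast_to(gamma, shape)
        ic025 = np.empty(shape)
        for idx in np.ndindex(shape):
            p11 = rng.beta(af[idx] + g11,
                           nf[idx] - af[idx] + gf[idx] - g11, size=mc_samples)
            p1 = rng.beta(mdf[idx] + a1,
                          nf[idx] - mdf[idx] + al - a1, size=mc_samples)
            p2 = rng.beta(mef[idx] + b1,
                          nf[idx] - mef[idx] + be - b1, size=mc_samples)
            ic025[idx] = np.quantile(np.log2(p11 / (p1 * p2)), 0.025)
        if np.isscalar(n) or np.ndim(a) == 0:
            ic025 = ic025.reshape(np.shape(ic))
    else:
        raise ValueError("ic025_method must be 'closed_form' or 'monte_carlo'")
    ic025 = np.where(bad, np.nan, ic025)
    return ic, ic025


def signal_flags(a, ror_ci_low, prr, chi2, ic025):
    """Vectorized Table-6 criteria: returns (flag_ror, flag_prr, flag_bcpnn).

    flag_ror: ROR 95% CI lower bound > 1 and a >= 2.
    flag_prr: PRR >= 2 and chi2 >= 4 and a >= 3.
    flag_bcpnn: IC025 > 0.
    NaN statistics never flag.
    """
    a = np.asarray(a, dtype=float)
    ror_ci_low, prr, chi2, ic025 = _asfloat(ror_ci_low, prr, chi2, ic025)
    with np.errstate(invalid="ignore"):
        f_ror = np.isfinite(ror_ci_low) & (ror_ci_low > 1) & (a >= 2)
        f_prr = (np.isfinite(prr) & np.isfinite(chi2)
                 & (prr >= 2) & (chi2 >= 4) & (a >= 3))
        f_bcpnn = np.isfinite(ic025) & (ic025 > 0)
    return f_ror, f_prr, f_bcpnn


# ---------------------------------------------------------------------------
# scalar interfaces
# ---------------------------------------------------------------------------

def compute_ror(t: ContingencyTable, *, continuity_correction: bool = False
                ) -> tuple[float, float, float]:
    """ROR with Woolf 95% CI for one table; NaNs when any cell is zero."""
    ror, lo, hi = ror_stats(*t.as_tuple(),
                            continuity_correction=continuity_correction)
    return float(ror), float(lo), float(hi)


def compute_prr(t: ContingencyTable, *, yates: bool = False,
                continuity_correction: bool = False) -> tuple[float, float]:
    """PRR and Pearson chi-square for one table."""
    prr, chi2 = prr_stats(*t.as_tuple(), yates=yates,
                          continuity_correction=continuity_correction)
    return float(prr), float(chi2)


def compute_ic(t: ContingencyTable, prior: PriorConfig = PriorConfig(), *,
               smoothing: bool = True, ic025_method: str = "closed_form",
               mc_samples: int = 20_000, mc_seed: int = 0
               ) -> tuple[float, float]:
    """Information component point estimate and IC025 for one table."""
    ic, ic025 = ic_stats(*t.as_tuple(), prior, smoothing=smoothing,
                         ic025_method=ic025_method, mc_samples=mc_samples,
                         mc_seed=mc_seed)
    return float(ic), float(ic025)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def contingency_from_masks(exposed: np.ndarray,
                           has_event: np.ndarray) -> ContingencyTable:
    """Build the 2x2 table from per-report boolean exposure/event masks."""
    exposed = np.asarray(exposed, dtype=bool)
    has_event = np.asarray(has_event, dtype=bool)
    if exposed.shape != has_event.shape:
        raise ValueError("mask shapes differ")
    a = int(np.sum(exposed & has_event))
    c = int(np.sum(exposed & ~has_event))
    b = int(np.sum(~exposed & has_event))
    d = int(np.sum(~exposed & ~has_event))
    return ContingencyTable(a=a, b=b, c=c, d=d)


def build_contingency(dataset: AnalysisDataset, drug_group: str,
                      pt: str) -> ContingencyTable:
    """Count a/b/c/d for one (drug group, PT) pair against the full
    background of deduplicated reports in the dataset.

    A report exposed to several study drug groups contributes to ``a`` (or
    ``c``) for each of them; it is never counted in ``b``/``d`` for a group
    it is exposed to.
    """
    if dataset.n_reports == 0:
        raise ValueError("empty dataset")
    exposed = np.fromiter((drug_group in dataset.exposures[pid]
                           for pid in dataset.reports), dtype=bool,
                          count=dataset.n_reports)
    has_event = np.fromiter((pt in dataset.events[pid]
                             for pid in dataset.reports), dtype=bool,
                            count=dataset.n_reports)
    return contingency_from_masks(exposed, has_event)


def detect_signals(dataset: AnalysisDataset,
                   drug_groups: Sequence[str] | None = None,
                   pts: Sequence[str] | None = None,
                   prior: PriorConfig = PriorConfig(),
                   options: SignalOptions = SignalOptions()) -> pd.DataFrame:
    """Compute all three statistics for every (drug group, PT) pair with
    at least one co-occurring report.

    Returns a DataFrame with one row per pair, sorted by system organ class
    then preferred term, with per-algorithm signal flags.
    """
    if drug_groups is None:
        drug_groups = dataset.drug_groups
    if pts is None:
        pts = dataset.all_pts
    exp = dataset.exposure_matrix(drug_groups).to_numpy()
    evt = dataset.event_matrix(pts).to_numpy()

    # all pairwise cell counts at once: a[g, p] = #(exposed_g & event_p)
    a = exp.T.astype(np.int64) @ evt.astype(np.int64)
    n_drug = exp.sum(axis=0).astype(np.int64)[:, None]
    n_event = evt.sum(axis=0).astype(np.int64)[None, :]
    n = np.int64(exp.shape[0])
    c = n_drug - a
    b = n_event - a
    d = n - a - b - c

    rows = []
    gi, pi = np.nonzero(a >= 1)
    av, bv, cv, dv = a[gi, pi], b[gi, pi], c[gi, pi], d[gi, pi]
    ror, lo, hi = ror_stats(av, bv, cv, dv,
                            continuity_correction=options.continuity_correction)
    prr, chi2 = prr_stats(av, bv, cv, dv, yates=options.yates,
                          continuity_correction=options.continuity_correction)
    ic, ic025 = ic_stats(av, bv, cv, dv, prior,
                         smoothing=options.ic_smoothing,
                         ic025_method=options.ic025_method,
                         mc_samples=options.mc_samples, mc_seed=options.mc_seed)
    f_ror, f_prr, f_bcpnn = signal_flags(av, lo, prr, chi2, ic025)
    for k in range(len(gi)):
        pt = pts[pi[k]]
        rows.append({
            "soc": dataset.pt_to_soc.get(pt, ""),
            "pt_code": dataset.pt_to_code.get(pt),
            "pt": pt,
            "drug_group": drug_groups[gi[k]],
            "a": int(av[k]), "b": int(bv[k]),
            "c": int(cv[k]), "d": int(dv[k]),
            "ror": ror[k], "ror_ci_low": lo[k], "ror_ci_high": hi[k],
            "prr": prr[k], "chi2": chi2[k], "ic": ic[k], "ic025": ic025[k],
            "flag_ror": bool(f_ror[k]), "flag_prr": bool(f_prr[k]),
            "flag_bcpnn": bool(f_bcpnn[k]),
        })
    frame = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["soc", "pt", "drug_group"],
                                  kind="mergesort").reset_index(drop=True)
    return frame
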