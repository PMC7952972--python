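"""Cohort-level rate tables and group-comparison statistics.

Aggregates per-embryo classifications into the rate tables used to report
PGT cohorts (per rearrangement type, age band, fresh/FET, ...), with rates
formatted ``x.y(n/d)`` to one decimal, and runs the standard contingency
tests (Pearson chi-square without continuity correction, Fisher's exact
test) plus per-cycle clinical outcome summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "CohortTable",
    "format_rate",
    "tabulate",
    "chi_square",
    "fisher_exact",
    "auto_test",
    "outcome_summary",
]

CATEGORY_ORDER = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def format_rate(n: int, d: int) -> str:
    """Render a rate as ``x.y(n/d)`` with one decimal; ``NA`` if d == 0."""
    if d == 0:
        return "NA"
    return f"{100.0 * n / d:.1f}({n}/{d})"


@dataclass(frozen=True)
class CohortTable:
    """Per-group counts plus formatted rates.

    ``counts`` holds integer tallies (rows = groups); ``rates`` the
    ``x.y(n/d)`` strings against the informative denominator, matching the
    printed-table convention of excluding QC failures.
    """

    counts: pd.DataFrame
    rates: pd.DataFrame
    grouping: str

    def rate(self, group: str, item: str) -> str:
        return self.rates.loc[group, item]


def tabulate(records: pd.DataFrame, grouping: str = "group",
             group_order: list[str] | None = None) -> CohortTable:
    """Tally embryo classifications per group.

    ``records`` needs one row per biopsied embryo with columns
    ``grouping``, ``informative`` (bool) and ``category`` (I–V, ignored
    for non-informative embryos).  The informative count is the
    denominator for all category rates; euploid means category V.
    """
    for col in (grouping, "informative", "category"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    if records[grouping].isna().any():
        raise ValueError("unknown (missing) group label in records")
    groups = group_order or list(dict.fromkeys(records[grouping]))
    unknown = set(records[grouping]) - set(groups)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")

    rows = []
    for g in groups:
        sub = records[records[grouping] == g]
        info = sub[sub["informative"].astype(bool)]
        bad = set(info["category"]) - set(CATEGORY_ORDER)
        if bad:
            raise ValueError(f"unknown category label(s): {sorted(bad)}")
        row = {
            "embryos_biopsied": len(sub),
            "informative": len(info),
            "euploid": int((info["category"] == "V").sum()),
        }
        for cat in CATEGORY_ORDER[:4]:
            row[f"type_{cat}"] = int((info["category"] == cat).sum())
        rows.append(row)
    counts = pd.DataFrame(rows, index=pd.Index(groups, name=grouping))

    rates = pd.DataFrame(index=counts.index, dtype=object)
    rates["informative"] = [
        format_rate(r.informative, r.embryos_biopsied)
        for r in counts.itertuples()]
    rates["euploid"] = [
        format_rate(r.euploid, r.informative) for r in counts.itertuples()]
    for cat in CATEGORY_ORDER[:4]:
        rates[f"type_{cat}"] = [
            format_rate(getattr(r, f"type_{cat}"), r.informative)
            for r in counts.itertuples()]
    rates["type_I_plus_III"] = [
        format_rate(r.type_I + r.type_III, r.informative)
        for r in counts.itertuples()]
    rates["type_II_plus_III"] = [
        format_rate(r.type_II + r.type_III, r.informative)
        for r in counts.itertuples()]
    return CohortTable(counts, rates, grouping)


def chi_square(table) -> TestResult:
    """Pearson chi-square without continuity correction on an r x c table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    if np.any(t < 0):
        raise ValueError("negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(stat), int(df), float(p), "chi-square")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table (sum of hypergeometric
    probabilities not exceeding the observed table's)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("Fisher's exact test needs a non-negative 2x2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), 1, float(p), "fisher")


def auto_test(table) -> TestResult:
    """Fisher's exact when any expected 2x2 cell is below 5, else
    chi-square — the usual applied convention; both remain callable
    directly."""
    t = np.asarray(table, dtype=float)
    if t.shape == (2, 2):
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (expected < 5).any():
            return fisher_exact(t.astype(int))
    return chi_square(t)


def outcome_summary(transfers: pd.DataFrame) -> dict[str, object]:
    """Per-cycle clinical outcome rates.

    ``transfers`` needs one row per transfer cycle with columns
    ``embryos_transferred``, ``sacs``, ``clinical_pregnancy``,
    ``live_birth`` and ``early_miscarriage``.  The implantation rate is
    gestational sacs per embryo transferred; pregnancy, live-birth and
    early-miscarriage rates are per transfer cycle.
    """
    req = ("embryos_transferred", "sacs", "clinical_pregnancy",
           "live_birth", "early_miscarriage")
    for col in req:
        if col not in transfers.columns:
            raise ValueError(f"transfer records lack column {col!r}")
    if (transfers["sacs"] > transfers["embryos_transferred"]).any():
        raise ValueError("more gestational sacs than embryos transferred")
    cycles = len(transfers)
    transferred = int(transfers["embryos_transferred"].sum())
    sacs = int(transfers["sacs"].sum())
    cp = int(transfers["clinical_pregnancy"].astype(bool).sum())
    lb = int(transfers["live_birth"].astype(bool).sum())
    mc = int(transfers["early_miscarriage"].astype(bool).sum())
    return {
        "cycles": cycles,
        "embryos_transferred": transferred,
        "implantation": format_rate(sacs, transferred),
        "clinical_pregnancy": format_rate(cp, cycles),
        "live_birth": format_rate(lb, cycles),
        "early_miscarriage": format_rate(mc, cycles),
        "implantation_pct": 100.0 * sacs / transferred if transferred else np.nan,
        "clinical_pregnancy_pct": 100.0 * cp / cycles if cycles else np.nan,
        "live_birth_pct": 100.0 * lb / cycles if cycles else np.nan,
        "early_miscarriage_pct": 100.0 * mc / cycles if cycles else np.nan,
    }
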