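"""Statistical primitives and cohort-comparison tables.

Implements the small set of inferential tools the analysis relies on:

* an exact two-sided Fisher test for 2x2 tables (hypergeometric enumeration
  with the probability-mass <= observed rule, computed in exact integer
  arithmetic),
* the Wald binomial confidence interval on the percentage scale,
* a Wilcoxon rank-sum test (exact for small untied samples, normal
  approximation with tie and continuity corrections otherwise),

plus builders for the demographics table, the per-test utilization
comparison, and a charge-based cost-savings estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AgeBand, Encounter, age_band

__all__ = [
    "DemographicsRow",
    "DemographicsTable",
    "ProportionCI",
    "Table2x2",
    "TestUtilization",
    "UtilizationComparison",
    "binomial_ci",
    "demographics_table",
    "estimate_savings",
    "fisher_exact_2x2",
    "rank_sum_test",
    "utilization_compare",
]

#: Test-flag fields in pattern-bit order (see scampqi.variation).
TEST_FIELDS = ("echo_done", "est_done", "holter_done", "event_monitor_done")
TEST_LABELS = {
    "echo_done": "echocardiogram",
    "est_done": "exercise stress test",
    "holter_done": "Holter monitor",
    "event_monitor_done": "event monitor",
}


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table; rows are groups, columns outcome/no-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its confidence interval, on the percentage scale."""

    numerator: int
    denominator: int
    estimate_pct: float
    ci_low_pct: float
    ci_high_pct: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")
        if not (
            0.0 <= self.ci_low_pct <= self.estimate_pct <= self.ci_high_pct <= 100.0
        ):
            raise ValueError("CI bounds must satisfy 0 <= low <= estimate <= high <= 100")

    @property
    def fraction(self) -> float:
        """The point estimate as a fraction in [0, 1]."""
        return self.numerator / self.denominator


def binomial_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wald binomial confidence interval, expressed in percent.

    ``p_hat +/- z * sqrt(p_hat (1 - p_hat) / n)``, clipped to [0, 100].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return ProportionCI(
        numerator=int(k),
        denominator=int(n),
        estimate_pct=100.0 * p,
        ci_low_pct=max(0.0, 100.0 * (p - half)),
        ci_high_pct=min(100.0, 100.0 * (p + half)),
        level=level,
    )


def fisher_exact_2x2(table: Table2x2) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums the conditional probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table.
    All arithmetic is exact (integer binomials), so the comparison carries no
    floating-point tolerance at all; exact ties are included.

    A table with any zero margin is degenerate (only one table is compatible
    with the margins) and returns p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    observed = math.comb(r1, a) * math.comb(r2, c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numer = 0
    for k in range(lo, hi + 1):
        weight = math.comb(r1, k) * math.comb(r2, c1 - k)
        if weight <= observed:
            numer += weight
    return float(Fraction(numer, math.comb(n, c1)))


def _exact_rank_sum_p(ranks_a: Sequence[float], n_total: int) -> float:
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    n1 = len(ranks_a)
    w_obs = sum(ranks_a)
    mu = n1 * (n_total + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for combo in combinations(range(1, n_total + 1), n1):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum test.

    Exact by enumeration when both samples have at most 10 observations and
    there are no ties; otherwise the normal approximation with tie correction
    and a continuity correction of 1/2. Returns p = 1 when the pooled variance
    is zero (all observations identical).
    """
    xs = [float(v) for v in sample_a]
    ys = [float(v) for v in sample_b]
    if not xs or not ys:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(xs), len(ys)
    n = n1 + n2
    pooled = np.asarray(xs + ys)
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n
    if n1 <= 10 and n2 <= 10 and not has_ties:
        return _exact_rank_sum_p(ranks[:n1], n)
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return 1.0
    z = max(0.0, (abs(w - mu) - 0.5) / math.sqrt(var))
    return min(1.0, 2.0 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# cohort-level comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestUtilization:
    """Per-era performed-rate for one diagnostic test, with a Fisher p."""

    test: str
    rate_historical: ProportionCI
    rate_scamp: ProportionCI
    fisher_p: float


@dataclass(frozen=True)
class UtilizationComparison:
    """Per-test utilization rates of two eras (the data behind Figure 2)."""

    n_historical: int
    n_scamp: int
    tests: Mapping[str, TestUtilization]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tu in self.tests.values():
            for era, ci in (
                ("historical", tu.rate_historical),
                ("scamp", tu.rate_scamp),
            ):
                rows.append(
                    {
                        "test": tu.test,
                        "era": era,
                        "n_performed": ci.numerator,
                        "n_total": ci.denominator,
                        "rate_pct": ci.estimate_pct,
                        "ci_low": ci.ci_low_pct,
                        "ci_high": ci.ci_high_pct,
                        "fisher_p": tu.fisher_p,
                    }
                )
        return pd.DataFrame(rows)


def utilization_compare(
    historical: Sequence[Encounter], scamp: Sequence[Encounter]
) -> UtilizationComparison:
    """Compare performed-rates of the four tests between eras."""
    if not historical or not scamp:
        raise ValueError("both cohorts must be nonempty")
    out = {}
    for fld in TEST_FIELDS:
        kh = sum(getattr(e, fld) for e in historical)
        ks = sum(getattr(e, fld) for e in scamp)
        nh, ns = len(historical), len(scamp)
        p = fisher_exact_2x2(Table2x2(kh, nh - kh, ks, ns - ks))
        out[fld] = TestUtilization(
            test=TEST_LABELS[fld],
            rate_historical=binomial_ci(kh, nh),
            rate_scamp=binomial_ci(ks, ns),
            fisher_p=p,
        )
    return UtilizationComparison(
        n_historical=len(historical), n_scamp=len(scamp), tests=out
    )


def estimate_savings(
    utilization: UtilizationComparison,
    unit_charges: Mapping[str, float],
    cost_to_charge: float,
) -> float:
    """Estimated cost savings from the drop in per-test utilization.

    For each test: (historical rate - scamp rate) x scamp cohort size x unit
    charge x cost-to-charge ratio, summed. Tests whose utilization increased
    contribute negative terms. A test with a nonzero rate difference but no
    unit charge raises ``KeyError``.
    """
    if not 0.0 < cost_to_charge <= 1.0:
        raise ValueError("cost_to_charge must be in (0, 1]")
    for test, charge in unit_charges.items():
        if charge <= 0:
            raise ValueError(f"unit charge for {test!r} must be positive")
    total = 0.0
    for key, tu in utilization.tests.items():
        diff = tu.rate_historical.fraction - tu.rate_scamp.fraction
        charge = unit_charges.get(key, unit_charges.get(tu.test))
        if charge is None:
            if diff != 0.0:
                raise KeyError(f"no unit charge for test {tu.test!r}")
            continue
        total += diff * utilization.n_scamp * charge * cost_to_charge
    return total


# ---------------------------------------------------------------------------
# demographics table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicsRow:
    label: str
    historical: str
    scamp: str
    p_value: Optional[float]


@dataclass(frozen=True)
class DemographicsTable:
    rows: Sequence[DemographicsRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.label,
                    "historical": r.historical,
                    "scamp": r.scamp,
                    "p_value": r.p_value,
                }
                for r in self.rows
            ]
        )

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)


def _fmt_pct(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else float("nan")
    if 0.0 < pct < 1.0:
        return f"{pct:.1f}"
    return f"{pct:.0f}"


def _binary_row(
    label: str,
    historical: Sequence[Encounter],
    scamp: Sequence[Encounter],
    flag: str,
) -> DemographicsRow:
    kh = sum(getattr(e, flag) for e in historical)
    ks = sum(getattr(e, flag) for e in scamp)
    nh, ns = len(historical), len(scamp)
    p = fisher_exact_2x2(Table2x2(kh, nh - kh, ks, ns - ks))
    return DemographicsRow(
        label,
        f"{kh} ({_fmt_pct(kh, nh)}%)",
        f"{ks} ({_fmt_pct(ks, ns)}%)",
        p,
    )


def demographics_table(
    historical: Sequence[Encounter], scamp: Sequence[Encounter]
) -> DemographicsTable:
    """Build the demographic/clinical comparison table.

    Sex and binary clinical features use Fisher's exact test; the age
    distribution uses the rank-sum test; the 3x2 age-band association uses a
    Pearson chi-square test (one p-value shared by the three band rows).
    """
    if not historical or not scamp:
        raise ValueError("both cohorts must be nonempty")
    nh, ns = len(historical), len(scamp)
    rows: list[DemographicsRow] = []

    males_h = sum(e.sex.value == "male" for e in historical)
    males_s = sum(e.sex.value == "male" for e in scamp)
    rows.append(
        DemographicsRow(
            "Male (n, %)",
            f"{males_h} ({_fmt_pct(males_h, nh)}%)",
            f"{males_s} ({_fmt_pct(males_s, ns)}%)",
            fisher_exact_2x2(Table2x2(males_h, nh - males_h, males_s, ns - males_s)),
        )
    )

    ages_h = [e.age_years for e in historical]
    ages_s = [e.age_years for e in scamp]
    rows.append(
        DemographicsRow(
            "Age (median, range in y)",
            f"{np.median(ages_h):g} ({min(ages_h):.0f}-{max(ages_h):.0f})",
            f"{np.median(ages_s):g} ({min(ages_s):.0f}-{max(ages_s):.0f})",
            rank_sum_test(ages_h, ages_s),
        )
    )

    band_counts = {}
    for era_name, cohort in (("historical", historical), ("scamp", scamp)):
        counts = {band: 0 for band in AgeBand}
        for e in cohort:
            counts[age_band(e.age_years)] += 1
        band_counts[era_name] = counts
    contingency = np.array(
        [
            [band_counts["historical"][band] for band in AgeBand],
            [band_counts["scamp"][band] for band in AgeBand],
        ]
    )
    if (contingency.sum(axis=0) > 0).all():
        chi2_p = float(stats.chi2_contingency(contingency, correction=False)[1])
    else:  # a band empty in both eras: drop it from the association test
        keep = contingency.sum(axis=0) > 0
        reduced = contingency[:, keep]
        chi2_p = (
            float(stats.chi2_contingency(reduced, correction=False)[1])
            if reduced.shape[1] > 1
            else 1.0
        )
    for i, band in enumerate(AgeBand):
        ch = band_counts["historical"][band]
        cs = band_counts["scamp"][band]
        rows.append(
            DemographicsRow(
                f"Age {band.value}, y (%)",
                f"{ch} ({_fmt_pct(ch, nh)})",
                f"{cs} ({_fmt_pct(cs, ns)})",
                chi2_p if i == 0 else None,
            )
        )

    for label, flag in (
        ("Exertional chest pain", "exertional_pain"),
        ("Associated palpitations", "palpitations"),
        ("Positive past medical history", "positive_pmh"),
        ("Positive family history", "positive_fh"),
        ("Abnormal physical examination", "abnormal_exam"),
        ("Abnormal ECG", "abnormal_ecg"),
    ):
        rows.append(_binary_row(label, historical, scamp, flag))
    return DemographicsTable(tuple(rows))
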