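"""The echocardiogram-indication rule, adherence accounting, and audit tables.

The decision rule is a disjunction over five clinical triggers: exertional
pain, pertinent past medical history, pertinent family history, abnormal
examination, abnormal ECG.  An encounter with none of the five has chest pain
only at rest without concerning features, where an echocardiogram is not
indicated.  Indications for the other three tests are not specified by the
plan analyzed here; a caller-supplied hook may provide them and defaults to
"never indicated".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import TRIGGER_FLAGS, DeviationCategory, Encounter, Era
from .inference import ProportionCI, Table2x2, binomial_ci, fisher_exact_2x2

__all__ = [
    "AdherenceResult",
    "AppropriatenessRow",
    "AppropriatenessTable",
    "DeviationTable",
    "adherence",
    "appropriateness_table",
    "deviation_table",
    "echo_indicated",
    "secondary_test_indicated",
]


def echo_indicated(encounter: Encounter) -> bool:
    """True iff any of the five trigger flags is set."""
    return any(getattr(encounter, flag) for flag in TRIGGER_FLAGS)


def secondary_test_indicated(
    encounter: Encounter,
    rule: Optional[Callable[[Encounter], bool]] = None,
) -> bool:
    """Indication hook for EST / rhythm monitors; defaults to never indicated."""
    return bool(rule(encounter)) if rule is not None else False


@dataclass(frozen=True)
class AdherenceResult:
    """Adherence to the echo recommendation, split by indication stratum.

    Either proportion is ``None`` when its stratum is empty (undefined, never
    silently 0/0).  ``n_indicated + n_not_indicated`` equals the number of
    encounters assessed.
    """

    followed_when_indicated: Optional[ProportionCI]
    withheld_when_not_indicated: Optional[ProportionCI]
    n_indicated: int
    n_not_indicated: int


def adherence(encounters: Sequence[Encounter]) -> AdherenceResult:
    """Adherence proportions with 95% CIs over a plan-era cohort."""
    if any(e.era is not Era.SCAMP for e in encounters):
        raise ValueError("adherence is defined for scamp-era encounters only")
    indicated = [e for e in encounters if echo_indicated(e)]
    not_indicated = [e for e in encounters if not echo_indicated(e)]
    followed = (
        binomial_ci(sum(e.echo_done for e in indicated), len(indicated))
        if indicated
        else None
    )
    withheld = (
        binomial_ci(sum(not e.echo_done for e in not_indicated), len(not_indicated))
        if not_indicated
        else None
    )
    return AdherenceResult(
        followed_when_indicated=followed,
        withheld_when_not_indicated=withheld,
        n_indicated=len(indicated),
        n_not_indicated=len(not_indicated),
    )


@dataclass(frozen=True)
class AppropriatenessRow:
    label: str
    historical: Optional[ProportionCI]
    scamp: Optional[ProportionCI]
    fisher_p: Optional[float]


@dataclass(frozen=True)
class AppropriatenessTable:
    rows: Sequence[AppropriatenessRow]

    def to_frame(self) -> pd.DataFrame:
        out = []
        for r in self.rows:
            rec = {"stratum": r.label, "fisher_p": r.fisher_p}
            for era, ci in (("historical", r.historical), ("scamp", r.scamp)):
                if ci is None:
                    rec[f"{era}"] = None
                    rec[f"{era}_pct"] = None
                else:
                    rec[f"{era}"] = f"{ci.numerator}/{ci.denominator}"
                    rec[f"{era}_pct"] = (
                        f"{ci.estimate_pct:.1f} "
                        f"{{{ci.ci_low_pct:.1f}-{ci.ci_high_pct:.1f}}}"
                    )
            out.append(rec)
        return pd.DataFrame(out)

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)


def _stratum_row(
    label: str,
    historical: Sequence[Encounter],
    scamp: Sequence[Encounter],
    member: Callable[[Encounter], bool],
    outcome: Callable[[Encounter], bool],
) -> AppropriatenessRow:
    strat_h = [e for e in historical if member(e)]
    strat_s = [e for e in scamp if member(e)]
    kh = sum(outcome(e) for e in strat_h)
    ks = sum(outcome(e) for e in strat_s)
    ci_h = binomial_ci(kh, len(strat_h)) if strat_h else None
    ci_s = binomial_ci(ks, len(strat_s)) if strat_s else None
    p = (
        fisher_exact_2x2(Table2x2(kh, len(strat_h) - kh, ks, len(strat_s) - ks))
        if strat_h and strat_s
        else None
    )
    return AppropriatenessRow(label, ci_h, ci_s, p)


def appropriateness_table(
    historical: Sequence[Encounter], scamp: Sequence[Encounter]
) -> AppropriatenessTable:
    """Appropriateness of echocardiogram use, per era.

    Row 1: among patients with exertional chest pain, the proportion who did
    *not* have an echocardiogram.  Row 2: among patients with pain only at
    rest and no concerning features (no trigger flags), the proportion who
    *did*.  Each row carries a two-sided Fisher p across eras.  Empty strata
    yield ``None`` entries rather than 0/0.
    """
    return AppropriatenessTable(
        (
            _stratum_row(
                "exertional chest pain, no echocardiogram",
                historical,
                scamp,
                lambda e: e.exertional_pain,
                lambda e: not e.echo_done,
            ),
            _stratum_row(
                "rest-only pain without concerning features, echocardiogram done",
                historical,
                scamp,
                lambda e: not echo_indicated(e),
                lambda e: e.echo_done,
            ),
        )
    )


@dataclass(frozen=True)
class DeviationTable:
    """Echocardiograms ordered despite a recommendation not to, by reason."""

    counts: Mapping[DeviationCategory, int]
    n: int

    def fraction(self, category: DeviationCategory) -> float:
        return self.counts[category] / self.n if self.n else 0.0

    def percent_display(self, category: DeviationCategory) -> int:
        """Percentage rounded to an integer for display."""
        return round(100.0 * self.fraction(category))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reason": cat.value,
                    "count": self.counts[cat],
                    "percent": self.percent_display(cat),
                }
                for cat in DeviationCategory
            ]
        )

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)


def deviation_table(encounters: Sequence[Encounter]) -> DeviationTable:
    """Tabulate stated deviation reasons.

    The universe is encounters with an echocardiogram performed although not
    indicated, with a deviation reason recorded.
    """
    universe = [
        e
        for e in encounters
        if e.echo_done and not echo_indicated(e) and e.deviation_reason is not None
    ]
    counts = {cat: 0 for cat in DeviationCategory}
    for e in universe:
        counts[e.deviation_reason] += 1
    return DeviationTable(counts=counts, n=len(universe))
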