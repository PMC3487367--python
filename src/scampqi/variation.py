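"""Testing-pattern census and the resampling test for practice variation.

Each encounter's diagnostic work-up is one of the 16 subsets of
{echocardiogram, exercise stress test, Holter, event monitor}, encoded as a
4-bit integer.  The number of *distinct* patterns observed in a cohort — its
pattern richness — measures practice variation; the difference in richness
between two cohorts is tested by resampling under a pooled null in which both
cohorts share a single empirical pattern distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Encounter

__all__ = [
    "N_PATTERNS",
    "PatternCensus",
    "VariationResult",
    "census_to_frame",
    "decode_pattern",
    "encode_pattern",
    "pattern_census",
    "pattern_of",
    "variation_test",
    "variation_test_codes",
]

N_PATTERNS = 16
_BIT_NAMES = ("echo", "est", "holter", "event_monitor")


def encode_pattern(echo: bool, est: bool, holter: bool, event: bool) -> int:
    """Encode the four test flags as an integer in [0, 15].

    ``code = echo*1 + est*2 + holter*4 + event*8``; :func:`decode_pattern` is
    the exact inverse.
    """
    return int(bool(echo)) | int(bool(est)) << 1 | int(bool(holter)) << 2 | int(bool(event)) << 3


def decode_pattern(code: int) -> tuple[bool, bool, bool, bool]:
    """Inverse of :func:`encode_pattern`."""
    if not 0 <= code < N_PATTERNS:
        raise ValueError(f"pattern code must be in [0, {N_PATTERNS - 1}], got {code!r}")
    return bool(code & 1), bool(code & 2), bool(code & 4), bool(code & 8)


def pattern_of(encounter: Encounter) -> int:
    """The testing-pattern code of one encounter."""
    return encode_pattern(
        encounter.echo_done,
        encounter.est_done,
        encounter.holter_done,
        encounter.event_monitor_done,
    )


@dataclass(frozen=True)
class PatternCensus:
    """Counts of every testing pattern in one cohort."""

    counts: Mapping[int, int]
    n: int
    richness: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(range(N_PATTERNS)):
            raise ValueError("counts must map every code 0..15")
        if sum(self.counts.values()) != self.n:
            raise ValueError("counts must sum to n")
        if self.richness != sum(1 for v in self.counts.values() if v > 0):
            raise ValueError("richness must equal the number of nonzero cells")


def pattern_census(encounters: Sequence[Encounter]) -> PatternCensus:
    """Census of testing patterns; errors on an empty cohort."""
    if not encounters:
        raise ValueError("cannot take a pattern census of an empty cohort")
    codes = np.array([pattern_of(e) for e in encounters])
    counts = np.bincount(codes, minlength=N_PATTERNS)
    return PatternCensus(
        counts={i: int(c) for i, c in enumerate(counts)},
        n=len(encounters),
        richness=int((counts > 0).sum()),
    )


def census_to_frame(census: PatternCensus) -> pd.DataFrame:
    """16-row table (code, test bits, count, percent) behind the variation figure."""
    rows = []
    for code in range(N_PATTERNS):
        bits = decode_pattern(code)
        row = {"code": code}
        row.update({name: int(b) for name, b in zip(_BIT_NAMES, bits)})
        row["count"] = census.counts[code]
        row["percent"] = 100.0 * census.counts[code] / census.n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariationResult:
    """Outcome of the practice-variation resampling test."""

    census_a: PatternCensus
    census_b: PatternCensus
    observed_diff: int
    p_value: float
    n_resamples: int
    seed: int
    method: str = "pooled_bootstrap"


def _row_richness(codes: np.ndarray) -> np.ndarray:
    """Pattern richness of each row of a (resamples x n) code matrix."""
    n_rows = codes.shape[0]
    offset = codes + N_PATTERNS * np.arange(n_rows)[:, None]
    counts = np.bincount(offset.ravel(), minlength=N_PATTERNS * n_rows)
    return (counts.reshape(n_rows, N_PATTERNS) > 0).sum(axis=1)


def _census_of_codes(codes: np.ndarray) -> PatternCensus:
    counts = np.bincount(codes, minlength=N_PATTERNS)
    return PatternCensus(
        counts={i: int(c) for i, c in enumerate(counts)},
        n=len(codes),
        richness=int((counts > 0).sum()),
    )


def variation_test_codes(
    codes_a: Sequence[int],
    codes_b: Sequence[int],
    n_resamples: int = 10_000,
    seed: int = 0,
    method: str = "pooled_bootstrap",
    _chunk: int = 2_000,
) -> VariationResult:
    """:func:`variation_test` on raw pattern codes instead of encounters."""
    codes_a = np.asarray(codes_a, dtype=np.int64)
    codes_b = np.asarray(codes_b, dtype=np.int64)
    if codes_a.size == 0 or codes_b.size == 0:
        raise ValueError("both cohorts must be nonempty")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if method not in ("pooled_bootstrap", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    census_a = _census_of_codes(codes_a)
    census_b = _census_of_codes(codes_b)
    observed = census_a.richness - census_b.richness

    pool = np.concatenate([codes_a, codes_b])
    na, nb = len(codes_a), len(codes_b)

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_resamples:
        r = min(_chunk, n_resamples - done)
        if method == "pooled_bootstrap":
            ra = _row_richness(pool[rng.integers(0, len(pool), size=(r, na))])
            rb = _row_richness(pool[rng.integers(0, len(pool), size=(r, nb))])
        else:
            order = np.argsort(rng.random((r, len(pool))), axis=1)
            permuted = pool[order]
            ra = _row_richness(permuted[:, :na])
            rb = _row_richness(permuted[:, na:])
        exceed += int(np.sum(np.abs(ra - rb) >= abs(observed)))
        done += r

    return VariationResult(
        census_a=census_a,
        census_b=census_b,
        observed_diff=observed,
        p_value=(1 + exceed) / (n_resamples + 1),
        n_resamples=n_resamples,
        seed=seed,
        method=method,
    )


def variation_test(
    cohort_a: Sequence[Encounter],
    cohort_b: Sequence[Encounter],
    n_resamples: int = 10_000,
    seed: int = 0,
    method: str = "pooled_bootstrap",
) -> VariationResult:
    """Two-sided resampling test for a change in pattern richness.

    The statistic is ``richness(a) - richness(b)``.  Under the default
    ``pooled_bootstrap`` null both cohorts share the pooled empirical pattern
    distribution: each resample redraws |a| and |b| encounters *with
    replacement* from the pooled codes and recomputes the richness
    difference.  ``method="permutation"`` instead relabels the pooled codes
    (sampling without replacement).  In both cases

        p = (1 + #{ |diff*| >= |observed| }) / (n_resamples + 1)

    so p has resolution 1/(n_resamples + 1) and is never exactly 0.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be nonempty")
    return variation_test_codes(
        [pattern_of(e) for e in cohort_a],
        [pattern_of(e) for e in cohort_b],
        n_resamples=n_resamples,
        seed=seed,
        method=method,
    )
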