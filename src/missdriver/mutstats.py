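"""Mutation-preference statistics over driver/passenger substitution counts.

Substitution preferences (n_ij / N), driver-vs-passenger odds ratios with
explicit flags for class-unique substitutions, motif preference calls at the
>=1.2 / <=0.8 odds cutoffs, Fisher's exact test for residue-composition
differences, and Wilson score intervals for mutation-frequency plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from ._aminoacids import AA20
from .io import MutationRecord


@dataclass
class SubstitutionCounts:
    """20x20 wt->mut substitution counts per class; the diagonal is undefined
    (a missense substitution never maps a residue to itself)."""

    counts_driver: np.ndarray = field(
        default_factory=lambda: np.zeros((20, 20), dtype=int)
    )
    counts_passenger: np.ndarray = field(
        default_factory=lambda: np.zeros((20, 20), dtype=int)
    )

    def __post_init__(self) -> None:
        for name in ("counts_driver", "counts_passenger"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (20, 20):
                raise ValueError(f"{name} must be 20x20, got {arr.shape}")
            if np.any(np.diag(arr) != 0):
                raise ValueError(f"{name}: diagonal must stay empty")
            setattr(self, name, arr)

    @property
    def n_driver(self) -> int:
        return int(self.counts_driver.sum())

    @property
    def n_passenger(self) -> int:
        return int(self.counts_passenger.sum())

    @classmethod
    def from_records(cls, records: Sequence[MutationRecord]) -> "SubstitutionCounts":
        sc = cls()
        for r in records:
            if r.wt not in AA20 or r.mut not in AA20:
                continue
            i, j = AA20.index(r.wt), AA20.index(r.mut)
            if r.label == "driver":
                sc.counts_driver[i, j] += 1
            elif r.label == "passenger":
                sc.counts_passenger[i, j] += 1
        return sc

    def table(self, label: str) -> np.ndarray:
        if label == "driver":
            return self.counts_driver
        if label == "passenger":
            return self.counts_passenger
        raise ValueError(f"class must be driver or passenger, got {label!r}")


def substitution_preference(counts: SubstitutionCounts, label: str) -> np.ndarray:
    """Relative substitution frequencies n_ij / N for one class; sums to 1."""
    table = counts.table(label)
    total = table.sum()
    if total == 0:
        raise ValueError(f"no {label} substitutions: preference undefined")
    return table / total


@dataclass(frozen=True)
class OddsResult:
    """Odds ratio of one substitution with a uniqueness flag.

    flag: 'ok' (finite, both classes observed), 'driver-unique' (absent in
    passengers; odds undefined/infinite), 'passenger-unique' (absent in
    drivers; odds 0), 'unobserved' (absent in both).
    """

    odds: float
    flag: str


def odds_ratio(counts: SubstitutionCounts, wt: str, mut: str) -> OddsResult:
    """Driver-vs-passenger odds of one substitution:
    (n_D / N_D) / (n_P / N_P); > 1 means driver-preferred.

    No continuity correction: class-unique substitutions are reported as
    flags, not forced to a number.
    """
    i, j = AA20.index(wt), AA20.index(mut)
    if i == j:
        raise ValueError("wt == mut has no defined odds")
    n_d = int(counts.counts_driver[i, j])
    n_p = int(counts.counts_passenger[i, j])
    nd_total, np_total = counts.n_driver, counts.n_passenger
    if nd_total == 0 or np_total == 0:
        raise ValueError("both classes need at least one substitution")
    if n_d == 0 and n_p == 0:
        return OddsResult(odds=float("nan"), flag="unobserved")
    if n_p == 0:
        return OddsResult(odds=float("inf"), flag="driver-unique")
    if n_d == 0:
        return OddsResult(odds=0.0, flag="passenger-unique")
    return OddsResult(odds=(n_d / nd_total) / (n_p / np_total), flag="ok")


def classify_motif_preference(
    odds: float, driver_cutoff: float = 1.2, passenger_cutoff: float = 0.8
) -> str:
    """Call a motif driver-preferred (odds >= 1.2), passenger-preferred
    (odds <= 0.8) or neither; both boundaries inclusive."""
    if odds < 0:
        raise ValueError(f"odds must be >= 0, got {odds}")
    if odds >= driver_cutoff:
        return "driver"
    if odds <= passenger_cutoff:
        return "passenger"
    return "neither"


def composition_fisher(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Fisher's exact test on a residue-vs-rest by class-a-vs-class-b 2x2 table.

    ``counts_a``/``counts_b`` are (count of this residue, count of all other
    residues) in each class. Returns (odds, two-sided p) by hypergeometric
    enumeration.
    """
    table = np.array([counts_a, counts_b])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in 2x2 table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)
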