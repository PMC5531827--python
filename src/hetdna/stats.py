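"""Cohort-level statistics: the headline computations of the study.

All functions return full-precision values; rounding is presentation-layer
only.  Statistical tests delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .genome import InvalidParameterError


def detection_fraction(n_co_both: int, n_co_one: int, n_co_none: int) -> float:
    """Fraction of crossover chromatids with an observable heteroduplex or
    conversion tract.

    Assuming every crossover leaves heteroduplex on both interacting
    chromatids, crossovers with tracts visible on both / one / neither
    chromatid give the per-chromatid detection fraction
    (2*both + one) / (2*(both + one + none)).  With the study's counts
    (23, 8, 2) this is 54/66 ~ 0.82, the basis of the "we detect about 80%
    of conversions" estimate.
    """
    if min(n_co_both, n_co_one, n_co_none) < 0:
        raise InvalidParameterError("counts must be non-negative")
    total = n_co_both + n_co_one + n_co_none
    if total < 1:
        raise InvalidParameterError("need at least one crossover")
    return (2 * n_co_both + n_co_one) / (2 * total)


def expected_dscb_mix(
    p_simple: float, n_dscb: int
) -> tuple[float, float, float]:
    """Expected DSCB composition if the two repairs are independent.

    With per-repair probability ``p_simple`` of a simple (Classes 1-8)
    outcome, ``n_dscb`` double-sister-chromatid-break events split as
    (n p^2, 2 n p (1-p), n (1-p)^2) into two-simple / one-each /
    two-complex.  Full precision; round only for presentation.
    """
    if not 0 <= p_simple <= 1:
        raise InvalidParameterError("p_simple must be in [0, 1]")
    p, n = float(p_simple), float(n_dscb)
    return (n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p))


def snp_density(n_variants: int, total_tract_bp: float) -> float:
    """Variants per bp over a set of tracts (report to 2 significant
    figures at presentation)."""
    if total_tract_bp <= 0:
        raise InvalidParameterError("total_tract_bp must be positive")
    return n_variants / total_tract_bp


def sector_frequency(n_sectored: int, n_total: int) -> float:
    """Red/white sectored colonies per division (simple ratio)."""
    if n_total <= 0 or not 0 <= n_sectored <= n_total:
        raise InvalidParameterError("need 0 <= n_sectored <= n_total, n_total > 0")
    return n_sectored / n_total


def independent_dscb_rate(scb_rate: float) -> float:
    """Expected apparent-DSCB rate if two SCB events were independent:
    the square of the per-assay SCB rate."""
    return scb_rate * scb_rate


def tract_median_cl(
    lengths: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Median tract length with a percentile-bootstrap confidence interval.

    Deterministic under ``seed``.  CO tract lengths should be pre-summed
    over the two crossover chromatids before pooling.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("need at least one length")
    med = float(np.median(arr))
    if arr.size == 1:
        return med, (med, med)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(int(n_boot), arr.size))
    boots = np.median(arr[idx], axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return med, (float(lo), float(hi))


def compare_counts(
    table,
    test: str = "fisher",
    *,
    expected_ratio: Optional[Sequence[float]] = None,
    continuity: bool = True,
):
    """Standard count comparisons used for report annotation.

    ``fisher``: 2x2 table, two-sided Fisher exact test.
    ``chi-square``: 1xk observed counts against ``expected_ratio``
    (default uniform); for 1x2 a Yates continuity correction is applied by
    default (this reproduces the study's quoted p-values).
    ``mann-whitney``: two samples.

    Returns (statistic, p).
    """
    if test == "fisher":
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise InvalidParameterError("fisher test needs a 2x2 table")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise InvalidParameterError("table has a zero margin")
        res = sps.fisher_exact(arr, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "chi-square":
        obs = np.asarray(table, dtype=float).ravel()
        if obs.sum() <= 0:
            raise InvalidParameterError("empty table")
        if expected_ratio is None:
            exp = np.full(obs.size, obs.sum() / obs.size)
        else:
            ratio = np.asarray(expected_ratio, dtype=float)
            exp = obs.sum() * ratio / ratio.sum()
        if obs.size == 2 and continuity:
            stat = float(np.sum((np.abs(obs - exp) - 0.5) ** 2 / exp))
        else:
            stat = float(np.sum((obs - exp) ** 2 / exp))
        p = float(sps.chi2.sf(stat, df=obs.size - 1))
        return stat, p
    if test == "mann-whitney":
        x, y = table
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise InvalidParameterError(f"unknown test {test!r}")


@dataclass
class CohortSummary:
    """Counts and distributions over a cohort of classified events."""

    n_colonies: int = 0
    initiation_counts: dict = field(default_factory=dict)
    outcome_counts: dict = field(default_factory=dict)
    class_counts: dict = field(default_factory=dict)
    nco_lengths: list = field(default_factory=list)
    co_lengths: list = field(default_factory=list)
    nco_median: Optional[float] = None
    nco_cl: Optional[tuple] = None
    co_median: Optional[float] = None
    co_cl: Optional[tuple] = None
    all_median: Optional[float] = None
    all_cl: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "n_colonies": self.n_colonies,
            "initiation_counts": dict(self.initiation_counts),
            "outcome_counts": dict(self.outcome_counts),
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "nco_median_bp": self.nco_median,
            "nco_cl_bp": self.nco_cl,
            "co_median_bp": self.co_median,
            "co_cl_bp": self.co_cl,
            "all_median_bp": self.all_median,
            "all_cl_bp": self.all_cl,
        }


def summarize_cohort(colony_calls, *, seed: int = 0, n_boot: int = 2000) -> CohortSummary:
    """Aggregate initiation/outcome/class counts and tract-length medians
    (CO lengths are already per-event sums over the two chromatids)."""
    s = CohortSummary(n_colonies=len(colony_calls))
    for call in colony_calls:
        s.initiation_counts[call.initiation] = (
            s.initiation_counts.get(call.initiation, 0) + 1
        )
        for ev in call.events:
            s.outcome_counts[ev.outcome] = s.outcome_counts.get(ev.outcome, 0) + 1
            if ev.event_class is not None:
                s.class_counts[ev.event_class] = (
                    s.class_counts.get(ev.event_class, 0) + 1
                )
            if ev.tract_length_bp is None:
                continue
            if ev.outcome == "CO":
                s.co_lengths.append(ev.tract_length_bp)
            elif ev.outcome == "NCO":
                s.nco_lengths.append(ev.tract_length_bp)
    if s.nco_lengths:
        s.nco_median, s.nco_cl = tract_median_cl(
            s.nco_lengths, n_boot=n_boot, seed=seed
        )
    if s.co_lengths:
        s.co_median, s.co_cl = tract_median_cl(
            s.co_lengths, n_boot=n_boot, seed=seed + 1
        )
    pooled = s.nco_lengths + s.co_lengths
    if pooled:
        s.all_median, s.all_cl = tract_median_cl(
            pooled, n_boot=n_boot, seed=seed + 2
        )
    return s
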