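"""Carrier-frequency, incidence and projection statistics.

The estimator is deliberately simple.  With ``x`` reportable alleles observed
in a cohort of ``n`` sequenced individuals, the carrier frequency is the
binomial proportion ``cf = x/n`` (each rare allele assumed to sit in a
distinct heterozygote).  Under Hardy–Weinberg equilibrium with major-allele
frequency p ~ 1, the disease-allele frequency is ``q = cf/2 = x/(2n)``, and
the birth incidence of the recessive disease is ``q**2``, reported as
"1 in round(1/q**2)".

Confidence intervals: the default is the Clopper–Pearson exact binomial
interval (Beta quantiles); an exact Poisson ("rate") interval on the carrier
count, Wilson score and Wald intervals are available via ``method=``.  The
rate interval is what classic clinical-statistics packages produce for a
count, and is the method reproduced by the packaged reference pipeline.
Incidence CI bounds are obtained by pushing the carrier-frequency bounds
through the same q = bound/2 transform; the lower CF bound maps to the rarer
incidence (larger denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, chi2

from .records import VariantRecord

__all__ = [
    "clopper_pearson",
    "poisson_rate_ci",
    "binomial_ci",
    "CarrierEstimate",
    "IncidenceEstimate",
    "ProjectionReport",
    "carrier_count",
    "carrier_frequency",
    "hwe_incidence",
    "project_census",
    "spectrum_matrix",
    "SpectrumResult",
    "round_half_up",
    "CI_METHODS",
]

CI_METHODS = ("clopper-pearson", "rate-poisson", "wilson", "wald")

CarrierPolicy = Literal["alleles_as_carriers", "genotype_aware"]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as report tables expect."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def _check_xn(x: int, n: int, conf: float) -> None:
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("x and n must be integers")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must be in (0, 1), got {conf}")


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial CI for a proportion x/n.

    The lower bound is the alpha/2 quantile of Beta(x, n-x+1) (0 when x = 0);
    the upper bound the 1-alpha/2 quantile of Beta(x+1, n-x) (1 when x = n).
    Coverage is conservative: at least ``conf`` for every true proportion.
    """
    _check_xn(x, n, conf)
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def poisson_rate_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact Poisson (Garwood) CI on the count x, scaled to a proportion of n.

    Treats the carrier count as a Poisson-distributed count of rare events —
    the classic "confidence interval for a rate".  Bounds on the count are
    ``chi2(alpha/2, 2x)/2`` and ``chi2(1-alpha/2, 2x+2)/2``; dividing by n
    gives bounds on the carrier frequency.  For rare events this is nearly
    identical to the exact binomial interval but not capped at 1.
    """
    _check_xn(x, n, conf)
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(chi2.ppf(alpha / 2, 2 * x)) / 2.0
    high = float(chi2.ppf(1 - alpha / 2, 2 * x + 2)) / 2.0
    return low / n, min(high / n, 1.0)


def binomial_ci(
    x: int, n: int, conf: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Dispatch to the requested CI method (see ``CI_METHODS``)."""
    if method == "clopper-pearson":
        return clopper_pearson(x, n, conf)
    if method == "rate-poisson":
        return poisson_rate_ci(x, n, conf)
    if method in ("wilson", "wald"):
        from statsmodels.stats.proportion import proportion_confint

        _check_xn(x, n, conf)
        sm_method = "wilson" if method == "wilson" else "normal"
        low, high = proportion_confint(x, n, alpha=1 - conf, method=sm_method)
        return max(float(low), 0.0), min(float(high), 1.0)
    raise ValueError(f"unknown CI method {method!r}; choose from {CI_METHODS}")


@dataclass(frozen=True)
class CarrierEstimate:
    """Carrier count, cohort size, frequency and its confidence interval."""

    population: str
    carriers: int
    cohort_n: int
    cf: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    ci_method: str = "clopper-pearson"
    policy: str = "alleles_as_carriers"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.cf <= self.ci_high <= 1.0):
            raise ValueError(
                f"CI ordering violated: {self.ci_low} <= {self.cf} <= {self.ci_high}"
            )

    @property
    def cf_percent(self) -> float:
        return 100.0 * self.cf

    def display_percent(self, decimals: int = 1) -> str:
        """Report-style "cf (low-high)" string in percent."""
        fmt = f"{{:.{decimals}f}}"
        return (
            f"{fmt.format(round_half_up(self.cf_percent, decimals))} "
            f"({fmt.format(round_half_up(100 * self.ci_low, decimals))}–"
            f"{fmt.format(round_half_up(100 * self.ci_high, decimals))})"
        )


@dataclass(frozen=True)
class IncidenceEstimate:
    """Hardy–Weinberg incidence derived from a carrier estimate.

    ``reciprocal`` is the n of "1 in n"; ``ci_reciprocal_low`` is the common
    bound (smaller denominator, from the upper CF bound) and
    ``ci_reciprocal_high`` the rare bound (larger denominator, from the lower
    CF bound).  Both are None when the corresponding bound is zero, and
    everything but q/q2 is None when no carriers were observed.
    """

    q: float
    q2: float
    reciprocal: Optional[int]
    ci_reciprocal_low: Optional[int]
    ci_reciprocal_high: Optional[int]
    no_observed_carriers: bool = False

    def display(self) -> str:
        if self.no_observed_carriers:
            return "no observed carriers"
        ci = ""
        if self.ci_reciprocal_low is not None:
            high = f"1/{self.ci_reciprocal_high:,}" if self.ci_reciprocal_high else "—"
            ci = f" (1/{self.ci_reciprocal_low:,}–{high})"
        return f"1/{self.reciprocal:,}{ci}"


@dataclass(frozen=True)
class ProjectionReport:
    """Census projection of carrier and affected-birth counts."""

    population_size: int
    annual_births: int
    total_carriers: int
    newborn_carriers_per_year: int
    affected_births_per_year: int


def carrier_count(
    records: Iterable[VariantRecord],
    population: str,
    policy: CarrierPolicy = "alleles_as_carriers",
) -> int:
    """Number of carrier individuals implied by the reportable records.

    ``alleles_as_carriers`` (default) sums allele counts, assuming each
    reportable allele sits in a distinct heterozygote.  ``genotype_aware``
    counts each homozygote once (``ac - nhom``); compound heterozygotes
    across variants are not resolvable from aggregate counts under either
    policy.  Records without the population contribute zero.
    """
    total = 0
    for r in records:
        counts = r.pop_counts.get(population)
        if counts is None:
            continue
        if policy == "alleles_as_carriers":
            total += counts.ac
        elif policy == "genotype_aware":
            total += counts.ac - counts.nhom
        else:
            raise ValueError(f"unknown carrier policy {policy!r}")
    return total


def carrier_frequency(
    x: int,
    n: int,
    conf: float = 0.95,
    method: str = "clopper-pearson",
    population: str = "",
    policy: str = "alleles_as_carriers",
) -> CarrierEstimate:
    """Carrier frequency x/n with a two-sided confidence interval."""
    _check_xn(x, n, conf)
    low, high = binomial_ci(x, n, conf, method)
    return CarrierEstimate(
        population=population,
        carriers=int(x),
        cohort_n=int(n),
        cf=x / n,
        ci_low=low,
        ci_high=high,
        conf_level=conf,
        ci_method=method,
        policy=policy,
    )


def _bound_to_reciprocal(cf_bound: float, percent_decimals: Optional[int]) -> Optional[int]:
    if cf_bound <= 0:
        return None
    pct = 100.0 * cf_bound
    if percent_decimals is not None:
        pct = round(pct, percent_decimals)
        if pct <= 0:
            return None
    q = pct / 200.0
    return int(round_half_up(1.0 / (q * q)))


def hwe_incidence(
    est: CarrierEstimate,
    ci_percent_decimals: Optional[int] = None,
) -> IncidenceEstimate:
    """Hardy–Weinberg incidence q**2 from a carrier-frequency estimate.

    With p ~ 1 the carrier frequency 2pq ~ 2q, so q = cf/2 = x/(2n) exactly.
    CI bounds are pushed through the same transform: the lower CF bound gives
    the rare incidence bound, the upper the common one.  When
    ``ci_percent_decimals`` is set, each CF bound is first rounded to that
    many decimals in percent — matching pipelines that transcribe displayed
    CI bounds into the incidence transform (the packaged reference estimates
    were produced that way, at 4 decimals).

    A zero carrier count yields the "no observed carriers" sentinel rather
    than an infinite denominator.
    """
    q = est.cf / 2.0
    q2 = q * q
    if est.carriers == 0:
        return IncidenceEstimate(
            q=q, q2=q2, reciprocal=None, ci_reciprocal_low=None,
            ci_reciprocal_high=None, no_observed_carriers=True,
        )
    return IncidenceEstimate(
        q=q,
        q2=q2,
        reciprocal=int(round_half_up(1.0 / q2)),
        ci_reciprocal_low=_bound_to_reciprocal(est.ci_high, ci_percent_decimals),
        ci_reciprocal_high=_bound_to_reciprocal(est.ci_low, ci_percent_decimals),
        no_observed_carriers=False,
    )


def project_census(
    inc: IncidenceEstimate,
    est: CarrierEstimate,
    population_size: int,
    annual_births: int,
) -> ProjectionReport:
    """Project carrier and affected-birth counts onto census figures.

    Carrier projections use the carrier frequency as displayed (rounded to
    one decimal in percent) — the convention of the reference report —
    while affected births use the unrounded q**2.
    """
    if population_size < 0 or annual_births < 0:
        raise ValueError("census figures must be non-negative")
    cf_displayed = round_half_up(est.cf_percent, 1) / 100.0
    return ProjectionReport(
        population_size=population_size,
        annual_births=annual_births,
        total_carriers=int(round_half_up(population_size * cf_displayed)),
        newborn_carriers_per_year=int(round_half_up(annual_births * cf_displayed)),
        affected_births_per_year=int(round_half_up(annual_births * inc.q2)),
    )


class SpectrumResult(NamedTuple):
    """Presence/absence matrix plus variants private to one population."""

    matrix: pd.DataFrame
    exclusive: dict[str, list[str]]


def spectrum_matrix(
    records: Sequence[VariantRecord],
    populations: Sequence[str],
) -> SpectrumResult:
    """Boolean variant-by-population presence matrix (True iff AC > 0).

    ``exclusive`` maps each population to the variants observed in it and in
    no other *requested* population.
    """
    data = {
        pop: [
            (r.pop_counts[pop].ac > 0) if pop in r.pop_counts else False
            for r in records
        ]
        for pop in populations
    }
    matrix = pd.DataFrame(data, index=[r.hgvs_c for r in records], columns=list(populations))
    exclusive: dict[str, list[str]] = {}
    row_sums = matrix.sum(axis=1)
    for pop in populations:
        exclusive[pop] = [
            hgvs for hgvs in matrix.index[(row_sums == 1) & matrix[pop]]
        ]
    return SpectrumResult(matrix=matrix, exclusive=exclusive)
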