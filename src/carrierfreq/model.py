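"""Model / Results interface for carrier-frequency estimation.

Follows the fit-then-inspect convention of statistical modelling packages:
:class:`CarrierFrequencyModel` is built from data (either a reportable-variant
record set or a raw carrier count), ``fit()`` returns a
:class:`CarrierFrequencyResults` carrying the estimates, their confidence
intervals, the derived Hardy–Weinberg incidence, and a ``summary()`` table;
census projection hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import Scheme, select_reportable
from .records import VariantRecord
from .stats import (
    CarrierEstimate,
    IncidenceEstimate,
    ProjectionReport,
    carrier_count,
    carrier_frequency,
    hwe_incidence,
    project_census,
    round_half_up,
)

__all__ = ["CarrierFrequencyModel", "CarrierFrequencyResults", "build_report"]


class CarrierFrequencyModel:
    """Binomial carrier-frequency model for one population.

    Parameters
    ----------
    carriers : int
        Observed carrier individuals (reportable alleles under the default
        counting policy).
    cohort_n : int
        Number of sequenced individuals in the population.
    population, scheme : str
        Labels carried through to reports.
    policy : str
        Carrier counting policy used to obtain ``carriers``.
    """

    def __init__(
        self,
        carriers: int,
        cohort_n: int,
        population: str = "",
        scheme: str = "",
        policy: str = "alleles_as_carriers",
        n_variants: Optional[int] = None,
    ) -> None:
        if cohort_n < 1:
            raise ValueError("cohort_n must be positive")
        if not 0 <= carriers <= cohort_n:
            raise ValueError(f"carriers must be in [0, cohort_n], got {carriers}")
        self.carriers = int(carriers)
        self.cohort_n = int(cohort_n)
        self.population = population
        self.scheme = str(scheme)
        self.policy = policy
        self.n_variants = n_variants

    @classmethod
    def from_records(
        cls,
        records: Sequence[VariantRecord],
        population: str,
        cohort_n: Optional[int] = None,
        policy: str = "alleles_as_carriers",
        scheme: str = "",
    ) -> "CarrierFrequencyModel":
        """Build from an already-reportable record set.

        ``cohort_n`` defaults to the cohort size declared on the records for
        this population.
        """
        if cohort_n is None:
            declared = {
                r.pop_counts[population].cohort_n
                for r in records
                if population in r.pop_counts and r.pop_counts[population].cohort_n
            }
            if len(declared) != 1:
                raise ValueError(
                    f"cohort_n for {population!r} is not uniquely declared on the "
                    f"records ({sorted(declared)}); pass it explicitly"
                )
            cohort_n = declared.pop()
        x = carrier_count(records, population, policy=policy)
        n_variants = sum(
            1 for r in records
            if population in r.pop_counts and r.pop_counts[population].ac > 0
        )
        return cls(
            carriers=x, cohort_n=cohort_n, population=population,
            scheme=scheme, policy=policy, n_variants=n_variants,
        )

    @classmethod
    def from_annotated_records(
        cls,
        records: Sequence[VariantRecord],
        population: str,
        scheme: Scheme | str,
        annotations: Mapping[str, object],
        cohort_n: Optional[int] = None,
        policy: str = "alleles_as_carriers",
    ) -> "CarrierFrequencyModel":
        """Select reportable records under ``scheme`` and build the model."""
        reportable = select_reportable(records, scheme, annotations)
        return cls.from_records(
            reportable, population, cohort_n=cohort_n, policy=policy,
            scheme=Scheme(scheme).value,
        )

    def fit(
        self,
        conf: float = 0.95,
        ci_method: str = "clopper-pearson",
        ci_percent_decimals: Optional[int] = None,
    ) -> "CarrierFrequencyResults":
        """Estimate the carrier frequency and derived incidence.

        ``ci_percent_decimals`` controls pre-rounding of CF bounds (in
        percent) before the incidence transform; None transforms unrounded
        bounds.
        """
        est = carrier_frequency(
            self.carriers, self.cohort_n, conf=conf, method=ci_method,
            population=self.population, policy=self.policy,
        )
        inc = hwe_incidence(est, ci_percent_decimals=ci_percent_decimals)
        return CarrierFrequencyResults(self, est, inc)


@dataclass(frozen=True)
class CarrierFrequencyResults:
    """Fitted carrier-frequency estimates and Hardy–Weinberg incidence."""

    model: CarrierFrequencyModel
    carrier: CarrierEstimate
    incidence: IncidenceEstimate

    @property
    def cf(self) -> float:
        return self.carrier.cf

    @property
    def conf_level(self) -> float:
        return self.carrier.conf_level

    def project(self, population_size: int, annual_births: int) -> ProjectionReport:
        """Project carrier and affected-birth counts onto census figures."""
        return project_census(self.incidence, self.carrier, population_size, annual_births)

    def to_dict(self) -> dict:
        """All unrounded intermediates, suitable for JSON export."""
        return {
            "population": self.model.population,
            "scheme": self.model.scheme,
            "policy": self.model.policy,
            "n_variants": self.model.n_variants,
            "carriers": self.carrier.carriers,
            "cohort_n": self.carrier.cohort_n,
            "carrier_frequency": self.carrier.cf,
            "cf_ci_low": self.carrier.ci_low,
            "cf_ci_high": self.carrier.ci_high,
            "conf_level": self.carrier.conf_level,
            "ci_method": self.carrier.ci_method,
            "q": self.incidence.q,
            "q2": self.incidence.q2,
            "incidence_denominator": self.incidence.reciprocal,
            "incidence_ci_common_denominator": self.incidence.ci_reciprocal_low,
            "incidence_ci_rare_denominator": self.incidence.ci_reciprocal_high,
            "no_observed_carriers": self.incidence.no_observed_carriers,
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        m = self.model
        lines = [
            "Carrier Frequency Model Results",
            "=" * 46,
            f"{'Population:':<28}{m.population or '—'}",
            f"{'Classification scheme:':<28}{m.scheme or '—'}",
            f"{'Counting policy:':<28}{m.policy}",
            f"{'Reportable variants:':<28}{m.n_variants if m.n_variants is not None else '—'}",
            f"{'Carrier individuals:':<28}{m.carriers}",
            f"{'Cohort size (individuals):':<28}{m.cohort_n}",
            "-" * 46,
            f"{'Carrier frequency:':<28}{self.carrier.display_percent()} %",
            f"{'CI method:':<28}{self.carrier.ci_method} "
            f"({100 * self.conf_level:.0f}%)",
            f"{'Disease allele freq q:':<28}{self.incidence.q:.6g}",
            f"{'HWE incidence q^2:':<28}{self.incidence.q2:.6g}",
            f"{'Estimated incidence:':<28}{self.incidence.display()}",
            "=" * 46,
        ]
        return "\n".join(lines)


def build_report(
    records: Sequence[VariantRecord],
    annotations: Mapping[str, Mapping[str, object]],
    schemes: Sequence[str],
    populations: Sequence[str],
    cohort_sizes: Optional[Mapping[str, int]] = None,
    conf: float = 0.95,
    ci_method: str = "clopper-pearson",
    ci_percent_decimals: Optional[int] = None,
    policy: str = "alleles_as_carriers",
) -> pd.DataFrame:
    """One report row per (population, scheme), in reference-table shape.

    ``annotations`` maps scheme name to its per-variant payload map.  Columns
    mirror the standard carrier-screening report: variant count, carrier
    count, carrier frequency % with CI, and reciprocal incidence with CI.
    """
    rows = []
    for pop in populations:
        for scheme in schemes:
            scheme = Scheme(scheme).value
            payloads = annotations.get(scheme, {})
            cohort_n = cohort_sizes.get(pop) if cohort_sizes else None
            model = CarrierFrequencyModel.from_annotated_records(
                records, pop, scheme, payloads, cohort_n=cohort_n, policy=policy
            )
            res = model.fit(
                conf=conf, ci_method=ci_method, ci_percent_decimals=ci_percent_decimals
            )
            rows.append(
                {
                    "population": pop,
                    "scheme": scheme,
                    "n_variants": model.n_variants,
                    "carriers": model.carriers,
                    "cohort_n": model.cohort_n,
                    "cf_pct": round_half_up(res.carrier.cf_percent, 1),
                    "cf_ci_low_pct": round_half_up(100 * res.carrier.ci_low, 1),
                    "cf_ci_high_pct": round_half_up(100 * res.carrier.ci_high, 1),
                    "incidence_denominator": res.incidence.reciprocal,
                    "incidence_ci_common": res.incidence.ci_reciprocal_low,
                    "incidence_ci_rare": res.incidence.ci_reciprocal_high,
                }
            )
    return pd.DataFrame(rows)
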