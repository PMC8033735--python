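"""Reproduction of the packaged reference estimates.

Re-runs the full pipeline on the packaged DHCR7 table and compares every
reported cell — carrier counts, carrier frequency with CI (one-decimal
percent), reciprocal incidence with CI — against the published reference
values, plus the Korean census projection.

The ACMG2015 rows are derived end-to-end from the packaged variant table
(annotation selection, column sums).  The HGMD and ClinVar rows use the
packaged scheme-level carrier/variant counts: those schemes drew on the full
gnomAD gene extract (variants beyond the PV/LPV table), which is not
redistributable here.  All statistics are recomputed either way.

The reference pipeline's CI convention is the exact Poisson rate interval
with CF bounds rounded to 4 decimals (percent) before the incidence
transform; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import Scheme, select_reportable
from .datasets import (
    GNOMAD_COHORTS,
    KOREAN_CENSUS,
    load_dhcr7_annotations,
    load_dhcr7_variants,
    load_reference_estimates,
)
from .model import CarrierFrequencyModel
from .stats import ProjectionReport, round_half_up

__all__ = ["ReproductionResult", "reproduce_reference"]

#: CI convention of the reference pipeline.
REFERENCE_CI_METHOD = "rate-poisson"
REFERENCE_CI_PERCENT_DECIMALS = 4


@dataclass
class ReproductionResult:
    """Recomputed report, projection, and any deviations from the reference."""

    report: pd.DataFrame
    projection: ProjectionReport
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def _check(mismatches: list[str], label: str, got, expected) -> None:
    if got != expected:
        mismatches.append(f"{label}: computed {got!r} != reference {expected!r}")


def reproduce_reference(conf: float = 0.95) -> ReproductionResult:
    """Recompute all six report rows and the census projection, with diffs."""
    reference = load_reference_estimates()
    records = load_dhcr7_variants()
    annotations = load_dhcr7_annotations()
    scheme_counts = reference["scheme_counts"]
    expected = reference["expected"]

    mismatches: list[str] = []
    rows = []
    results = {}
    for pop in ("EAS", "KOR"):
        for scheme in (Scheme.ACMG2015, Scheme.HGMD, Scheme.CLINVAR):
            packaged = scheme_counts[pop][scheme.value]
            if scheme is Scheme.ACMG2015:
                reportable = select_reportable(records, scheme, annotations[scheme.value])
                model = CarrierFrequencyModel.from_records(
                    reportable, pop, cohort_n=GNOMAD_COHORTS[pop], scheme=scheme.value
                )
                _check(
                    mismatches, f"{pop}/{scheme.value} carriers from variant table",
                    model.carriers, packaged["carriers"],
                )
                _check(
                    mismatches, f"{pop}/{scheme.value} variants from variant table",
                    model.n_variants, packaged["variants"],
                )
            else:
                model = CarrierFrequencyModel(
                    carriers=packaged["carriers"],
                    cohort_n=GNOMAD_COHORTS[pop],
                    population=pop,
                    scheme=scheme.value,
                    n_variants=packaged["variants"],
                )
            res = model.fit(
                conf=conf,
                ci_method=REFERENCE_CI_METHOD,
                ci_percent_decimals=REFERENCE_CI_PERCENT_DECIMALS,
            )
            results[(pop, scheme.value)] = res
            exp = expected[pop][scheme.value]
            cf_pct = round_half_up(res.carrier.cf_percent, 1)
            ci_pct = [
                round_half_up(100 * res.carrier.ci_low, 1),
                round_half_up(100 * res.carrier.ci_high, 1),
            ]
            label = f"{pop}/{scheme.value}"
            _check(mismatches, f"{label} cf%", cf_pct, exp["cf_pct"])
            _check(mismatches, f"{label} cf CI%", ci_pct, list(exp["cf_ci_pct"]))
            _check(
                mismatches, f"{label} incidence denominator",
                res.incidence.reciprocal, exp["incidence_denominator"],
            )
            _check(
                mismatches, f"{label} incidence CI denominators",
                [res.incidence.ci_reciprocal_low, res.incidence.ci_reciprocal_high],
                list(exp["incidence_ci_denominators"]),
            )
            rows.append(
                {
                    "population": pop,
                    "scheme": scheme.value,
                    "n_variants": model.n_variants,
                    "carriers": model.carriers,
                    "cohort_n": model.cohort_n,
                    "cf_pct": cf_pct,
                    "cf_ci_pct": f"{ci_pct[0]:.1f}–{ci_pct[1]:.1f}",
                    "incidence": res.incidence.display(),
                }
            )

    korean_acmg = results[("KOR", "ACMG2015")]
    projection = korean_acmg.project(
        KOREAN_CENSUS["population_size"], KOREAN_CENSUS["annual_births"]
    )
    exp_proj = reference["expected_projection"]["KOR"]
    _check(mismatches, "KOR total carriers", projection.total_carriers, exp_proj["total_carriers"])
    _check(
        mismatches, "KOR newborn carriers/year",
        projection.newborn_carriers_per_year, exp_proj["newborn_carriers_per_year"],
    )
    _check(
        mismatches, "KOR affected births/year",
        projection.affected_births_per_year, exp_proj["affected_births_per_year"],
    )

    return ReproductionResult(
        report=pd.DataFrame(rows), projection=projection, mismatches=mismatches
    )
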