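"""Core variant containers for population allele-count data.

A :class:`VariantRecord` is one alternate allele at one site, annotated with a
coding HGVS name, a Sequence-Ontology-style consequence term and per-population
allele counts in the gnomAD convention (AC = alternate allele count, AN = total
called alleles, nhom = homozygous-alternate individuals).  Cohort size (number
of sequenced individuals) is carried separately from AN because downstream
carrier statistics use the cohort as denominator, while AN varies per site with
call rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "PopulationCounts",
    "VariantRecord",
    "ConsequenceFilterSpec",
    "CONSEQUENCE_VOCABULARY",
    "DEFAULT_IMPACT_TERMS",
    "ValidationError",
]


class ValidationError(ValueError):
    """A record violated a structural invariant (e.g. AC > AN)."""


#: Controlled vocabulary of consequence terms understood by the filter.
CONSEQUENCE_VOCABULARY = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "synonymous_variant",
        "intron_variant",
        "start_lost",
        "other",
    }
)

#: Terms predicted to have a large impact on the protein: missense, nonsense,
#: stop-lost, frameshifts, in-frame indels, and the canonical (consensus)
#: splice-site positions.  ``splice_region_variant`` is deliberately excluded:
#: only the two canonical-site terms qualify as consensus splice changes.
DEFAULT_IMPACT_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)


@dataclass
class PopulationCounts:
    """Allele counts for one variant in one population.

    Parameters
    ----------
    population : str
        Population code (e.g. ``EAS``, ``KOR``).
    ac, an : int
        Alternate allele count and total called alleles at the site.
    nhom : int
        Number of homozygous-alternate individuals.
    cohort_n : int
        Declared number of sequenced individuals in the population.  When the
        source file does not declare it, callers may infer ``ceil(max AN / 2)``
        and must then set ``cohort_n_inferred``.
    """

    population: str
    ac: int
    an: int
    nhom: int = 0
    cohort_n: int = 0
    cohort_n_inferred: bool = False

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.nhom < 0:
            raise ValidationError(
                f"{self.population}: negative count (ac={self.ac}, an={self.an}, nhom={self.nhom})"
            )
        if self.ac > self.an:
            raise ValidationError(
                f"{self.population}: AC ({self.ac}) exceeds AN ({self.an})"
            )
        if 2 * self.nhom > self.ac:
            raise ValidationError(
                f"{self.population}: 2*nhom ({2 * self.nhom}) exceeds AC ({self.ac})"
            )
        if self.cohort_n and self.an > 2 * self.cohort_n:
            raise ValidationError(
                f"{self.population}: AN ({self.an}) exceeds 2*cohort_n ({2 * self.cohort_n})"
            )

    @property
    def frequency(self) -> float:
        """Allele frequency ac/an (0 when AN is 0)."""
        return self.ac / self.an if self.an else 0.0


_HGVS_SNV = re.compile(r"c\.[*+-]?\d+(?:[+-]\d+)?([ACGT])>([ACGT])$")


@dataclass
class VariantRecord:
    """One alternate allele with annotations and per-population counts.

    Genomic coordinates are 1-based (VCF convention).  Records sourced from
    frequency tables keyed on HGVS names may omit ``chrom``/``pos``/``ref``/
    ``alt``; for simple substitutions the alleles are recovered from the HGVS
    coding name.
    """

    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    consequence: str = "other"
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    pop_counts: dict[str, PopulationCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hgvs_c:
            raise ValidationError("hgvs_c must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref is None and self.alt is None:
            m = _HGVS_SNV.match(self.hgvs_c)
            if m:
                self.ref, self.alt = m.group(1), m.group(2)
        if self.ref is not None and self.ref == self.alt:
            raise ValidationError(f"{self.hgvs_c}: ref equals alt ({self.ref})")
        for code, counts in self.pop_counts.items():
            if counts.population != code:
                raise ValidationError(
                    f"{self.hgvs_c}: pop_counts key {code!r} does not match "
                    f"PopulationCounts.population {counts.population!r}"
                )

    def counts(self, population: str) -> Optional[PopulationCounts]:
        return self.pop_counts.get(population)

    @property
    def key(self) -> str:
        """Stable identifier used by annotation tables."""
        return self.hgvs_c


@dataclass(frozen=True)
class ConsequenceFilterSpec:
    """Which consequence terms count as large-impact and are retained."""

    included_terms: frozenset[str] = DEFAULT_IMPACT_TERMS

    def __post_init__(self) -> None:
        terms = frozenset(self.included_terms)
        object.__setattr__(self, "included_terms", terms)
        if not terms:
            raise ValidationError("ConsequenceFilterSpec needs at least one term")
        unknown = terms - CONSEQUENCE_VOCABULARY
        if unknown:
            raise ValidationError(f"unknown consequence terms: {sorted(unknown)}")

    def accepts(self, term: str) -> bool:
        return term in self.included_terms


def total_allele_count(records: Iterable[VariantRecord], population: str) -> int:
    """Sum of alternate allele counts over ``records`` for one population."""
    return sum(
        (r.pop_counts[population].ac if population in r.pop_counts else 0)
        for r in records
    )
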