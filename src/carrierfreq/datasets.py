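"""Packaged datasets: the DHCR7 study table, annotations and reference values.

The packaged variant table holds the pathogenic / likely pathogenic (PV/LPV)
DHCR7 variants observed in gnomAD v2.1.1 exomes with per-population allele
counts; cohort sizes follow the gnomAD v2.1.1 exome populations, with the
Korean subset (KOR, n=1909) of the East Asian cohort (EAS, n=9197) broken out.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .classify import load_annotation_table
from .io import parse_variant_tsv
from .records import VariantRecord

__all__ = [
    "GNOMAD_COHORTS",
    "KOREAN_CENSUS",
    "load_dhcr7_variants",
    "load_dhcr7_annotations",
    "load_reference_estimates",
]

#: Sequenced individuals per gnomAD v2.1.1 exome population (KOR is the
#: Korean subset of EAS).  These cohort sizes — not per-variant allele
#: numbers — are the denominators of all carrier statistics.
GNOMAD_COHORTS: dict[str, int] = {
    "KOR": 1909,
    "EAS": 9197,
    "AFR": 8128,
    "AMR": 17296,
    "ASJ": 5040,
    "FIN": 10824,
    "NFE": 56885,
    "OTH": 3070,
    "SAS": 15308,
}

#: 2019 South Korean census: total population and annual births.
KOREAN_CENSUS = {"population_size": 51_800_000, "annual_births": 302_676}


def _data_path(name: str):
    return resources.files("carrierfreq.data").joinpath(name)


def load_dhcr7_variants() -> list[VariantRecord]:
    """The packaged DHCR7 PV/LPV variant table (15 records).

    East Asian and Korean counts are present on every record; the seven other
    gnomAD populations only where the allele was observed there.
    """
    with resources.as_file(_data_path("dhcr7_gnomad_pvlpv.tsv")) as path:
        return parse_variant_tsv(path, cohort_sizes=GNOMAD_COHORTS)


def load_dhcr7_annotations() -> dict[str, dict[str, str]]:
    """Per-variant scheme annotations for the packaged table.

    Reportable status per scheme matches the published study; the individual
    ACMG evidence codes are illustrative stand-ins (the study did not publish
    its per-variant code assignments).
    """
    with resources.as_file(_data_path("dhcr7_annotations.tsv")) as path:
        return load_annotation_table(path)


@lru_cache(maxsize=1)
def load_reference_estimates() -> dict:
    """Published reference estimates and scheme-level carrier counts."""
    return json.loads(_data_path("dhcr7_reference_estimates.json").read_text())
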