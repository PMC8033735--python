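"""Variant pathogenicity classification under three schemes.

The central piece is the 2015 ACMG-AMP evidence-combining engine: evidence
codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) are tallied by strength
level and combined into the five-tier scale pathogenic / likely pathogenic /
uncertain significance / likely benign / benign.  Codes are consumed as given
(expert-assigned); no automatic strength modification or frequency-based code
assignment is performed.

Two label-mapping schemes are provided alongside: HGMD variant classes (only
``DM`` is reportable, not ``DM?``) and ClinVar aggregate clinical-significance
strings (reportable only when every assertion in the aggregate is Pathogenic
or Likely_pathogenic).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from .records import VariantRecord

__all__ = [
    "EvidenceSet",
    "Classification",
    "Scheme",
    "combine_acmg_evidence",
    "parse_acmg_codes",
    "reportable_from_clinvar",
    "reportable_from_hgmd",
    "load_annotation_table",
    "select_reportable",
    "is_reportable",
]


@dataclass(frozen=True)
class EvidenceSet:
    """Tallied ACMG-AMP evidence codes for one variant.

    ``pvs1`` and ``ba1`` are single stand-alone codes; the remaining fields
    count how many codes of that strength level were assigned.
    """

    pvs1: bool = False
    ps: int = 0
    pm: int = 0
    pp: int = 0
    ba1: bool = False
    bs: int = 0
    bp: int = 0

    _RANGES = {"ps": 4, "pm": 6, "pp": 5, "bs": 4, "bp": 7}

    def __post_init__(self) -> None:
        for name, upper in self._RANGES.items():
            v = getattr(self, name)
            if not (0 <= v <= upper):
                raise ValueError(f"{name.upper()} count {v} outside 0..{upper}")


class Classification(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Benign-to-pathogenic ordering, for monotonicity reasoning.
CLASS_ORDER = [
    Classification.BENIGN,
    Classification.LIKELY_BENIGN,
    Classification.UNCERTAIN,
    Classification.LIKELY_PATHOGENIC,
    Classification.PATHOGENIC,
]


class Scheme(str, enum.Enum):
    ACMG2015 = "ACMG2015"
    HGMD = "HGMD"
    CLINVAR = "CLINVAR"


def combine_acmg_evidence(ev: EvidenceSet) -> Classification:
    """Combine tallied evidence codes into a five-tier class.

    Pathogenic requires PVS1 with supporting pathogenic evidence, two strong
    codes, or one strong code with sufficient moderate/supporting backing;
    likely pathogenic the weaker combinations; benign requires BA1 or two
    strong benign codes; likely benign one strong-plus-supporting or two
    supporting benign codes.  If evidence qualifies for both a pathogenic-
    direction tier and a benign-direction tier, the result is uncertain
    significance (contradictory evidence), evaluated on the raw tier flags
    before either class is resolved.
    """
    pathogenic = (
        (ev.pvs1 and (ev.ps >= 1 or ev.pm >= 2 or (ev.pm >= 1 and ev.pp >= 1) or ev.pp >= 2))
        or ev.ps >= 2
        or (ev.ps == 1 and (ev.pm >= 3 or (ev.pm >= 2 and ev.pp >= 2) or (ev.pm >= 1 and ev.pp >= 4)))
    )
    likely_pathogenic = (
        (ev.pvs1 and ev.pm >= 1)
        or (ev.ps == 1 and ev.pm >= 1)
        or (ev.ps == 1 and ev.pp >= 2)
        or ev.pm >= 3
        or (ev.pm >= 2 and ev.pp >= 2)
        or (ev.pm >= 1 and ev.pp >= 4)
    )
    benign = ev.ba1 or ev.bs >= 2
    likely_benign = (ev.bs >= 1 and ev.bp >= 1) or ev.bp >= 2

    pathogenic_direction = pathogenic or likely_pathogenic
    benign_direction = benign or likely_benign
    if pathogenic_direction and benign_direction:
        return Classification.UNCERTAIN
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN


def parse_acmg_codes(codes: str) -> EvidenceSet:
    """Parse a comma-separated code list such as ``"PVS1,PM2,PP3"``.

    Codes are tallied by their strength prefix; an unrecognized token raises
    ``ValueError`` (a typo in an annotation table should not silently weaken
    a classification).
    """
    pvs1 = ba1 = False
    tallies = {"PS": 0, "PM": 0, "PP": 0, "BS": 0, "BP": 0}
    for token in codes.split(","):
        token = token.strip().upper()
        if not token:
            continue
        if token == "PVS1":
            pvs1 = True
        elif token == "BA1":
            ba1 = True
        elif token[:2] in tallies and token[2:].isdigit():
            tallies[token[:2]] += 1
        else:
            raise ValueError(f"unrecognized ACMG evidence code: {token!r}")
    return EvidenceSet(
        pvs1=pvs1, ps=tallies["PS"], pm=tallies["PM"], pp=tallies["PP"],
        ba1=ba1, bs=tallies["BS"], bp=tallies["BP"],
    )


_CLINVAR_REPORTABLE_TOKENS = {"pathogenic", "likely pathogenic"}
_CLINVAR_KNOWN_TOKENS = _CLINVAR_REPORTABLE_TOKENS | {
    "uncertain significance",
    "likely benign",
    "benign",
    "conflicting interpretations of pathogenicity",
    "conflicting classifications of pathogenicity",
    "not provided",
    "drug response",
    "risk factor",
    "association",
    "other",
    "affects",
    "protective",
}


def reportable_from_clinvar(clnsig: str) -> bool:
    """True iff a ClinVar aggregate label asserts only Pathogenic / Likely_pathogenic.

    The aggregate is split on ``/`` and ``,``; every component must be a P or
    LP assertion.  Aggregates containing any other assertion — including
    "Conflicting_interpretations_of_pathogenicity" — are conservatively not
    reportable.  Unrecognized labels warn and return False.
    """
    tokens = [
        t.strip().replace("_", " ").lower()
        for part in clnsig.split("/")
        for t in part.split(",")
    ]
    tokens = [t for t in tokens if t]
    if not tokens:
        return False
    unknown = [t for t in tokens if t not in _CLINVAR_KNOWN_TOKENS]
    if unknown:
        warnings.warn(
            f"unrecognized ClinVar label {clnsig!r}; treated as not reportable",
            stacklevel=2,
        )
        return False
    return all(t in _CLINVAR_REPORTABLE_TOKENS for t in tokens)


_HGMD_CLASSES = {"DM", "DM?", "DP", "DFP", "FP", "R"}


def reportable_from_hgmd(variant_class: str) -> bool:
    """True iff the HGMD class is exactly ``DM`` (not the uncertain ``DM?``)."""
    label = variant_class.strip()
    if label not in _HGMD_CLASSES:
        warnings.warn(
            f"unrecognized HGMD class {variant_class!r}; treated as not reportable",
            stacklevel=2,
        )
        return False
    return label == "DM"


Annotation = Union[EvidenceSet, str]


def is_reportable(scheme: Scheme | str, annotation: Annotation) -> bool:
    """Scheme-dispatching reportability decision for one annotation payload."""
    scheme = Scheme(scheme)
    if scheme is Scheme.ACMG2015:
        ev = annotation if isinstance(annotation, EvidenceSet) else parse_acmg_codes(str(annotation))
        return combine_acmg_evidence(ev) in (
            Classification.PATHOGENIC,
            Classification.LIKELY_PATHOGENIC,
        )
    if scheme is Scheme.HGMD:
        return reportable_from_hgmd(str(annotation))
    return reportable_from_clinvar(str(annotation))


def load_annotation_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a (hgvs_c, scheme, payload) TSV into ``{scheme: {hgvs_c: payload}}``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"hgvs_c", "scheme", "payload"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    table: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        table.setdefault(row["scheme"], {})[row["hgvs_c"]] = row["payload"]
    return table


def select_reportable(
    records: Sequence[VariantRecord],
    scheme: Scheme | str,
    annotations: Mapping[str, Annotation],
) -> list[VariantRecord]:
    """Order-preserving subset of records reportable under ``scheme``.

    ``annotations`` maps coding HGVS names to scheme payloads (an
    :class:`EvidenceSet` or code string for ACMG2015, a class/significance
    label otherwise).  Records without an annotation are treated as
    non-reportable with a warning.
    """
    missing = [r.hgvs_c for r in records if r.hgvs_c not in annotations]
    if missing:
        warnings.warn(
            f"{len(missing)} record(s) lack a {Scheme(scheme).value} annotation "
            f"and are treated as non-reportable: {missing[:5]}",
            stacklevel=2,
        )
    return [
        r
        for r in records
        if r.hgvs_c in annotations and is_reportable(scheme, annotations[r.hgvs_c])
    ]
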