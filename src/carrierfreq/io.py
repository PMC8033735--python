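"""Reading and writing gnomAD-style variant frequency data.

Two input dialects are supported:

* tab-separated tables (such as gnomAD browser exports) with configurable
  column names, one ``AC_<POP>`` / ``AN_<POP>`` (and optionally
  ``NHOM_<POP>``) column pair per population, and
* VCF 4.x with the gnomAD INFO convention (``AC_<pop>``, ``AN_<pop>``,
  ``nhomalt_<pop>``) and a VEP ``CSQ`` annotation string.

Both produce :class:`~carrierfreq.records.VariantRecord` lists; the consequence
filter then keeps only large-impact terms.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    DEFAULT_IMPACT_TERMS,
    CONSEQUENCE_VOCABULARY,
    ConsequenceFilterSpec,
    PopulationCounts,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TsvDialect",
    "ParseError",
    "ConfigurationError",
    "parse_variant_tsv",
    "write_variant_tsv",
    "parse_gnomad_vcf",
    "filter_by_consequence",
]


class ParseError(ValueError):
    """Malformed input row; the message names the offending line."""


class ConfigurationError(ValueError):
    """Requested populations or columns absent from the input."""


@dataclass(frozen=True)
class TsvDialect:
    """Column mapping for tabular variant inputs.

    Per-population columns are discovered from the header using the
    ``ac_pattern`` / ``an_pattern`` / ``nhom_pattern`` templates, where
    ``{pop}`` stands for the population code.
    """

    gene: str = "gene"
    hgvs_c: str = "hgvs_c"
    hgvs_p: str = "hgvs_p"
    consequence: str = "consequence"
    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    ac_pattern: str = "AC_{pop}"
    an_pattern: str = "AN_{pop}"
    nhom_pattern: str = "NHOM_{pop}"

    def population_codes(self, columns: Sequence[str]) -> list[str]:
        rx = re.compile("^" + re.escape(self.ac_pattern).replace(r"\{pop\}", "(.+)") + "$")
        codes = []
        for col in columns:
            m = rx.match(col)
            if m and self.an_pattern.format(pop=m.group(1)) in columns:
                codes.append(m.group(1))
        return codes


def _cell_int(row, col, line_no: int, default: Optional[int] = None) -> Optional[int]:
    if col not in row or pd.isna(row[col]) or row[col] == "":
        return default
    try:
        val = row[col]
        ival = int(float(str(val).replace(",", "")))
    except (TypeError, ValueError):
        raise ParseError(f"line {line_no}: column {col!r} is not an integer: {row[col]!r}")
    return ival


def parse_variant_tsv(
    path: str | Path,
    dialect: TsvDialect | None = None,
    cohort_sizes: Optional[dict[str, int]] = None,
) -> list[VariantRecord]:
    """Read a tab-separated variant frequency table into records.

    Zero allele counts are data, not absence: a row with ``AC=0`` is retained.
    A population is attached to a record whenever its AC cell is non-empty.
    When ``cohort_sizes`` does not declare a population, its cohort size is
    inferred as ``ceil(max AN / 2)`` over all rows and flagged
    ``cohort_n_inferred`` on every affected count.

    Raises
    ------
    ParseError
        On a malformed (non-integer) cell, naming the line number.
    ValidationError
        When a row violates count invariants such as AC > AN.
    """
    dialect = dialect or TsvDialect()
    cohort_sizes = dict(cohort_sizes or {})
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if dialect.hgvs_c not in df.columns:
        raise ConfigurationError(
            f"required column {dialect.hgvs_c!r} missing; found {list(df.columns)}"
        )
    pops = dialect.population_codes(list(df.columns))

    # First pass: collect per-population max AN so undeclared cohort sizes can
    # be inferred before records are built (cohort_n is validated on build).
    inferred: dict[str, int] = {}
    rows = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        parsed = {}
        for pop in pops:
            ac = _cell_int(row, dialect.ac_pattern.format(pop=pop), line_no)
            if ac is None:
                continue
            an = _cell_int(row, dialect.an_pattern.format(pop=pop), line_no, default=0)
            nhom = _cell_int(row, dialect.nhom_pattern.format(pop=pop), line_no, default=0)
            parsed[pop] = (ac, an, nhom)
        rows.append((line_no, row, parsed))
        for pop, (ac, an, nhom) in parsed.items():
            if pop not in cohort_sizes:
                inferred[pop] = max(inferred.get(pop, 0), math.ceil(an / 2))

    records: list[VariantRecord] = []
    for line_no, row, parsed in rows:
        pop_counts = {}
        for pop, (ac, an, nhom) in parsed.items():
            was_inferred = pop not in cohort_sizes
            cohort_n = cohort_sizes.get(pop, inferred.get(pop, 0))
            try:
                pop_counts[pop] = PopulationCounts(
                    population=pop,
                    ac=ac,
                    an=an,
                    nhom=nhom,
                    cohort_n=cohort_n,
                    cohort_n_inferred=was_inferred,
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
        pos = _cell_int(row, dialect.pos, line_no)
        records.append(
            VariantRecord(
                gene=row.get(dialect.gene, "") or "",
                hgvs_c=row[dialect.hgvs_c],
                hgvs_p=row.get(dialect.hgvs_p, "") or "",
                consequence=row.get(dialect.consequence, "") or "other",
                chrom=(row.get(dialect.chrom) or None),
                pos=pos,
                ref=(row.get(dialect.ref) or None),
                alt=(row.get(dialect.alt) or None),
                pop_counts=pop_counts,
            )
        )
    return records


def write_variant_tsv(
    records: Iterable[VariantRecord],
    path: str | Path,
    dialect: TsvDialect | None = None,
    populations: Optional[Sequence[str]] = None,
) -> None:
    """Serialize records to the tabular dialect (inverse of parse_variant_tsv)."""
    dialect = dialect or TsvDialect()
    records = list(records)
    if populations is None:
        seen: list[str] = []
        for r in records:
            for pop in r.pop_counts:
                if pop not in seen:
                    seen.append(pop)
        populations = seen
    rows = []
    for r in records:
        row: dict[str, object] = {
            dialect.gene: r.gene,
            dialect.hgvs_c: r.hgvs_c,
            dialect.hgvs_p: r.hgvs_p,
            dialect.consequence: r.consequence,
        }
        if r.chrom is not None:
            row[dialect.chrom] = r.chrom
        if r.pos is not None:
            row[dialect.pos] = r.pos
        for pop in populations:
            counts = r.pop_counts.get(pop)
            if counts is None:
                continue
            row[dialect.ac_pattern.format(pop=pop)] = counts.ac
            row[dialect.an_pattern.format(pop=pop)] = counts.an
            if counts.nhom:
                row[dialect.nhom_pattern.format(pop=pop)] = counts.nhom
        rows.append(row)
    cols = [dialect.gene, dialect.hgvs_c, dialect.hgvs_p, dialect.consequence]
    if any(dialect.chrom in row for row in rows):
        cols += [dialect.chrom, dialect.pos]
    for pop in populations:
        cols += [dialect.ac_pattern.format(pop=pop), dialect.an_pattern.format(pop=pop)]
        if any(dialect.nhom_pattern.format(pop=pop) in row for row in rows):
            cols.append(dialect.nhom_pattern.format(pop=pop))
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF ingestion


def _csq_field_names(vcf) -> list[str]:
    try:
        desc = vcf.get_header_type("CSQ")["Description"]
    except KeyError:
        return []
    if "Format:" not in desc:
        return []
    return desc.split("Format:", 1)[1].strip().strip('"').split("|")


def _vep_allele(ref: str, alt: str) -> str:
    # VEP's minimal-allele convention: SNVs keep the alt base; for simple
    # insertions/deletions sharing the first base, that base is trimmed and
    # deletions become "-".
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if len(ref) >= 1 and len(alt) > len(ref) and alt.startswith(ref[0]):
        return alt[1:]
    if len(ref) > len(alt) and alt and ref.startswith(alt[0]):
        return alt[1:] if len(alt) > 1 else "-"
    return alt


def parse_gnomad_vcf(
    path: str | Path,
    populations: Sequence[str],
    cohort_sizes: Optional[dict[str, int]] = None,
) -> list[VariantRecord]:
    """Read a gnomAD-convention VCF into one record per alternate allele.

    Multi-allelic sites are decomposed; per-population counts come from the
    ``AC_<pop>`` / ``AN_<pop>`` / ``nhomalt_<pop>`` INFO keys (population codes
    are matched case-insensitively against the lower-case gnomAD convention).
    The consequence, gene symbol and HGVS names are taken from the VEP ``CSQ``
    entry matching the alternate allele, preferring the canonical transcript.

    Raises
    ------
    ConfigurationError
        When an ``AC_<pop>``/``AN_<pop>`` INFO key for a requested population
        is missing from the header; the message lists the available keys.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    info_keys = set()
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "INFO":
                info_keys.add(h["ID"])
        except KeyError:
            continue
    key_map: dict[str, tuple[str, str, Optional[str]]] = {}
    for pop in populations:
        candidates = [pop, pop.lower()]
        ac_key = next(
            (f"AC_{c}" for c in candidates if f"AC_{c}" in info_keys), None
        )
        an_key = next(
            (f"AN_{c}" for c in candidates if f"AN_{c}" in info_keys), None
        )
        nhom_key = next(
            (f"nhomalt_{c}" for c in candidates if f"nhomalt_{c}" in info_keys), None
        )
        if ac_key is None or an_key is None:
            available = sorted(k for k in info_keys if k.startswith(("AC_", "AN_")))
            raise ConfigurationError(
                f"population {pop!r} has no AC/AN INFO keys; available: {available}"
            )
        key_map[pop] = (ac_key, an_key, nhom_key)

    csq_fields = _csq_field_names(vcf)
    records: list[VariantRecord] = []
    raw: list[tuple[dict, dict]] = []
    max_an: dict[str, int] = {p: 0 for p in populations}

    for variant in vcf:
        alts = variant.ALT or []
        csq_entries = []
        if csq_fields and variant.INFO.get("CSQ"):
            for entry in str(variant.INFO.get("CSQ")).split(","):
                vals = entry.split("|")
                csq_entries.append(dict(zip(csq_fields, vals)))
        for i, alt in enumerate(alts):
            fields: dict = {
                "gene": "",
                "hgvs_c": "",
                "hgvs_p": "",
                "consequence": "other",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": alt,
            }
            vep_allele = _vep_allele(variant.REF, alt)
            matching = [e for e in csq_entries if e.get("Allele", "") in (vep_allele, alt)]
            canonical = [e for e in matching if e.get("CANONICAL", "") == "YES"]
            chosen = (canonical or matching or [None])[0]
            if chosen:
                fields["gene"] = chosen.get("SYMBOL", "") or ""
                hgvs_c = chosen.get("HGVSc", "") or ""
                fields["hgvs_c"] = hgvs_c.split(":", 1)[-1] if hgvs_c else ""
                hgvs_p = chosen.get("HGVSp", "") or ""
                fields["hgvs_p"] = hgvs_p.split(":", 1)[-1] if hgvs_p else ""
                terms = (chosen.get("Consequence", "") or "").split("&")
                known = [t for t in terms if t in CONSEQUENCE_VOCABULARY]
                fields["consequence"] = known[0] if known else "other"
            if not fields["hgvs_c"]:
                fields["hgvs_c"] = f"g.{variant.POS}{variant.REF}>{alt}"
            counts = {}
            for pop, (ac_key, an_key, nhom_key) in key_map.items():
                ac_val = variant.INFO.get(ac_key)
                an_val = variant.INFO.get(an_key)
                if ac_val is None or an_val is None:
                    continue
                ac = (ac_val[i] if isinstance(ac_val, tuple) else int(ac_val))
                an = (an_val[i] if isinstance(an_val, tuple) else int(an_val))
                nhom = 0
                if nhom_key is not None:
                    nh = variant.INFO.get(nhom_key)
                    if nh is not None:
                        nhom = nh[i] if isinstance(nh, tuple) else int(nh)
                counts[pop] = (int(ac), int(an), int(nhom))
                max_an[pop] = max(max_an[pop], int(an))
            raw.append((fields, counts))

    cohort_sizes = dict(cohort_sizes or {})
    for fields, counts in raw:
        pop_counts = {}
        for pop, (ac, an, nhom) in counts.items():
            was_inferred = pop not in cohort_sizes
            cohort_n = cohort_sizes.get(pop, math.ceil(max_an[pop] / 2))
            pop_counts[pop] = PopulationCounts(
                population=pop, ac=ac, an=an, nhom=nhom,
                cohort_n=cohort_n, cohort_n_inferred=was_inferred,
            )
        records.append(VariantRecord(pop_counts=pop_counts, **fields))
    return records


# ---------------------------------------------------------------------------
# Consequence filtering


def filter_by_consequence(
    records: Sequence[VariantRecord],
    spec: ConsequenceFilterSpec | None = None,
) -> list[VariantRecord]:
    """Keep records whose predicted consequence is a large-impact term.

    Order-preserving and idempotent.  Terms outside the controlled vocabulary
    are excluded with a warning (never an error): an unknown annotation cannot
    be assumed to damage the protein.
    """
    spec = spec or ConsequenceFilterSpec()
    kept: list[VariantRecord] = []
    unknown: set[str] = set()
    for r in records:
        if spec.accepts(r.consequence):
            kept.append(r)
        elif r.consequence not in CONSEQUENCE_VOCABULARY:
            unknown.add(r.consequence)
    if unknown:
        warnings.warn(
            f"excluded records with unknown consequence terms: {sorted(unknown)}",
            stacklevel=2,
        )
    logger.info(
        "consequence filter: %d of %d records retained (%d removed)",
        len(kept), len(records), len(records) - len(kept),
    )
    return kept
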