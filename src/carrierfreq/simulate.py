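"""Synthetic gnomAD-like cohorts with known truth.

Diploid genotypes are drawn per individual and variant as Binomial(2, q) under
Hardy–Weinberg equilibrium, independently across variants (no linkage — the
downstream estimator is additive over rare allele counts, so linkage would
only matter for the compound-heterozygote accounting that aggregate counts
cannot resolve anyway).  Genotype matrices aggregate to the same AC/AN/nhom
records the IO layer produces, so every downstream stage can be exercised
without any external download, and parameter-recovery experiments can measure
estimator bias and confidence-interval coverage against the known truth.

Seeding: one master seed per configuration; replicate streams are derived
with ``numpy.random.SeedSequence(master).spawn(...)`` in replicate order, so
any replicate is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import Scheme, select_reportable
from .records import PopulationCounts, VariantRecord
from .stats import carrier_count, carrier_frequency, hwe_incidence

__all__ = [
    "VariantSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "aggregate",
    "recovery_experiment",
    "RecoverySummary",
    "cohort_to_tsv",
    "cohort_to_vcf",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class VariantSpec:
    """Truth for one simulated variant.

    ``q`` maps population code to the true pathogenic allele frequency;
    ``annotations`` maps scheme name to the payload the classifier will see
    (ACMG code string, HGMD class or ClinVar label).
    """

    hgvs_c: str
    consequence: str = "missense_variant"
    q: Mapping[str, float] = field(default_factory=dict)
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, freq in self.q.items():
            if not 0.0 <= freq <= 0.5:
                raise ConfigError(
                    f"{self.hgvs_c}: q[{pop}]={freq} outside [0, 0.5]"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort structure and truth parameters for one simulation."""

    seed: int
    populations: Sequence[tuple[str, int]]
    variants: Sequence[VariantSpec]
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        for code, n in self.populations:
            if n < 1:
                raise ConfigError(f"population {code!r}: n_individuals must be >= 1")
        if not 0.0 < self.conf_level < 1.0:
            raise ConfigError("conf_level must be in (0, 1)")

    def annotation_tables(self) -> dict[str, dict[str, str]]:
        """``{scheme: {hgvs_c: payload}}`` collected from the variant specs."""
        tables: dict[str, dict[str, str]] = {}
        for v in self.variants:
            for scheme, payload in v.annotations.items():
                tables.setdefault(Scheme(scheme).value, {})[v.hgvs_c] = payload
        return tables

    def true_sum_q(self, population: str) -> float:
        return float(sum(v.q.get(population, 0.0) for v in self.variants))


@dataclass
class SyntheticCohort:
    """Genotype matrices (individuals x variants, values 0/1/2) plus truth."""

    genotypes: dict[str, np.ndarray]
    truth: SimulationConfig

    @property
    def records(self) -> list[VariantRecord]:
        return aggregate(self)


def _simulate_genotypes(
    cfg: SimulationConfig, seed_seq: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed_seq)
    genotypes = {}
    for code, n in cfg.populations:
        qs = np.array([v.q.get(code, 0.0) for v in cfg.variants])
        genotypes[code] = rng.binomial(2, qs, size=(n, len(cfg.variants)))
    return genotypes


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw HWE genotypes for every population; reproducible under the seed."""
    return SyntheticCohort(
        genotypes=_simulate_genotypes(cfg, np.random.SeedSequence(cfg.seed)),
        truth=cfg,
    )


def aggregate(cohort: SyntheticCohort) -> list[VariantRecord]:
    """Collapse genotype matrices to per-variant AC/AN/nhom records."""
    cfg = cohort.truth
    pops = {code: n for code, n in cfg.populations}
    records = []
    for j, variant in enumerate(cfg.variants):
        pop_counts = {}
        for code, n in cfg.populations:
            column = cohort.genotypes[code][:, j]
            pop_counts[code] = PopulationCounts(
                population=code,
                ac=int(column.sum()),
                an=2 * n,
                nhom=int((column == 2).sum()),
                cohort_n=pops[code],
            )
        records.append(
            VariantRecord(
                gene="SIM",
                hgvs_c=variant.hgvs_c,
                consequence=variant.consequence,
                pop_counts=pop_counts,
            )
        )
    return records


@dataclass(frozen=True)
class RecoverySummary:
    """Parameter-recovery metrics for one population over many replicates."""

    population: str
    replicates: int
    true_sum_q: float
    mean_q_hat: float
    bias: float
    rmse: float
    coverage: Optional[float]
    coverage_mcse: Optional[float]
    sentinel_replicates: int
    policy_disagreements: int


def recovery_experiment(
    cfg: SimulationConfig,
    replicates: int,
    scheme: Scheme | str = Scheme.ACMG2015,
    ci_method: str = "clopper-pearson",
) -> dict[str, RecoverySummary]:
    """Full-pipeline recovery: simulate, select, estimate, check coverage.

    Per replicate: aggregate the cohort, select reportable variants under
    ``scheme`` using the config's annotation table, estimate the carrier
    frequency with its CI and the Hardy–Weinberg q.  Summarises, per
    population, the bias and RMSE of q_hat = x/(2n) against the true sum of
    pathogenic allele frequencies, the empirical CI coverage of the true
    carrier frequency 2*sum(q), the count of zero-carrier (sentinel)
    replicates, and how often the two carrier-counting policies disagree.
    """
    if replicates < 100:
        raise ConfigError("recovery_experiment needs at least 100 replicates")
    tables = cfg.annotation_tables()
    payloads = tables.get(Scheme(scheme).value, {})
    seeds = np.random.SeedSequence(cfg.seed).spawn(replicates)
    q_hats: dict[str, list[float]] = {code: [] for code, _ in cfg.populations}
    covered: dict[str, int] = {code: 0 for code, _ in cfg.populations}
    sentinels: dict[str, int] = {code: 0 for code, _ in cfg.populations}
    disagreements: dict[str, int] = {code: 0 for code, _ in cfg.populations}

    for seed_seq in seeds:
        cohort = SyntheticCohort(
            genotypes=_simulate_genotypes(cfg, seed_seq), truth=cfg
        )
        records = aggregate(cohort)
        reportable = (
            select_reportable(records, scheme, payloads) if payloads else records
        )
        for code, n in cfg.populations:
            x = carrier_count(reportable, code)
            x_geno = carrier_count(reportable, code, policy="genotype_aware")
            if x != x_geno:
                disagreements[code] += 1
            q_hats[code].append(x / (2 * n))
            if x == 0:
                sentinels[code] += 1
            true_cf = min(2 * cfg.true_sum_q(code), 1.0)
            est = carrier_frequency(
                min(x, n), n, conf=cfg.conf_level, method=ci_method
            )
            hwe_incidence(est)  # exercised for the sentinel path
            if est.ci_low <= true_cf <= est.ci_high:
                covered[code] += 1

    summaries = {}
    for code, n in cfg.populations:
        arr = np.array(q_hats[code])
        true_q = cfg.true_sum_q(code)
        cov = covered[code] / replicates if true_q > 0 else None
        mcse = (
            float(np.sqrt(cov * (1 - cov) / replicates)) if cov is not None else None
        )
        summaries[code] = RecoverySummary(
            population=code,
            replicates=replicates,
            true_sum_q=true_q,
            mean_q_hat=float(arr.mean()),
            bias=float(arr.mean() - true_q),
            rmse=float(np.sqrt(((arr - true_q) ** 2).mean())),
            coverage=cov,
            coverage_mcse=mcse,
            sentinel_replicates=sentinels[code],
            policy_disagreements=disagreements[code],
        )
    return summaries


def study_like_config(seed: int) -> SimulationConfig:
    """Simulation defaults emulating the packaged DHCR7 study conditions.

    East Asian (n=9197) and Korean (n=1909) cohorts; one simulated variant
    per packaged PV/LPV record with true allele frequency equal to the
    observed AC/AN in each population; annotations copied from the packaged
    annotation table so all three schemes are exercised.
    """
    from .datasets import load_dhcr7_annotations, load_dhcr7_variants

    records = load_dhcr7_variants()
    tables = load_dhcr7_annotations()
    variants = []
    for r in records:
        q = {
            pop: r.pop_counts[pop].frequency
            for pop in ("EAS", "KOR")
            if pop in r.pop_counts
        }
        annotations = {
            scheme: payloads[r.hgvs_c]
            for scheme, payloads in tables.items()
            if r.hgvs_c in payloads
        }
        variants.append(
            VariantSpec(
                hgvs_c=r.hgvs_c,
                consequence=r.consequence,
                q=q,
                annotations=annotations,
            )
        )
    return SimulationConfig(
        seed=seed,
        populations=(("EAS", 9197), ("KOR", 1909)),
        variants=tuple(variants),
    )


# ---------------------------------------------------------------------------
# Emission in the formats the IO layer reads


def cohort_to_tsv(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write the aggregated cohort in the tabular dialect ``parse_variant_tsv`` reads."""
    from .io import write_variant_tsv

    write_variant_tsv(aggregate(cohort), path)


def write_truth_sidecar(cohort: SyntheticCohort, path: str | Path) -> None:
    """JSON sidecar with the true simulation parameters, for recovery tests."""
    cfg = cohort.truth
    payload = {
        "seed": cfg.seed,
        "populations": [[code, n] for code, n in cfg.populations],
        "conf_level": cfg.conf_level,
        "variants": [
            {
                "hgvs_c": v.hgvs_c,
                "consequence": v.consequence,
                "q": dict(v.q),
                "annotations": dict(v.annotations),
            }
            for v in cfg.variants
        ],
        "true_sum_q": {code: cfg.true_sum_q(code) for code, _ in cfg.populations},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def cohort_to_vcf(cohort: SyntheticCohort, path: str | Path, chrom: str = "1") -> None:
    """Write a minimal VCF 4.2 with gnomAD-style INFO keys and a VEP CSQ field."""
    cfg = cohort.truth
    records = aggregate(cohort)
    pops = [code for code, _ in cfg.populations]
    lines = ["##fileformat=VCFv4.2", f"##contig=<ID={chrom}>"]
    for pop in pops:
        p = pop.lower()
        lines += [
            f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Allele count ({pop})">',
            f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Allele number ({pop})">',
            f'##INFO=<ID=nhomalt_{p},Number=A,Type=Integer,Description="Homozygote count ({pop})">',
        ]
    lines.append(
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        'Format: Allele|Consequence|SYMBOL|HGVSc|HGVSp|CANONICAL">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    bases = ("A", "C")
    for j, (spec, rec) in enumerate(zip(cfg.variants, records)):
        ref, alt = bases
        info = []
        for pop in pops:
            counts = rec.pop_counts[pop]
            p = pop.lower()
            info += [
                f"AC_{p}={counts.ac}",
                f"AN_{p}={counts.an}",
                f"nhomalt_{p}={counts.nhom}",
            ]
        info.append(
            f"CSQ={alt}|{spec.consequence}|SIM|SIM_TX:{spec.hgvs_c}||YES"
        )
        lines.append(
            f"{chrom}\t{1000 + 10 * j}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
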