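# Methods

## Estimand and model

The package estimates, for one population at a time, the carrier frequency of
an autosomal recessive disease from aggregate sequencing data, and derives
the expected birth incidence.  The data are per-variant alternate allele
counts (AC), total called alleles (AN) and homozygote counts (nhom) for a
cohort of `n` sequenced individuals; individual-level genotypes are not
available.

With `x` the total count of reportable alleles across the selected variants,
the model treats `x ~ Binomial(n, cf)`: every reportable allele is assumed to
occupy a distinct heterozygous individual.  This is the standard
approximation for rare disease alleles; the package quantifies it rather than
assuming it silently (see *Carrier counting policies*).  Under Hardy–Weinberg
equilibrium with major-allele frequency p ≈ 1, carrier frequency 2pq ≈ 2q,
so `q = cf/2 = x/(2n)` and incidence `= q²`, reported as `1 in
round(1/q²)`.  Note the denominator is the cohort size `n` declared for the
population, not the per-variant AN: AN varies per site with call rate and
would make carrier counts from different variants incommensurable.  Per-site
AN is retained for reporting and for allele-frequency checks only.

Consanguinity, population substructure (Wahlund effect), reduced penetrance
and prenatal loss are all outside the model; for diseases with substantial
in-utero mortality the q² figure is an upper bound on live-born incidence.

## Variant selection

Before any counting, variants pass a predicted-impact consequence filter.
The default retained set is missense, stop-gained (nonsense), stop-lost,
frameshift, in-frame insertion/deletion, and the two canonical splice-site
terms.  `splice_region_variant` is deliberately excluded: only
acceptor/donor-site changes qualify as consensus splice-site disruption under
the narrow reading this package adopts.  Unknown terms are excluded with a
warning, never an error.

Reportability is then decided per scheme:

* **ACMG2015.** The evidence-combining rules of the 2015 ACMG-AMP framework
  are implemented in full over tallied code counts (PVS1; PS 0–4; PM 0–6;
  PP 0–5; BA1; BS 0–4; BP 0–7).  Pathogenic-direction and benign-direction
  tiers are evaluated on the raw flags first; if both directions fire, the
  variant is uncertain significance (contradiction rule), otherwise the
  strongest tier wins.  The engine is verified against an independently
  hand-coded rule-table oracle over the exhaustive grid of evidence
  combinations, and by a monotonicity property (adding pathogenic-direction
  evidence never moves a variant toward benign, and vice versa).  Codes are
  consumed at face value from an annotation table keyed on the coding HGVS
  name; evidence-strength modification and automatic code assignment from
  frequency or in-silico scores are out of scope — code assignment is expert
  judgement, and this package only combines.
* **HGMD.** Reportable iff the class is exactly `DM`.  `DM?` encodes curator
  doubt and is excluded; treating it as reportable would not be conservative
  for carrier estimation.
* **ClinVar.** The aggregate string is split on `/` and `,`; reportable iff
  every assertion is Pathogenic or Likely_pathogenic.
  `Conflicting_interpretations_of_pathogenicity` is therefore not
  reportable — a deliberate conservative policy, switchable only by editing
  the annotation payloads, since the package does not re-adjudicate ClinVar
  submissions.

## Confidence intervals

Four CI methods are exposed; all operate on (x, n) at confidence `conf`
(default 0.95):

* `clopper-pearson` (default): exact binomial, Beta-quantile form; coverage
  is conservative (≥ nominal everywhere).  Verified against a direct
  binomial-tail bisection oracle to 1e-9 for all x ≤ n ≤ 200.
* `rate-poisson`: exact Poisson (Garwood) interval on the count,
  `[χ²(α/2, 2x)/2, χ²(1−α/2, 2x+2)/2] / n`.  For rare events it is nearly
  identical to Clopper–Pearson; it is what classic clinical-statistics
  software reports for a count, and it is the method under which the packaged
  reference estimates reproduce exactly.
* `wilson`, `wald`: standard approximations, for sensitivity analysis only
  (delegated to statsmodels).

Incidence CI bounds apply q = bound/2, 1/q² to each CF bound; the *lower* CF
bound maps to the *rarer* incidence (larger denominator).  Reports print the
common bound first.  A zero carrier count returns a "no observed carriers"
sentinel instead of an infinite denominator.

## Rounding conventions

All display rounding is half-up (2.5 → 3), matching clinical report style
rather than banker's rounding.  Carrier frequencies are displayed to one
decimal in percent.  Reciprocal incidences are rounded to the nearest
integer from the *unrounded* q.  For the CI bounds of the reproduction
pipeline, each CF bound is first rounded to 4 decimals in percent and then
transformed — this mirrors pipelines in which displayed interval bounds are
transcribed into the incidence calculation, and it is the convention under
which every packaged reference CI denominator reproduces exactly
(`ci_percent_decimals=4`; pass `None` for fully unrounded transforms, the
default for new analyses).  Census projections use the one-decimal displayed
carrier frequency for carrier counts and the unrounded q² for affected
births, again matching how such projections are quoted.

## Carrier counting policies

`alleles_as_carriers` (default) counts Σ AC: each allele one heterozygote.
`genotype_aware` counts Σ (AC − nhom), so each homozygote is one individual;
compound heterozygosity across variants is unresolvable from aggregate data
under either policy.  Simulation under the packaged study conditions (15
variants at the observed East Asian frequencies, n = 9197) shows the two
policies disagree in well under 1% of replicate cohorts, quantifying the
default's adequacy at these allele frequencies.  At common-variant
frequencies the default overestimates carriers and the genotype-aware policy
should be preferred.

## Packaged dataset and reproduction

The packaged table holds the 15 *DHCR7* PV/LPV variants observed in gnomAD
v2.1.1 East Asian exomes with per-population AC/AN (cohorts: EAS 9197, KOR
1909, AFR 8128, AMR 17,296, ASJ 5040, FIN 10,824, NFE 56,885, OTH 3070, SAS
15,308).  The reproduction pipeline (`carrierfreq.reproduce`, CLI
`carrierfreq reproduce`) derives the ACMG2015 rows entirely from this table
(selection → column sums 33 EAS / 19 KOR → statistics).  The HGMD and
ClinVar rows use packaged scheme-level counts (9 variants/21 alleles and 10/23
in EAS; 3/12 and 2/11 in KOR): those schemes classified the full gnomAD gene
extract, which includes variants outside the PV/LPV table and is not
redistributable, so their carrier totals are study inputs here while every
statistic computed from them is recomputed.  The packaged per-variant ACMG
evidence-code sets are synthetic illustrations (only the resulting
reportable status is authoritative); the per-variant HGMD/ClinVar labels are
likewise chosen so that scheme selection on the packaged table is
demonstrable, reproducing the EAS HGMD and KOR ClinVar totals exactly.

One small source discrepancy is worth noting: the source cohort is variously
given as 9191 or 9197 East Asians; this package uses 9197 throughout, which
is the figure consistent with the reference incidence 1/310,688.

## Synthetic cohorts

The generator emulates the study conditions: per population, `n` diploid
individuals; per variant, genotypes drawn i.i.d. Binomial(2, q) under HWE;
variants independent (no linkage — the estimator is additive over rare
allele counts and no haplotype information exists in the source data).
Aggregation to AC/AN/nhom is exact by construction (`AN = 2n`, i.e. full
call rate — real gnomAD sites have per-site missingness the simulator does
not model; nor are sequencing error, demography or consanguinity modelled).
Default parameters are the study conditions: EAS 9197 and KOR 1909
individuals, 15 variants at the observed allele frequencies.  Passing tests
therefore certify the estimator and intervals under idealized HWE sampling,
not robustness to call-rate variation or substructure.

Seeding: one master seed per configuration; replicate streams come from
`numpy.random.SeedSequence(master).spawn(k)` in replicate order, so any
replicate can be regenerated in isolation.

Validation experiments (sizes chosen to exercise the asymptotics at
desk-scale): CI coverage at true carrier frequencies 0.001–0.01 with
n = 10,000 over 2000 replicates must be ≥ nominal − 3·MCSE; estimator bias
under study conditions (n = 9197, Σq = 0.0018, 1000 replicates) must be
within 3 MCSE of zero; recovery is also checked at n ∈ {10³, 10⁴, 10⁵}.

## Known limitations

* No structural-variant or large-deletion handling; carrier frequencies from
  SNV/indel tables alone underestimate the true carrier burden for genes
  with recurrent deletions.
* Aggregate counts cannot detect compound heterozygotes or distinguish one
  homozygote from two heterozygotes without `nhom`.
* The five-tier engine implements the 2015 combining rules only — no
  Bayesian point systems or later refinements.
* Multi-allelic VCF sites are decomposed, but indel normalisation/left
  alignment and liftover are out of scope; consequence annotations are
  trusted as given.
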