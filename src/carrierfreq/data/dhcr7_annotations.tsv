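# Classification annotations for the packaged DHCR7 variant table, one row per
# (variant, scheme).  Scheme ACMG2015 payloads are comma-separated evidence
# codes; HGMD payloads are variant-class labels; CLINVAR payloads are aggregate
# clinical-significance strings.
# SYNTHETIC/ILLUSTRATIVE: the reportable status per scheme matches the published
# study, but the individual ACMG evidence codes were not published and the code
# sets below are plausible stand-ins, not curated assignments.
hgvs_c	scheme	payload
c.16C>T	ACMG2015	PVS1,PM2,PP3
c.356A>G	ACMG2015	PM1,PM2,PM5,PP3
c.724C>T	ACMG2015	PM1,PM2,PP2,PP3
c.725G>A	ACMG2015	PM1,PM2,PP2,PP3
c.730G>A	ACMG2015	PM1,PM2,PM5,PP3
c.852C>A	ACMG2015	PM1,PM2,PP2,PP3
c.860A>G	ACMG2015	PM1,PM2,PP2,PP3
c.907G>A	ACMG2015	PS1,PM1,PM2,PM3,PP3
c.1055G>A	ACMG2015	PS1,PM1,PM2,PP3
c.1084C>A	ACMG2015	PM1,PM2,PM5,PP3
c.1085G>A	ACMG2015	PM1,PM2,PM5,PP3
c.1139G>T	ACMG2015	PM1,PM2,PM5,PP3
c.1140C>A	ACMG2015	PVS1,PM2,PP3
c.1190C>T	ACMG2015	PM1,PM2,PP2,PP3
c.1426T>C	ACMG2015	PVS1,PM2
c.16C>T	HGMD	DM
c.356A>G	HGMD	DM?
c.724C>T	HGMD	DM
c.725G>A	HGMD	DM
c.730G>A	HGMD	DM
c.852C>A	HGMD	DM
c.860A>G	HGMD	DM?
c.907G>A	HGMD	DM
c.1055G>A	HGMD	DM?
c.1084C>A	HGMD	DM?
c.1085G>A	HGMD	DM
c.1139G>T	HGMD	DM?
c.1140C>A	HGMD	DM
c.1190C>T	HGMD	DM
c.1426T>C	HGMD	DM?
c.16C>T	CLINVAR	Likely_pathogenic
c.356A>G	CLINVAR	Likely_pathogenic
c.724C>T	CLINVAR	Pathogenic/Likely_pathogenic
c.725G>A	CLINVAR	Likely_pathogenic
c.730G>A	CLINVAR	Likely_pathogenic
c.852C>A	CLINVAR	Likely_pathogenic
c.860A>G	CLINVAR	Likely_pathogenic
c.907G>A	CLINVAR	Pathogenic
c.1055G>A	CLINVAR	Pathogenic/Likely_pathogenic
c.1084C>A	CLINVAR	Uncertain_significance
c.1085G>A	CLINVAR	Conflicting_interpretations_of_pathogenicity
c.1139G>T	CLINVAR	Uncertain_significance
c.1140C>A	CLINVAR	not_provided
c.1190C>T	CLINVAR	Uncertain_significance
c.1426T>C	CLINVAR	Likely_pathogenic
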