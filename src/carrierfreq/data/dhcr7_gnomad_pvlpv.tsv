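# DHCR7 pathogenic / likely pathogenic variants observed in gnomAD v2.1.1 exomes,
# with per-population allele counts (AC) and allele numbers (AN).
# Populations: KOR Korean, EAS East Asian (includes KOR), AFR African,
# AMR Latino/Admixed American, ASJ Ashkenazi Jewish, FIN Finnish,
# NFE non-Finnish European, OTH other, SAS South Asian.
# Empty AC/AN cells mean the allele was not observed in that population.
gene	hgvs_c	hgvs_p	consequence	AC_KOR	AN_KOR	AC_EAS	AN_EAS	AC_AFR	AN_AFR	AC_AMR	AN_AMR	AC_ASJ	AN_ASJ	AC_FIN	AN_FIN	AC_NFE	AN_NFE	AC_OTH	AN_OTH	AC_SAS	AN_SAS
DHCR7	c.16C>T	p.Gln6Ter	stop_gained	0	0	1	18394
DHCR7	c.356A>G	p.His119Arg	missense_variant	0	0	1	18382									8	113532			8	30502
DHCR7	c.724C>T	p.Arg242Cys	missense_variant	0	0	1	18394	3	16244							19	113650	1	6136	1	30616
DHCR7	c.725G>A	p.Arg242His	missense_variant	0	0	1	18394									4	113650
DHCR7	c.730G>A	p.Gly244Arg	missense_variant	0	0	1	18392									1	113638			6	30616
DHCR7	c.852C>A	p.Phe284Leu	missense_variant	0	0	1	18362
DHCR7	c.860A>G	p.Asn287Ser	missense_variant	0	0	1	18370
DHCR7	c.907G>A	p.Gly303Arg	missense_variant	10	3818	10	18386	4	16254	1	34580			1	21578	7	113704
DHCR7	c.1055G>A	p.Arg352Gln	missense_variant	1	3814	1	18270	2	16022							2	111962			1	30594
DHCR7	c.1084C>A	p.Arg362Ser	missense_variant	0	0	1	18308
DHCR7	c.1085G>A	p.Arg362His	missense_variant	0	0	1	18316									5	111722			3	30604
DHCR7	c.1139G>T	p.Cys380Phe	missense_variant	4	3816	4	18280
DHCR7	c.1140C>A	p.Cys380Ter	stop_gained	4	3818	4	18286
DHCR7	c.1190C>T	p.Ser397Leu	missense_variant	0	0	1	18046									2	109128
DHCR7	c.1426T>C	p.Ter476GlnextTer510	stop_lost	0	0	4	18276
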