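{
  "description": "Published reference estimates of DHCR7 carrier frequency and Smith-Lemli-Opitz syndrome incidence in gnomAD v2.1.1 East Asian (EAS) and Korean (KOR) exomes, under three classification schemes. Used as the regression reference for the reproduction pipeline. HGMD and CLINVAR scheme-level counts include variants outside the packaged PV/LPV table (classified from the full gnomAD gene extract) and are therefore study inputs here, not derivable from the packaged variant table.",
  "cohorts": {
    "KOR": 1909,
    "EAS": 9197,
    "AFR": 8128,
    "AMR": 17296,
    "ASJ": 5040,
    "FIN": 10824,
    "NFE": 56885,
    "OTH": 3070,
    "SAS": 15308
  },
  "census": {
    "KOR": {
      "population_size": 51800000,
      "annual_births": 302676
    }
  },
  "scheme_counts": {
    "EAS": {
      "ACMG2015": {"variants": 15, "carriers": 33},
      "HGMD": {"variants": 9, "carriers": 21},
      "CLINVAR": {"variants": 10, "carriers": 23}
    },
    "KOR": {
      "ACMG2015": {"variants": 4, "carriers": 19},
      "HGMD": {"variants": 3, "carriers": 12},
      "CLINVAR": {"variants": 2, "carriers": 11}
    }
  },
  "expected": {
    "EAS": {
      "ACMG2015": {
        "cf_pct": 0.4,
        "cf_ci_pct": [0.2, 0.5],
        "incidence_denominator": 310688,
        "incidence_ci_denominators": [157533, 655641]
      },
      "HGMD": {
        "cf_pct": 0.2,
        "cf_ci_pct": [0.1, 0.3],
        "incidence_denominator": 767209,
        "incidence_ci_denominators": [328405, 2003437]
      },
      "CLINVAR": {
        "cf_pct": 0.3,
        "cf_ci_pct": [0.2, 0.4],
        "incidence_denominator": 639583,
        "incidence_ci_denominators": [284141, 1592214]
      }
    },
    "KOR": {
      "ACMG2015": {
        "cf_pct": 1.0,
        "cf_ci_pct": [0.6, 1.6],
        "incidence_denominator": 40380,
        "incidence_ci_denominators": [16557, 111408]
      },
      "HGMD": {
        "cf_pct": 0.6,
        "cf_ci_pct": [0.3, 1.1],
        "incidence_denominator": 101230,
        "incidence_ci_denominators": [33178, 379165]
      },
      "CLINVAR": {
        "cf_pct": 0.6,
        "cf_ci_pct": [0.3, 1.0],
        "incidence_denominator": 120472,
        "incidence_ci_denominators": [37631, 483595]
      }
    }
  },
  "expected_projection": {
    "KOR": {
      "total_carriers": 518000,
      "newborn_carriers_per_year": 3027,
      "affected_births_per_year": 7
    }
  }
}
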