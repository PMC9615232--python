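{
  "n_cases": 1618,
  "arms": {
    "retrospective": 565,
    "prospective": 1053
  },
  "per_step": {
    "1": {
      "positive": 187,
      "inconclusive": 55
    },
    "2": {
      "positive": 28,
      "inconclusive": 68
    },
    "3": {
      "positive": 14,
      "inconclusive": 8
    }
  },
  "total_positive": 229,
  "total_inconclusive": 131,
  "inheritance_mix": {
    "AD_de_novo": 145,
    "AD_inherited": 27,
    "AR": 40,
    "XL_de_novo": 7,
    "XL_maternal": 10
  },
  "family_history": {
    "significant": [
      48,
      100
    ],
    "_comment_sporadic": "positives among family-history cases = 12 retro + 42 pro = 54; sporadic = (229-54)/(1618-134)",
    "sporadic": [
      175,
      1484
    ]
  },
  "arm_positive": {
    "retrospective": [
      98,
      565
    ],
    "prospective": [
      131,
      1053
    ]
  },
  "nt_strata": {
    "isolated_total": [
      6,
      121
    ],
    "isolated_3p5_4p9": [
      3,
      78
    ],
    "isolated_ge5p0": [
      3,
      43
    ],
    "associated_ge3p5": [
      12,
      47
    ],
    "associated_3p0_3p4": [
      null,
      522
    ]
  },
  "incidental_findings": 8,
  "secondary_findings": 13,
  "candidate_variants": 33,
  "candidate_cases": 31,
  "reanalysis_breakdown": {
    "vus_to_lp_new_phenotype": 1,
    "if_to_positive_new_phenotype": 7,
    "new_disease_gene": 3,
    "intragenic_cnv": 2,
    "second_allele_sanger": 1
  }
}
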