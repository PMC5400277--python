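{
  "version": 1,
  "description": "Reported gynoecium phenotype counts used for penetrance arithmetic and for reconciling the in silico knockout panel with observed mutants. Records with counts_printed=false carry a percentage or qualitative phenotype reported without the underlying counts; their percentages are stored as-is and never recomputed.",
  "observations": [
    {
      "label": "spt_no_ck_response",
      "genotype": "spt",
      "assay": "repeated exogenous cytokinin (BAP) application; scored for medial-domain tissue outgrowths 3-4 weeks later",
      "phenotype": "no cytokinin-induced proliferation response in the medial domain",
      "altered": true,
      "affected": 14,
      "total": 16,
      "reported_percent": 87.5,
      "counts_printed": true,
      "perturbation": "SPT",
      "note": ""
    },
    {
      "label": "spt_minor_ck_response",
      "genotype": "spt",
      "assay": "repeated exogenous cytokinin (BAP) application; scored for medial-domain tissue outgrowths 3-4 weeks later",
      "phenotype": "only a minor proliferation effect in the medial domain",
      "altered": true,
      "affected": 2,
      "total": 16,
      "reported_percent": 12.5,
      "counts_printed": true,
      "perturbation": null,
      "note": "complement of spt_no_ck_response within the same 16 gynoecia"
    },
    {
      "label": "spt_apical_rescue_by_ck",
      "genotype": "spt",
      "assay": "48-hour cytokinin (BAP) treatment; apical closure scored 24 hours later",
      "phenotype": "virtually complete rescue of the apical fusion defect (septum defects not rescued)",
      "altered": true,
      "affected": 20,
      "total": 26,
      "reported_percent": 76.9,
      "counts_printed": true,
      "perturbation": null,
      "note": "rescue experiment, not a knockout readout; kept for penetrance arithmetic"
    },
    {
      "label": "ck_signaling_mutant_defects",
      "genotype": "arr1 arr10 arr12",
      "assay": "morphological characterization of untreated gynoecia and fruits",
      "phenotype": "reduced gynoecium and fruit length, reduced replum width, fewer ovules; septum fusion and transmitting-tract defects",
      "altered": true,
      "affected": null,
      "total": null,
      "reported_percent": null,
      "counts_printed": false,
      "perturbation": "CK",
      "note": "closest reported genotype for loss of cytokinin signaling output; no single 'CK off' genotype exists"
    },
    {
      "label": "pin3_ck_response_lost",
      "genotype": "pin3",
      "assay": "repeated exogenous cytokinin (BAP) application; scored 3-4 weeks later",
      "phenotype": "medial outgrowths absent; only apical-basal defects observed",
      "altered": true,
      "affected": null,
      "total": 330,
      "reported_percent": 78.2,
      "counts_printed": false,
      "perturbation": "PIN3",
      "note": "percentage reported without the affected count; stored as reported, never recomputed"
    },
    {
      "label": "taa1_tar2_gynoecium_defects",
      "genotype": "taa1 tar2",
      "assay": "morphological characterization of mutant combinations deficient in local auxin biosynthesis",
      "phenotype": "severely affected gynoecium development",
      "altered": true,
      "affected": null,
      "total": null,
      "reported_percent": null,
      "counts_printed": false,
      "perturbation": "TAA1",
      "note": "qualitative report only"
    },
    {
      "label": "pin3_pin7_phenotype_distribution",
      "genotype": "pin3 pin7",
      "assay": "morphological classification of untreated gynoecia",
      "phenotype": "unequal carpels 9.3%; one carpel 15.2%; stem-like structure 42.2%; fused gynoecia-like structures 33.3%",
      "altered": true,
      "affected": null,
      "total": 277,
      "reported_percent": null,
      "counts_printed": false,
      "perturbation": null,
      "note": "distribution reported as percentages only; stored as reported, never recomputed"
    }
  ]
}
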