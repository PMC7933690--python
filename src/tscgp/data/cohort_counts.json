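{
  "description": "Aggregate contingency counts from a literature-curated cohort of 261 tuberous sclerosis complex patients (54 TSC1, 207 TSC2; 148 of known sex) scored for renal angiomyolipoma (RAML). Each table is [a, b, c, d] with a = exposed & RAML, b = exposed & non-RAML, c = unexposed & RAML, d = unexposed & non-RAML. TSC2 domain tables exclude large-fragment mutations (denominators 96 RAML / 100 non-RAML).",
  "tables": {
    "sex:female": [47, 38, 21, 42],
    "gene:TSC1": [22, 32, 104, 103],
    "TSC1:truncation:PT": [11, 30, 11, 2],
    "TSC1:truncation:NT": [11, 2, 11, 30],
    "TSC1:type:missense": [11, 2, 11, 30],
    "TSC1:type:nonsense": [6, 12, 16, 20],
    "TSC1:type:frameshift": [4, 15, 18, 17],
    "TSC1:type:large_fragment": [1, 3, 21, 29],
    "TSC2:truncation:PT": [75, 63, 29, 40],
    "TSC2:domain:LZD": [0, 0, 96, 100],
    "TSC2:domain:CCD1": [3, 3, 93, 97],
    "TSC2:domain:CCD2": [1, 4, 95, 96],
    "TSC2:domain:TAD1": [15, 5, 81, 95],
    "TSC2:domain:GAPD": [8, 11, 88, 89],
    "TSC2:domain:TAD2+CaBD": [14, 13, 82, 87],
    "TSC2:domain:Others": [55, 64, 41, 36]
  },
  "prevalence": {
    "overall": [126, 261],
    "TSC1": [22, 54],
    "TSC2": [104, 207],
    "female": [47, 85],
    "male": [21, 63],
    "TSC1_PT": [11, 41],
    "TSC1_NT": [11, 13]
  }
}
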