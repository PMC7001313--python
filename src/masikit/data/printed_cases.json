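{
  "case5": {
    "vaf": 0.732,
    "baf_upper": 0.910,
    "tumor_content": 0.642,
    "candidate_totals": [3, 4],
    "note": "1q segment, three or more copies"
  },
  "case15": {
    "vaf": 0.659,
    "baf_upper": 0.660,
    "tumor_content": 0.988,
    "candidate_totals": [3, 4],
    "note": "1q segment, three or more copies"
  },
  "case10": {
    "vaf": 0.680,
    "baf_upper": 0.710,
    "tumor_content": 0.641,
    "candidate_totals": [2, 3],
    "note": "whole chromosome 1, two or more copies"
  },
  "case12": {
    "vaf": 0.799,
    "baf_upper": 0.850,
    "tumor_content": 0.906,
    "candidate_totals": [1, 2],
    "note": "partial 1q region, two or fewer copies"
  }
}
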