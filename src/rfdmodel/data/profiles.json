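[
  {
    "label": "male-national-weightlifters",
    "baseline_rfd": 16652,
    "description": "Group-average peak IMTP RFD (N/s) of national-caliber male weightlifters at the start of a 20-week training block"
  },
  {
    "label": "female-national-weightlifters",
    "baseline_rfd": 7663,
    "description": "Group-average peak IMTP RFD (N/s) of national-caliber female weightlifters at the start of a 20-week training block"
  },
  {
    "label": "model-default",
    "baseline_rfd": 15000,
    "description": "Conceptual baseline used throughout the model's worked examples"
  }
]
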