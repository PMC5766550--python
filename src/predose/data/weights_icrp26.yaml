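# ICRP Publication 26 weighting factors (effective dose equivalent).
# Besides the named tissues, the five remaining organs with the highest
# doses each receive 0.06 (skin, gonad organs and whole-body summaries are
# not remainder candidates).
scheme_id: ICRP26_EDE
remainder_rule: top5_at_0.06
gonads_organ: testes
weights:
  gonads: 0.25
  breasts: 0.15
  red_marrow: 0.12
  lungs: 0.12
  thyroid: 0.03
  osteogenic_cells: 0.03
remainder_weight: 0.30
remainder_excluded:
  - skin
  - testes
  - ovaries
  - total_body
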