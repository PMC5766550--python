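# ICRP Publication 60 tissue weighting factors (effective dose).
# The colon is the mass-weighted ULI/LLI combination; the thymus stands in
# for the esophagus; the remainder is the mass-weighted mean dose of the
# remainder-organ set. Gonads default to testes (adult male reporting).
scheme_id: ICRP60_ED
remainder_rule: mass_weighted_mean
gonads_organ: testes
weights:
  gonads: 0.20
  red_marrow: 0.12
  colon: 0.12
  lungs: 0.12
  stomach_wall: 0.12
  urinary_bladder_wall: 0.05
  breasts: 0.05
  liver: 0.05
  esophagus: 0.05
  thyroid: 0.05
  skin: 0.01
  osteogenic_cells: 0.01
remainder_weight: 0.05
remainder_organs:
  - adrenals
  - brain
  - small_intestine
  - kidneys
  - muscle
  - pancreas
  - spleen
  - thymus
  - uterus
aliases:
  uli_wall: colon
  lli_wall: colon
  thymus: esophagus
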