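organ,kind,petct_blk,petct_nblk,exvivo_blk,exvivo_nblk
adrenals,organ,1.89,2.005,2.856,3.38
brain,organ,0.072,0.075,0.422,0.615
breasts,organ,0.502,0.53,0.867,1.076
gallbladder_wall,organ,3.24,3.45,3.71,4.14
lli_wall,organ,0.388,0.405,1.173,1.526
small_intestine,organ,0.694,0.733,6.14,6.88
stomach_wall,organ,0.932,0.977,3.256,3.826
uli_wall,organ,0.928,0.985,5.03,7.286
heart_wall,organ,17.05,17.75,6.51,7.606
kidneys,organ,1.335,1.41,13.166,17.866
liver,organ,35.15,37.55,32.866,34.166
lungs,organ,1.045,1.105,10.383,12.036
muscle,organ,1.825,1.905,2.12,2.59
ovaries,organ,0.502,0.526,1.413,1.81
pancreas,organ,1.735,1.83,6.123,8.36
red_marrow,organ,0.621,0.655,18.566,24.133
osteogenic_cells,organ,0.5,0.526,10.373,13.6
skin,organ,0.339,0.357,0.594,0.8
spleen,organ,6.705,6.075,13.5,18.766
testes,organ,0.273,0.284,0.464,0.638
thymus,organ,0.704,0.739,1.173,1.46
thyroid,organ,0.345,0.36,0.691,0.917
urinary_bladder_wall,organ,0.4,0.418,0.784,1.037
uterus,organ,0.473,0.495,1.16,1.523
total_body,organ,2.015,2.125,3.08,3.693
effective_dose_equivalent,summary,4.27,4.46,8.65,10.653
effective_dose,summary,2.37,2.515,6.413,7.69
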