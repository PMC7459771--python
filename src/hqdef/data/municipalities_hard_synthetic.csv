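# Synthetic municipality water-chemistry table (the study's per-municipality data are not published).
# Generated by hqdef.generate_group(SynthConfig(group='hard', n_municipalities=21, seed=20200916)).
municipality_id,name,population,group,ca_mg_l,mg_mg_l,hardness_mmol_l
hard-001,synthetic-hard-001,511,hard,57.513,35.229,2.8845
hard-002,synthetic-hard-002,3229,hard,50.951,35.706,2.7404
hard-003,synthetic-hard-003,3288,hard,73.102,31.289,3.1113
hard-004,synthetic-hard-004,2323,hard,86.222,41.013,3.8388
hard-005,synthetic-hard-005,1121,hard,108.665,25.203,3.7483
hard-006,synthetic-hard-006,1154,hard,60.217,25.502,2.5517
hard-007,synthetic-hard-007,3603,hard,67.055,25.55,2.7243
hard-008,synthetic-hard-008,3104,hard,111.21,25.33,3.817
hard-009,synthetic-hard-009,737,hard,105.683,35.16,4.0835
hard-010,synthetic-hard-010,1109,hard,92.124,49.194,4.3226
hard-011,synthetic-hard-011,3002,hard,88.913,26.736,3.3185
hard-012,synthetic-hard-012,3691,hard,119.336,30.997,4.2529
hard-013,synthetic-hard-013,2799,hard,92.573,27.502,3.4414
hard-014,synthetic-hard-014,4957,hard,88.305,25.198,3.2401
hard-015,synthetic-hard-015,1997,hard,95.293,45.271,4.2403
hard-016,synthetic-hard-016,4107,hard,79.212,30.263,3.2216
hard-017,synthetic-hard-017,4047,hard,69.282,29.76,2.9531
hard-018,synthetic-hard-018,4738,hard,89.016,36.494,3.7226
hard-019,synthetic-hard-019,3769,hard,62.329,27.637,2.6923
hard-020,synthetic-hard-020,660,hard,96.192,33.188,3.7656
hard-021,synthetic-hard-021,2093,hard,64.099,26.714,2.6985
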