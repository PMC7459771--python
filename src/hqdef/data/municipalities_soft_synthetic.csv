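# Synthetic municipality water-chemistry table (the study's per-municipality data are not published).
# Generated by hqdef.generate_group(SynthConfig(group='soft', n_municipalities=34, seed=20200915)).
municipality_id,name,population,group,ca_mg_l,mg_mg_l,hardness_mmol_l
soft-001,synthetic-soft-001,3371,soft,19.214,6.624,0.752
soft-002,synthetic-soft-002,4019,soft,17.495,4.512,0.6222
soft-003,synthetic-soft-003,4265,soft,26.984,4.756,0.869
soft-004,synthetic-soft-004,4598,soft,15.321,5.055,0.5903
soft-005,synthetic-soft-005,2544,soft,12.588,6.889,0.5975
soft-006,synthetic-soft-006,3021,soft,23.664,4.024,0.756
soft-007,synthetic-soft-007,1940,soft,16.592,1.678,0.483
soft-008,synthetic-soft-008,830,soft,25.149,4.658,0.8191
soft-009,synthetic-soft-009,4310,soft,17.304,4.996,0.6373
soft-010,synthetic-soft-010,3140,soft,19.424,4.102,0.6534
soft-011,synthetic-soft-011,2608,soft,18.434,9.86,0.8656
soft-012,synthetic-soft-012,4531,soft,22.585,6.302,0.8228
soft-013,synthetic-soft-013,3573,soft,22.981,9.189,0.9515
soft-014,synthetic-soft-014,4982,soft,15.089,2.815,0.4923
soft-015,synthetic-soft-015,960,soft,15.52,7.588,0.6994
soft-016,synthetic-soft-016,1570,soft,16.998,5.942,0.6686
soft-017,synthetic-soft-017,3212,soft,20.578,3.531,0.6587
soft-018,synthetic-soft-018,2189,soft,18.11,1.882,0.5293
soft-019,synthetic-soft-019,628,soft,19.308,5.561,0.7106
soft-020,synthetic-soft-020,1949,soft,20.078,4.223,0.6747
soft-021,synthetic-soft-021,2408,soft,16.803,4.639,0.6101
soft-022,synthetic-soft-022,3601,soft,22.605,4.727,0.7585
soft-023,synthetic-soft-023,4395,soft,18.409,4.147,0.63
soft-024,synthetic-soft-024,4329,soft,22.693,4.125,0.7359
soft-025,synthetic-soft-025,4579,soft,21.479,3.823,0.6932
soft-026,synthetic-soft-026,2859,soft,16.619,2.827,0.531
soft-027,synthetic-soft-027,2436,soft,22.367,0.843,0.5928
soft-028,synthetic-soft-028,4661,soft,23.866,1.247,0.6468
soft-029,synthetic-soft-029,747,soft,27.387,1.952,0.7637
soft-030,synthetic-soft-030,2151,soft,21.662,5.375,0.7616
soft-031,synthetic-soft-031,4075,soft,23.359,6.018,0.8304
soft-032,synthetic-soft-032,2351,soft,19.56,1.61,0.5543
soft-033,synthetic-soft-033,3488,soft,14.04,2.401,0.4491
soft-034,synthetic-soft-034,1607,soft,15.009,1.767,0.4472
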