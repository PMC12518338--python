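scenario,biochar_kg_per_dry_tonne,rng_GJ_per_dry_tonne
B10:M0,557,6.2
B9:M1,545,7.0
B8:M2,533,7.4
B7:M3,521,7.7
B6:M4,509,8.1
B5:M5,497,8.5
B4:M6,485,8.9
B3:M7,472,9.3
B2:M8,460,9.7
B1:M9,448,10.1
B0:M10,436,10.1
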