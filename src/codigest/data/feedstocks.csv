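name,TS,VS,RL,RF,RP,NDF,ADF,ADL,DVS
cattle_manure,17.99,84.74,3.26,26.59,13.74,47.73,36.54,14.96,49.5
switchgrass,91.00,93.79,8.39,49.60,5.89,71.30,43.06,5.35,36.1
indiangrass,91.00,92.38,11.01,44.24,8.14,69.23,37.97,3.80,36.1
big_bluestem,91.00,91.19,7.86,33.19,7.53,69.10,36.39,3.80,36.1
prairie_biomass,91.00,92.45,6.78,42.34,7.19,69.88,39.14,4.32,36.1
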