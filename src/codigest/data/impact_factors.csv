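stream,category,factor,unit
prairie_biomass,acidification,1.88e-2,mol H+ eq/kg
prairie_biomass,ecotoxicity,-1.04,kg 2-4-D eq/kg
prairie_biomass,eutrophication,3.09e-4,kg N/kg
prairie_biomass,global_warming,5.60e-2,kg CO2 eq/kg
prairie_biomass,ozone_depletion,5.80e-9,kg CFC-11 eq/kg
prairie_biomass,photochemical_oxidation,3.68e-4,kg NOx eq/kg
prairie_biomass,carcinogenics,-6.69e-5,kg benzene eq/kg
prairie_biomass,non_carcinogenics,-1.30e1,kg toluene eq/kg
prairie_biomass,respiratory_effects,9.08e-5,kg PM2.5 eq/kg
cattle_manure,acidification,-6.16e-3,mol H+ eq/kg
cattle_manure,ecotoxicity,-1.89e-2,kg 2-4-D eq/kg
cattle_manure,eutrophication,-1.93e-5,kg N/kg
cattle_manure,global_warming,-3.15e-2,kg CO2 eq/kg
cattle_manure,ozone_depletion,-1.80e-9,kg CFC-11 eq/kg
cattle_manure,photochemical_oxidation,-6.24e-5,kg NOx eq/kg
cattle_manure,carcinogenics,-4.96e-5,kg benzene eq/kg
cattle_manure,non_carcinogenics,-2.55e-1,kg toluene eq/kg
cattle_manure,respiratory_effects,-2.90e-5,kg PM2.5 eq/kg
avoided_n_fertilizer,acidification,-1.83,mol H+ eq/kg
avoided_n_fertilizer,ecotoxicity,-4.56,kg 2-4-D eq/kg
avoided_n_fertilizer,eutrophication,-6.29e-3,kg N/kg
avoided_n_fertilizer,global_warming,-9.7,kg CO2 eq/kg
avoided_n_fertilizer,ozone_depletion,-4.88e-7,kg CFC-11 eq/kg
avoided_n_fertilizer,photochemical_oxidation,-1.78e-2,kg NOx eq/kg
avoided_n_fertilizer,carcinogenics,-1.09e-2,kg benzene eq/kg
avoided_n_fertilizer,non_carcinogenics,-5.55e1,kg toluene eq/kg
avoided_n_fertilizer,respiratory_effects,-7.73e-3,kg PM2.5 eq/kg
mea,acidification,4.7e-1,mol H+ eq/kg
mea,ecotoxicity,1.05,kg 2-4-D eq/kg
mea,eutrophication,1.03e-2,kg N/kg
mea,global_warming,3.36,kg CO2 eq/kg
mea,ozone_depletion,1.43e-7,kg CFC-11 eq/kg
mea,photochemical_oxidation,5.41e-3,kg NOx eq/kg
mea,carcinogenics,4.32e-2,kg benzene eq/kg
mea,non_carcinogenics,1.09e1,kg toluene eq/kg
mea,respiratory_effects,3.27e-3,kg PM2.5 eq/kg
natural_gas,acidification,9.25e-2,mol H+ eq/kg
natural_gas,ecotoxicity,8.99e-2,kg 2-4-D eq/kg
natural_gas,eutrophication,7.05e-5,kg N/kg
natural_gas,global_warming,4.87e-1,kg CO2 eq/kg
natural_gas,ozone_depletion,2.38e-7,kg CFC-11 eq/kg
natural_gas,photochemical_oxidation,8.54e-4,kg NOx eq/kg
natural_gas,carcinogenics,8.32e-4,kg benzene eq/kg
natural_gas,non_carcinogenics,4.54,kg toluene eq/kg
natural_gas,respiratory_effects,3.47e-4,kg PM2.5 eq/kg
ch4_leak,acidification,0,mol H+ eq/kg
ch4_leak,ecotoxicity,2.45e-7,kg 2-4-D eq/kg
ch4_leak,eutrophication,0,kg N/kg
ch4_leak,global_warming,1.35e1,kg CO2 eq/kg
ch4_leak,ozone_depletion,0,kg CFC-11 eq/kg
ch4_leak,photochemical_oxidation,1.73e-3,kg NOx eq/kg
ch4_leak,carcinogenics,0,kg benzene eq/kg
ch4_leak,non_carcinogenics,1.50e-3,kg toluene eq/kg
ch4_leak,respiratory_effects,0,kg PM2.5 eq/kg
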