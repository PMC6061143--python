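biome,n_assessments,mean_kg_per_ha_yr,se_kg_per_ha_yr,area_ha
tropical_forests,7,112.5,9.2,1750e6
temperate_boreal_forests,44,44.1,6.2,2410e6
tropical_grasslands_savannas,7,15.8,2.8,3040e6
temperate_grasslands,11,7.5,0.9,1500e6
cropland,8,20.9,9.0,1350e6
deserts,18,4.1,0.8,2770e6
arctic_tundra,8,4.6,1.3,560e6
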