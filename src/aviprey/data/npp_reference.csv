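biome,npp_gC_per_m2_yr
tropical_forests,1250
temperate_boreal_forests,480
tropical_grasslands_savannas,540
temperate_grasslands,375
cropland,305
deserts,125
arctic_tundra,90
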