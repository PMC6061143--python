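biome,density_per_ha,mass_kg,area_ha,climate_class
tropical_forests,20.00,0.0320,1750e6,tropical
temperate_boreal_forests,10.00,0.0270,2410e6,temperate_cold
tropical_grasslands_savannas,9.25,0.0340,3040e6,tropical
temperate_grasslands,4.00,0.0450,1500e6,temperate_cold
cropland,3.00,0.0380,1350e6,temperate_cold
deserts,1.75,0.1558,2770e6,temperate_cold
arctic_tundra,2.00,0.0674,560e6,temperate_cold
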