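predator_type,biome_class,prey_kg_per_ha_yr_low,prey_kg_per_ha_yr_high
insectivorous_birds,salt_marsh,545,545
insectivorous_birds,urban_areas,84,289
insectivorous_birds,tropical_forests,100,176
insectivorous_birds,temperate_forests,35,137
insectivorous_birds,tree_lined_field_roads,36,79
insectivorous_birds,grasslands_crop_fields,10,31
piscivorous_birds,freshwater_lakes_marshes,8,49
insectivorous_primates,tropical_forest,10,32
insectivorous_bats,tropical_forest,4,4
shrews,taiga_forest,25,350
shrews,reed_swamp,6,6
hedgehogs,reed_swamp,1,1
lizards,various_biomes,3,9
lizards,tropical_island_woodland,85,85
salamanders,temperate_forests,7,7
frogs,tropical_forest,1,163
frogs,temperate_grasslands,1,180
ants,tropical_forest,21,147
ants,temperate_forest,177,177
ants,temperate_grasslands,46,536
spiders,tropical_coffee_plantation,160,320
spiders,temperate_forests,20,100
spiders,temperate_grasslands,20,230
spiders,crop_fields,10,10
scorpions,arid_zone,8,8
wasps,temperate_forest,1,8
robber_flies,tropical_forest,7,7
ground_beetles,temperate_forest_cropland,20,20
rove_beetles,temperate_forest,64,64
centipedes,temperate_forest,100,100
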