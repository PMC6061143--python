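biome,value_kg_per_ha,source_type,season_coverage,insectivore_applied,diet_applied,annualized
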