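# Example deny list: genera recurrently reported in sequenced negative
# controls of low-biomass studies (kit and reagent contaminants).
# Edit freely; matching is case-insensitive at any lineage rank.
Ralstonia
Delftia
Bradyrhizobium
Sphingomonas
Burkholderia
Stenotrophomonas
Cutibacterium
Methylobacterium
Herbaspirillum
Acidovorax
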