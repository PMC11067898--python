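taxon,chalybea,cryptoleuca,dominicensis,elegans,modesta,murphyi,sinaloae,subis,tapera
chalybea,,,,,,,,,
cryptoleuca,,,,,,,,,
dominicensis,,,,,,,,,
elegans,-2,-2,-1,,,,,,
modesta,,,,-1,,,,,
murphyi,-2,-2,-1,1,,,,,
sinaloae,,,,,,,,,
subis,,,1,2,1,1,,,
tapera,1,,-1,,-1,-1,,2,
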