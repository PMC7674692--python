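((((tree_shrew:85.0,(mouse_lemur:74.0,(marmoset:43.0,(macaque:29.0,(gorilla:9.0,(human:6.5,chimpanzee:6.5):2.5):20.0):14.0):31.0)Primates:11.0):3.0,(rabbit:82.0,(guinea_pig:73.0,(hamster:24.0,(mouse:12.0,rat:12.0):12.0)Muroidea:49.0)Rodentia:9.0)Glires:6.0)Euarchontoglires:6.0,(hedgehog:78.0,((pig:62.0,(cow:25.0,sheep:25.0):37.0):14.0,(horse:74.0,(cat:54.0,((panda:40.0,polar_bear:40.0):6.0,(red_fox:12.5,(dog:1.0,gray_wolf:1.0):11.5):33.5)Caniformia:8.0)Carnivora:20.0):2.0):2.0)Laurasiatheria:16.0)Boreoeutheria:5.0,(armadillo:90.0,tenrec:90.0)Atlantogenata:9.0);
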