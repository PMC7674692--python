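# SYNTHETIC life-history trait table (order-of-magnitude literature values),
# species match data/placental_tree.nwk tips.
species	body_mass_kg	max_longevity_yr	gestation_days
tree_shrew	0.18	12	45
mouse_lemur	0.06	18	62
marmoset	0.35	22	145
macaque	7.5	35	165
gorilla	140.0	50	255
human	62.0	85	270
chimpanzee	45.0	55	230
rabbit	2.0	12	31
guinea_pig	0.9	10	65
hamster	0.1	4	17
mouse	0.02	4	20
rat	0.3	5	22
hedgehog	0.8	10	40
pig	120.0	25	114
cow	650.0	22	280
sheep	80.0	20	150
horse	450.0	40	340
cat	4.5	25	65
panda	100.0	25	110
polar_bear	450.0	30	240
red_fox	6.0	12	52
dog	35.0	20	62
gray_wolf	40.0	18	63
armadillo	4.5	20	120
tenrec	0.9	10	60
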