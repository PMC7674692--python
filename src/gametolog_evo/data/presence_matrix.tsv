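# SYNTHETIC transcription of the ancestral-Y-gametolog presence/absence matrix.
# States chosen so that seven genes (SRY, RBMY, TSPY, DDX3Y, UTY, USP9Y, ZFY) are
# present in every species and minimum Dollo loss counts are 1 (EIF2S3Y),
# 2 (HSFY, UBA1Y, EIFA1Y, CULB4Y), 3 (TXLNGY), 4 (KDM5D), 5 (RPS4Y, TMSB4Y).
# pseudogene_expressed = detectable expression from an annotated pseudogene;
# unclear = status unknown (missing data). Species match data/placental_tree.nwk tips.
species	SRY	RBMY	TSPY	DDX3Y	UTY	USP9Y	ZFY	EIF2S3Y	HSFY	UBA1Y	EIFA1Y	CULB4Y	TXLNGY	KDM5D	RPS4Y	TMSB4Y
tree_shrew	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present	absent
mouse_lemur	present	present	present	present	present	present	present	present	present	present	present	present	present	present	absent	present
marmoset	present	present	present	present	present	present	present	present	present	present	present	present	present	absent	present	present
macaque	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present
gorilla	present	present	present	present	present	present	present	present	present	absent	present	present	present	present	present	present
human	present	present	present	present	present	present	present	present	present	absent	present	present	present	present	present	present
chimpanzee	present	present	present	present	present	present	present	present	present	absent	present	present	present	present	present	present
rabbit	present	present	present	present	present	present	present	present	present	present	present	absent	present	present	present	absent
guinea_pig	present	present	present	present	present	present	present	present	present	present	absent	present	present	present	absent	present
hamster	present	present	present	present	present	present	present	present	absent	present	present	present	present	absent	present	present
mouse	present	present	present	present	present	present	present	present	absent	present	present	present	absent	present	present	present
rat	present	present	present	present	present	present	present	present	absent	present	present	present	absent	present	present	present
hedgehog	present	present	present	present	present	present	present	present	present	present	present	present	present	absent	present	present
pig	present	present	present	present	present	present	present	present	present	present	present	present	absent	present	present	present
cow	present	present	present	present	present	present	present	present	present	present	absent	present	present	present	absent	present
sheep	present	present	present	present	present	present	present	present	present	present	absent	present	present	present	absent	present
horse	present	present	present	present	present	present	present	present	absent	present	present	present	present	present	present	absent
cat	present	present	present	present	present	present	present	present	present	present	present	absent	present	present	present	present
panda	present	present	present	present	present	present	present	present	present	present	present	present	present	present	absent	unclear
polar_bear	present	present	present	present	present	present	present	present	present	present	present	present	present	present	absent	present
red_fox	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present	absent
dog	present	pseudogene_expressed	present	present	present	present	present	present	present	present	present	present	present	present	present	present
gray_wolf	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present	present
armadillo	present	present	present	present	present	present	present	absent	present	present	present	present	absent	present	absent	present
tenrec	present	present	unclear	present	present	present	present	absent	present	absent	present	present	present	absent	present	absent
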