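Distance	LuminalA	LuminalB	HER2Plus	BasalLike	Unknown
LuminalA	0	151	573	589	1190
LuminalB	151	0	544	598	713
HER2Plus	573	544	0	302	990
BasalLike	589	598	302	0	1011
Unknown	1190	713	990	1011	0
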