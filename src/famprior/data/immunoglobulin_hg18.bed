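chr22	20715571	21595082	IGL
chr14	105065300	106352275	IGH
chr2	88937988	89411302	IGK
chr14	21159896	22090937	TRA
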