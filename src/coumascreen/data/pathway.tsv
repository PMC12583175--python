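from	to	enzyme	authenticated
phenylalanine	cinnamic acid	PAL	true
tyrosine	p-coumaric acid	TAL	true
cinnamic acid	p-coumaric acid	C4H	true
p-coumaric acid	caffeic acid	C3H	true
caffeic acid	ferulic acid	OMT	true
p-coumaric acid	2,4-dihydroxy-cinnamic acid	C2'H	true
2,4-dihydroxy-cinnamic acid	umbelliferone	COSY	true
ferulic acid	scopoletin	F6'H	true
umbelliferone	esculetin		false
scopoletin	scopolin	2GT	true
scopoletin	fraxetin	S8H	true
fraxetin	isofraxidin	OMT	true
esculetin	6,7-dimethoxycoumarin	OMT	false
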