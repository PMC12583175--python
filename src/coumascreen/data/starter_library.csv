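name,formula,class,subclass,source,score
scopoletin,C10H8O4,coumarin,hydroxycoumarin,literature,
isofraxidin,C11H10O5,coumarin,hydroxycoumarin,literature,
scopolin,C16H18O9,coumarin,coumarin glycoside,literature,
fraxetin,C10H8O5,coumarin,hydroxycoumarin,literature,
umbelliferone,C9H6O3,coumarin,hydroxycoumarin,literature,
esculetin,C9H6O4,coumarin,hydroxycoumarin,literature,
"6,7-dimethoxycoumarin",C11H10O4,coumarin,methoxycoumarin,literature,
"6,7,8-trimethoxycoumarin",C12H12O5,coumarin,methoxycoumarin,literature,
"5,6,7-trimethoxycoumarin",C12H12O5,coumarin,methoxycoumarin,literature,
chimsalicifoliusin A,C21H16O9,coumarin,bicoumarin,literature,
chimsalicifoliusin B,C20H14O8,coumarin,bicoumarin,literature,
arteminorin A,C22H18O10,coumarin,bicoumarin,literature,
"3,3'-biisofraxidin",C22H18O10,coumarin,bicoumarin,literature,
cinnamic acid,C9H8O2,cinnamic_acid,,literature,
p-coumaric acid,C9H8O3,cinnamic_acid,,literature,
caffeic acid,C9H8O4,cinnamic_acid,,literature,
ferulic acid,C10H10O4,cinnamic_acid,methoxylated,literature,
sinapinic acid,C11H12O5,cinnamic_acid,methoxylated,literature,
"2,4-dihydroxycinnamic acid",C9H8O4,cinnamic_acid,,literature,
luteoloside,C21H20O11,flavonoid,flavone glycoside,literature,
quercitrin,C21H20O11,flavonoid,flavonol glycoside,literature,
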